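"""Pulse-train detection, call measurement and rule-based classification.

The classifier reproduces an analyst's decision rules for ultrasonic beluga
calls:

* echolocation buzzes (rapidly accelerating click trains, or trains adjacent
  to echolocation click sequences) are excluded from communication calls;
* HFBP calls are pulse trains with a consistent repetition rate whose main
  band starts at or above 20 kHz — biphonal (HFBP-B) when an isolated
  low-frequency element sits below a silent spectral gap, monophonic
  (HFBP-M) when there is no energy below 30 kHz;
* contact calls (CC) are broadband (from a few hundred Hz to Nyquist),
  long-duration pulse trains;
* everything else (whistles, short bursts) is OTHER.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .calibration import CalibratedClip
from .selections import SelectionRecord

__all__ = [
    "PulseTrain",
    "CallMeasurements",
    "ClassifierConfig",
    "detect_pulses",
    "measure_call",
    "spectral_components",
    "classify_call",
    "classify_selection",
    "HFBP_M",
    "HFBP_B",
    "CC",
    "OTHER",
    "BUZZ_EXCLUDED",
]

HFBP_M = "HFBP_M"
HFBP_B = "HFBP_B"
CC = "CC"
OTHER = "OTHER"
BUZZ_EXCLUDED = "BUZZ_EXCLUDED"

#: minimum separation between detected pulses, seconds
MIN_PULSE_SEPARATION_S = 0.2e-3


@dataclass
class PulseTrain:
    """Detected pulse onsets and inter-pulse-interval (IPI) statistics."""

    pulse_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=np.float64)
        if self.pulse_times_s.size > 1 and np.any(np.diff(self.pulse_times_s) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times_s.size)

    @property
    def ipis_s(self) -> np.ndarray:
        return np.diff(self.pulse_times_s)

    @property
    def rate_hz(self) -> float:
        ipis = self.ipis_s
        return 1.0 / float(np.median(ipis)) if ipis.size else np.nan

    @property
    def ipi_cv(self) -> float:
        ipis = self.ipis_s
        if ipis.size < 2:
            return np.nan
        return float(np.std(ipis) / np.mean(ipis))

    @property
    def ipi_slope(self) -> float:
        """Least-squares slope of IPI versus time (s per s)."""
        ipis = self.ipis_s
        if ipis.size < 2:
            return np.nan
        t = self.pulse_times_s[:-1]
        return float(np.polyfit(t, ipis, 1)[0])

    @property
    def ipi_fractional_trend(self) -> float:
        """Fractional IPI change over the train (negative = accelerating)."""
        ipis = self.ipis_s
        if ipis.size < 2:
            return np.nan
        span = self.pulse_times_s[-1] - self.pulse_times_s[0]
        return float(self.ipi_slope * span / np.mean(ipis))


@dataclass
class CallMeasurements:
    """Acoustic call parameters in the units used for repertoire tables (kHz, s)."""

    low_freq_khz: float
    high_freq_khz: float
    delta_time_s: float
    peak_freq_khz: float
    center_freq_khz: float
    q1_freq_khz: float
    q3_freq_khz: float

    def __post_init__(self) -> None:
        order = (
            self.low_freq_khz,
            self.q1_freq_khz,
            self.center_freq_khz,
            self.q3_freq_khz,
            self.high_freq_khz,
        )
        if any(a > b + 1e-9 for a, b in zip(order, order[1:])):
            raise ValueError(f"quantile ordering violated: {order}")
        if self.delta_time_s <= 0:
            raise ValueError("delta_time must be positive")

    @property
    def delta_freq_khz(self) -> float:
        return self.high_freq_khz - self.low_freq_khz


@dataclass(frozen=True)
class ClassifierConfig:
    """Operational thresholds behind the qualitative call definitions.

    The repertoire definitions are qualitative ("consistent repetition
    rate", "immediately preceded"); these defaults operationalize them and
    are all configurable.
    """

    hfbp_min_low_khz: float = 20.0  # main band onset gating HFBP
    hfbp_m_clean_below_khz: float = 30.0  # typical HFBP-M: no energy below this
    # strict_hfbp_m=True demotes no-LF trains starting in 20-30 kHz to OTHER
    # instead of counting them as monophonic HFBP
    strict_hfbp_m: bool = False
    cc_min_bandwidth_khz: float = 20.0
    cc_min_duration_s: float = 0.5
    max_ipi_cv: float = 0.35  # "consistent repetition rate"
    buzz_trend_threshold: float = -0.3  # fractional IPI decline per call
    click_context_window_s: float = 1.0  # "immediately preceded or followed"
    edge_threshold_db: float = 20.0  # low/high freq at -20 dB re peak
    lf_gap_depth_db: float = 10.0  # silent gap between biphonal components
    lf_excess_db: float = 6.0  # LF element must clear ambient by this
    min_pulses: int = 3


def detect_pulses(
    clip: CalibratedClip,
    band: tuple[float, float],
    threshold_db: float = 10.0,
) -> PulseTrain:
    """Detect band-limited transients via the analytic-signal envelope.

    Band-passes the clip, takes the magnitude of the analytic signal
    (smoothed over ~0.15 ms so intra-pulse carrier jitter does not split
    one transient into several detections) and picks peaks more than
    ``threshold_db`` above the median envelope, with a minimum separation
    of 0.2 ms.  Returns an empty train for silence.
    """
    low, high = band
    nyq = clip.fs / 2.0
    if not 0 < low < high <= nyq + 1e-6:
        raise ValueError(f"invalid band {band} for fs={clip.fs}")
    high = min(high, nyq * 0.999)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=clip.fs, output="sos")
    x = signal.sosfiltfilt(sos, clip.samples)
    env = np.abs(signal.hilbert(x))
    smooth_n = max(3, int(round(0.75 * MIN_PULSE_SEPARATION_S * clip.fs)))
    kernel = np.hanning(smooth_n)
    env = np.convolve(env, kernel / kernel.sum(), mode="same")
    floor = np.median(env)
    if floor <= 0:
        return PulseTrain(np.empty(0))
    height = floor * 10.0 ** (threshold_db / 20.0)
    distance = max(1, int(round(MIN_PULSE_SEPARATION_S * clip.fs)))
    peaks, _ = signal.find_peaks(env, height=height, distance=distance)
    return PulseTrain(peaks / clip.fs)


def _segment_psd(clip: CalibratedClip, sel: SelectionRecord) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectrum (1024-point Hann) of the selection's time span."""
    if sel.high_hz > clip.nyquist + 1e-6:
        raise ValueError("selection extends beyond Nyquist")
    seg = clip.segment(sel.begin_s, min(sel.end_s, clip.duration_s))
    nperseg = min(1024, seg.samples.size)
    freqs, psd = signal.welch(
        seg.samples, fs=clip.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False, scaling="density",
    )
    return freqs, psd


def _energy_quantile(freqs: np.ndarray, psd: np.ndarray, frac: float) -> float:
    """Frequency below which ``frac`` of the energy lies (bin resolution)."""
    cum = np.cumsum(psd)
    total = cum[-1]
    idx = int(np.searchsorted(cum, frac * total))
    return float(freqs[min(idx, freqs.size - 1)])


def measure_call(
    clip: CalibratedClip,
    sel: SelectionRecord,
    band: tuple[float, float] | None = None,
    edge_threshold_db: float = 20.0,
) -> CallMeasurements:
    """Measure Table-style acoustic parameters of a selected call.

    Peak frequency is the argmax of the power spectrum within the analysis
    band (the selection's frequency bounds unless ``band`` narrows them,
    e.g. to the main pulse train of a biphonal call); center/Q1/Q3 are the
    50/25/75% cumulative-energy frequencies in that band; low/high are the
    first/last frequencies whose density exceeds the peak minus
    ``edge_threshold_db``.
    """
    freqs, psd = _segment_psd(clip, sel)
    lo, hi = band if band is not None else (sel.low_hz, sel.high_hz)
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band) or psd[in_band].max() <= 0:
        raise ValueError("no spectral energy inside the analysis band")
    fb, pb = freqs[in_band], psd[in_band]
    peak = float(fb[np.argmax(pb)])
    q1 = _energy_quantile(fb, pb, 0.25)
    center = _energy_quantile(fb, pb, 0.50)
    q3 = _energy_quantile(fb, pb, 0.75)
    thresh = pb.max() * 10.0 ** (-edge_threshold_db / 10.0)
    above = np.nonzero(pb >= thresh)[0]
    low = min(float(fb[above[0]]), q1)
    high = max(float(fb[above[-1]]), q3)
    return CallMeasurements(
        low_freq_khz=low / 1e3,
        high_freq_khz=high / 1e3,
        delta_time_s=sel.duration_s,
        peak_freq_khz=peak / 1e3,
        center_freq_khz=center / 1e3,
        q1_freq_khz=q1 / 1e3,
        q3_freq_khz=q3 / 1e3,
    )


@dataclass
class ComponentAnalysis:
    """Spectral components of a selection: main band plus optional LF element."""

    main_low_hz: float
    main_high_hz: float
    lf_present: bool
    lf_low_hz: float | None = None
    lf_high_hz: float | None = None


def spectral_components(
    clip: CalibratedClip,
    sel: SelectionRecord,
    config: ClassifierConfig = ClassifierConfig(),
    noise_psd: np.ndarray | None = None,
) -> ComponentAnalysis:
    """Split a selection's spectrum into a main band and a possible LF element.

    Contiguous runs of bins within ``edge_threshold_db`` of the spectral peak
    above 20 kHz form candidate components; the run containing that peak is
    the main pulse band.  A run wholly below 20 kHz counts as a biphonal LF
    element when its own peak clears the out-of-component floor by
    ``lf_excess_db`` and the gap between it and the main band dips at least
    ``lf_gap_depth_db`` below the LF peak ("no acoustic energy between the
    components").
    """
    freqs, psd = _segment_psd(clip, sel)
    use = freqs >= 50.0
    if noise_psd is not None:
        if noise_psd.shape != psd.shape:
            raise ValueError("noise_psd must share the selection's frequency grid")
        noise_psd = noise_psd[use]
    freqs, psd = freqs[use], psd[use]
    with np.errstate(divide="ignore"):
        level = 10.0 * np.log10(np.maximum(psd, 1e-300))
    hi_mask = freqs >= config.hfbp_min_low_khz * 1e3
    ref = level[hi_mask].max() if np.any(hi_mask) else level.max()
    ref = max(ref, level.max() - 40.0)  # guard: all-LF calls
    above = level >= ref - config.edge_threshold_db
    noise_level = None
    if noise_psd is not None:
        with np.errstate(divide="ignore"):
            noise_level = 10.0 * np.log10(np.maximum(noise_psd, 1e-300))
        # analyst-style spectrogram contrast: bins that do not stand clear
        # of the local background (vessel noise included) are background
        above &= level >= noise_level + config.lf_excess_db

    # contiguous runs of above-threshold bins
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, above.size - 1))
    if not runs:
        raise ValueError("selection has no spectral energy above the edge threshold")

    # anchor the main band at the ultrasonic peak when one exists: the LF
    # element of a biphonal call can carry the densest energy of the whole
    # selection, but it is never the main pulse band
    masked = np.where(above, level, -np.inf)
    if np.any(above & hi_mask):
        peak_idx = int(np.argmax(np.where(hi_mask, masked, -np.inf)))
    else:
        peak_idx = int(np.argmax(masked))
    main = next(r for r in runs if r[0] <= peak_idx <= r[1])
    main_low, main_high = float(freqs[main[0]]), float(freqs[main[1]])

    lf_present = False
    lf_low = lf_high = None
    in_any_run = np.zeros(freqs.size, dtype=bool)
    for r in runs:
        in_any_run[r[0] : r[1] + 1] = True
    for r in runs:
        if r == main or freqs[r[1]] >= config.hfbp_min_low_khz * 1e3:
            continue
        lf_peak = level[r[0] : r[1] + 1].max()
        if noise_level is not None:
            # direct ambient-excess test against the measured background
            floor = float(noise_level[r[0] : r[1] + 1].max())
        else:
            # ambient reference local to the candidate (octave neighborhood),
            # so the sloped ambient bed itself cannot pass as an LF element
            hood = (freqs >= freqs[r[0]] / 2.0) & (freqs <= freqs[r[1]] * 2.0) & ~in_any_run
            floor = float(np.median(level[hood])) if np.any(hood) else float(level.min())
        if lf_peak < floor + config.lf_excess_db:
            continue
        gap = level[r[1] + 1 : main[0]]
        if gap.size and gap.min() <= lf_peak - config.lf_gap_depth_db:
            lf_present = True
            lf_low, lf_high = float(freqs[r[0]]), float(freqs[r[1]])
            break
    return ComponentAnalysis(
        main_low_hz=main_low,
        main_high_hz=main_high,
        lf_present=lf_present,
        lf_low_hz=lf_low,
        lf_high_hz=lf_high,
    )


def classify_call(
    m: CallMeasurements,
    train: PulseTrain,
    near_click_train: bool = False,
    lf_present: bool = False,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Apply the rule cascade; ambiguity is resolved by rule order.

    1. BUZZ_EXCLUDED — accelerating IPIs or adjacency to echolocation clicks;
    2. HFBP — pulsed, consistent IPIs, main band at/above 20 kHz (HFBP_B
       with an isolated LF element, HFBP_M if also clean below 30 kHz);
    3. CC — pulsed, broadband from below 20 kHz, wide and long enough;
    4. OTHER — everything else.  Deterministic given its inputs.
    """
    pulsed = train.n_pulses >= config.min_pulses
    if pulsed and (
        near_click_train
        or (
            np.isfinite(train.ipi_fractional_trend)
            and train.ipi_fractional_trend < config.buzz_trend_threshold
        )
    ):
        return BUZZ_EXCLUDED
    consistent = np.isfinite(train.ipi_cv) and train.ipi_cv <= config.max_ipi_cv
    if pulsed and consistent and m.low_freq_khz >= config.hfbp_min_low_khz:
        if lf_present:
            return HFBP_B
        if m.low_freq_khz >= config.hfbp_m_clean_below_khz or not config.strict_hfbp_m:
            return HFBP_M
        return OTHER
    if (
        pulsed
        and m.low_freq_khz < config.hfbp_min_low_khz
        and m.delta_freq_khz >= config.cc_min_bandwidth_khz
        and m.delta_time_s >= config.cc_min_duration_s
    ):
        return CC
    return OTHER


def classify_selection(
    clip: CalibratedClip,
    sel: SelectionRecord,
    near_click_train: bool = False,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[str, CallMeasurements, PulseTrain]:
    """Measure and classify one selection end to end.

    Estimates the background spectrum from the quieter of the two windows
    adjacent to the selection (the contrast reference an analyst gets from
    the surrounding spectrogram), runs component analysis to isolate the
    main pulse band (excluding any biphonal LF element), detects the pulse
    train in that band, measures the main-band parameters, and applies the
    rule cascade.
    """
    noise_psd = _adjacent_noise_psd(clip, sel)
    comp = spectral_components(clip, sel, config, noise_psd=noise_psd)
    m = measure_call(
        clip, sel, band=(comp.main_low_hz, comp.main_high_hz),
        edge_threshold_db=config.edge_threshold_db,
    )
    # pulse detection in the upper part of the main band, where the ambient
    # bed and any vessel noise are weakest relative to the call
    seg = clip.segment(sel.begin_s, min(sel.end_s, clip.duration_s))
    band_low = max(comp.main_low_hz * 0.8, min(20_000.0, 0.25 * comp.main_high_hz), 100.0)
    train = detect_pulses(seg, (band_low, min(comp.main_high_hz * 1.05, clip.nyquist)))
    label = classify_call(
        m, train, near_click_train=near_click_train, lf_present=comp.lf_present, config=config
    )
    return label, m, train


def _adjacent_noise_psd(
    clip: CalibratedClip, sel: SelectionRecord, pad_s: float = 0.1, win_s: float = 0.5
) -> np.ndarray | None:
    """Background spectrum near a selection: per-bin minimum of the two
    flanking windows (the minimum is robust to a call in one of them).
    Returns None when neither side offers a full window."""
    seg_n = int(round((min(sel.end_s, clip.duration_s) - sel.begin_s) * clip.fs))
    nperseg = min(1024, seg_n)
    candidates = []
    for t0, t1 in (
        (sel.begin_s - pad_s - win_s, sel.begin_s - pad_s),
        (sel.end_s + pad_s, sel.end_s + pad_s + win_s),
    ):
        t0, t1 = max(t0, 0.0), min(t1, clip.duration_s)
        if (t1 - t0) * clip.fs < nperseg:
            continue
        seg = clip.segment(t0, t1)
        _, psd = signal.welch(
            seg.samples, fs=clip.fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend=False, scaling="density",
        )
        candidates.append(psd)
    if not candidates:
        return None
    return np.minimum.reduce(candidates)
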