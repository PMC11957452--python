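"""Sound spectral density levels (SSDL) and 1/3-octave band integration.

SSDL spectra are estimated by the Welch method with 1-s Hann windows at 50%
overlap, giving 1-Hz frequency bins, and reported in dB re 1 µPa²/Hz.  Only
the signal at and above 100 Hz is retained: in a shallow waveguide the
bottom acts as a high-pass filter, and energy below that floor is dominated
by local flow noise rather than by vessels.

Band integration uses the base-10 (IEC-style) 1/3-octave convention: band n
is centered at 10^(n/10) Hz with edge ratio 10^(1/10) per band.  All spectrum
averaging and integration happens in linear power; dB only at the interface.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .calibration import CalibratedClip

__all__ = [
    "SpectrumSSDL",
    "ThirdOctaveSpectrum",
    "welch_ssdl",
    "mean_ssdl",
    "third_octave_levels",
    "third_octave_bands",
    "extract_noise_snippets",
    "concatenate_snippets",
    "FLOOR_HZ",
]

#: Analysis floor in Hz; spectral bins below this are discarded.
FLOOR_HZ = 100.0


def db(power: np.ndarray | float) -> np.ndarray | float:
    """Linear power to dB."""
    return 10.0 * np.log10(power)


def undb(level: np.ndarray | float) -> np.ndarray | float:
    """dB to linear power."""
    return 10.0 ** (np.asarray(level, dtype=np.float64) / 10.0)


@dataclass
class SpectrumSSDL:
    """1-Hz sound spectral density levels in dB re 1 µPa²/Hz."""

    freqs: np.ndarray  # Hz, strictly increasing, 1-Hz spacing
    levels: np.ndarray  # dB re 1 µPa²/Hz
    n_avg: int = 1  # Welch snapshots averaged

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.freqs.shape != self.levels.shape:
            raise ValueError("freqs and levels must have equal shape")
        if self.freqs.size and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def power(self) -> np.ndarray:
        return undb(self.levels)


@dataclass
class ThirdOctaveSpectrum:
    """Band-integrated levels in dB re 1 µPa over base-10 1/3-octave bands."""

    centers: np.ndarray  # Hz
    lower: np.ndarray  # Hz, band lower edges
    upper: np.ndarray  # Hz, band upper edges
    levels: np.ndarray  # dB re 1 µPa
    partial: np.ndarray = field(default=None)  # bands only partly covered

    def __post_init__(self) -> None:
        for name in ("centers", "lower", "upper", "levels"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.partial is None:
            self.partial = np.zeros(self.centers.shape, dtype=bool)
        else:
            self.partial = np.asarray(self.partial, dtype=bool)
        if not (self.centers.shape == self.lower.shape == self.upper.shape == self.levels.shape):
            raise ValueError("band arrays must have equal shape")
        if np.any(self.lower >= self.upper):
            raise ValueError("band edges must be ordered")

    @property
    def power(self) -> np.ndarray:
        return undb(self.levels)


def welch_ssdl(clip: CalibratedClip, window_s: float = 1.0, floor_hz: float = FLOOR_HZ) -> SpectrumSSDL:
    """Welch SSDL of a calibrated clip: Hann windows, 50% overlap, 1-Hz bins.

    The default 1-s window at sampling rate fs gives nperseg = fs samples and
    hence 1-Hz bin spacing.  The estimate is density-scaled so band-limited
    white noise of variance sigma^2 yields sigma^2 / (fs/2) per Hz.  Bins
    below ``floor_hz`` are discarded after estimation.
    """
    nperseg = int(round(window_s * clip.fs))
    if clip.samples.size < nperseg:
        raise ValueError(
            f"clip of {clip.samples.size} samples is shorter than one "
            f"{window_s}-s analysis window ({nperseg} samples)"
        )
    freqs, psd = signal.welch(
        clip.samples,
        fs=clip.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    n_avg = 1 + (clip.samples.size - nperseg) // (nperseg - nperseg // 2)
    keep = freqs >= floor_hz
    with np.errstate(divide="ignore"):
        levels = db(psd[keep])
    return SpectrumSSDL(freqs=freqs[keep], levels=levels, n_avg=n_avg)


def mean_ssdl(spectra: Sequence[SpectrumSSDL]) -> SpectrumSSDL:
    """Average spectra per 1-Hz bin in linear power (µPa²/Hz), return dB."""
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != ref.shape or not np.allclose(s.freqs, ref):
            raise ValueError("frequency grids differ between spectra")
    power = np.mean([s.power for s in spectra], axis=0)
    return SpectrumSSDL(freqs=ref.copy(), levels=db(power), n_avg=sum(s.n_avg for s in spectra))


def third_octave_bands(f_min: float, f_max: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Base-10 1/3-octave bands fully contained in [f_min, f_max].

    Returns (centers, lower edges, upper edges) with centers 10^(n/10) Hz and
    edges center * 10^(±1/20).
    """
    edge = 10.0 ** (1.0 / 20.0)
    n_lo = int(np.ceil(10.0 * np.log10(f_min * edge)))
    n_hi = int(np.floor(10.0 * np.log10(f_max / edge)))
    if n_hi < n_lo:
        raise ValueError("frequency range does not cover a full 1/3-octave band")
    n = np.arange(n_lo, n_hi + 1)
    centers = 10.0 ** (n / 10.0)
    return centers, centers / edge, centers * edge


def third_octave_levels(spec: SpectrumSSDL) -> ThirdOctaveSpectrum:
    """Integrate 1-Hz SSDL into 1/3-octave band levels (dB re 1 µPa).

    Band level = 10 log10( sum of in-band linear density * 1 Hz ).  Bands are
    half-open [lower, upper); only bands whose edges both lie within the
    spectrum's frequency coverage are returned, so partial edge bands at the
    100-Hz floor or at Nyquist are excluded rather than under-integrated.
    """
    if spec.freqs.size < 2:
        raise ValueError("spectrum too short for band integration")
    df = float(np.median(np.diff(spec.freqs)))
    f_lo = spec.freqs[0] - df / 2.0
    f_hi = spec.freqs[-1] + df / 2.0
    centers, lower, upper = third_octave_bands(f_lo, f_hi)
    power = spec.power
    levels = np.empty(centers.size)
    for i, (lo, up) in enumerate(zip(lower, upper)):
        in_band = (spec.freqs >= lo) & (spec.freqs < up)
        levels[i] = db(power[in_band].sum() * df)
    return ThirdOctaveSpectrum(centers=centers, lower=lower, upper=upper, levels=levels)


def extract_noise_snippets(
    clip_duration_s: float,
    selections: Sequence[tuple[float, float]],
    n: int = 10,
    len_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Earliest-first call-free windows of ``len_s`` seconds.

    ``selections`` are half-open [begin, end) intervals occupied by calls.
    Returns ``n`` non-overlapping windows with no overlap with any selection.
    Raises if fewer than ``n`` call-free windows exist, naming the shortfall.
    """
    occupied = sorted((float(b), float(e)) for b, e in selections)
    windows: list[tuple[float, float]] = []
    t = 0.0
    while len(windows) < n and t + len_s <= clip_duration_s + 1e-9:
        blocker = None
        for b, e in occupied:
            if b < t + len_s and e > t:  # overlap with [t, t+len_s)
                blocker = e
                break
        if blocker is None:
            windows.append((t, t + len_s))
            t += len_s
        else:
            t = blocker
    if len(windows) < n:
        raise ValueError(
            f"only {len(windows)} call-free {len_s}-s windows available, need {n}"
        )
    return windows


def concatenate_snippets(clip: CalibratedClip, windows: Sequence[tuple[float, float]]) -> CalibratedClip:
    """Concatenate windows of a clip into one noise sample (e.g. 10 x 0.5 s -> 5 s)."""
    parts = [clip.segment(b, e).samples for b, e in windows]
    return CalibratedClip(np.concatenate(parts), clip.fs, source=clip.source)
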