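"""Vessel-noise signal excess and masking frequency.

The signal excess per 1/3-octave band is

    dSSDL_b = L_during,b - 10 log10( (P_before,b + P_after,b) / 2 )

i.e. the during-noise band level minus the linear-power mean of the flanking
before/after band levels.  Bands where dSSDL <= 0 are where the vessel is
statistically indiscernible from the ambient baseline.  The masking
frequency f_down is the center of the lowest band at which dSSDL <= 0 *and
stays* <= 0 for every higher band (a suffix condition, robust to
non-monotone excess curves); if no such band exists the vessel dominates the
full analysed bandwidth and a flag is returned instead.  A lower bound on
f_down shifts the threshold up by the hydrophone measurement uncertainty
(default 3 dB).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import ThirdOctaveSpectrum, db

__all__ = [
    "SignalExcess",
    "MaskingResult",
    "MaskingSummary",
    "signal_excess",
    "masking_frequency",
    "summarize_masking",
    "cutoff_frequency",
]


@dataclass
class SignalExcess:
    """Per-band signal excess dSSDL in dB re 1 µPa."""

    centers: np.ndarray  # Hz
    lower: np.ndarray
    upper: np.ndarray
    delta_db: np.ndarray

    def __post_init__(self) -> None:
        for name in ("centers", "lower", "upper", "delta_db"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if not (self.centers.shape == self.delta_db.shape):
            raise ValueError("one excess value per band required")


@dataclass
class MaskingResult:
    """Masking frequency of one noise event.

    ``f_down`` / ``f_down_lower`` are band-center frequencies in Hz, or None
    when the vessel noise dominates the full analysed bandwidth (``full_band``
    set accordingly).
    """

    f_down: float | None
    f_down_lower: float | None
    full_band: bool
    full_band_lower: bool
    event_id: str = ""


@dataclass
class MaskingSummary:
    """Across-event summary of defined masking frequencies."""

    mean_hz: float
    sd_hz: float
    percentiles_hz: dict[int, float]  # keys 5, 25, 50, 75, 95
    n: int
    n_full_band: int


def signal_excess(
    during: ThirdOctaveSpectrum,
    before: ThirdOctaveSpectrum,
    after: ThirdOctaveSpectrum,
) -> SignalExcess:
    """dSSDL per band: during level minus linear-power mean of before/after.

    Defined only over the bands common to all three treatments (the spectra
    must share one band grid).
    """
    for other in (before, after):
        if other.centers.shape != during.centers.shape or not np.allclose(
            other.centers, during.centers
        ):
            raise ValueError("band grids differ between treatments")
    baseline = db((before.power + after.power) / 2.0)
    return SignalExcess(
        centers=during.centers.copy(),
        lower=during.lower.copy(),
        upper=during.upper.copy(),
        delta_db=during.levels - baseline,
    )


def _suffix_crossing(delta: np.ndarray, threshold: float) -> int | None:
    """Index of the lowest band with delta <= threshold for it and all above."""
    below = delta <= threshold
    # suffix scan: last False blocks everything at or below it
    idx = None
    for i in range(delta.size - 1, -1, -1):
        if not below[i]:
            break
        idx = i
    return idx


def masking_frequency(
    excess: SignalExcess, uncertainty_db: float = 3.0, event_id: str = ""
) -> MaskingResult:
    """Estimate f_down (and its uncertainty-shifted lower bound) from dSSDL.

    f_down is the center frequency of the lowest band at which dSSDL <= 0 and
    remains <= 0 for all higher bands; f_down_lower applies the same rule at
    threshold +uncertainty_db.  When no band satisfies the rule the vessel
    noise dominates the full bandwidth and the corresponding flag is set.
    """
    if excess.centers.size < 2:
        raise ValueError("need at least two bands to locate a crossing")
    i0 = _suffix_crossing(excess.delta_db, 0.0)
    i1 = _suffix_crossing(excess.delta_db, float(uncertainty_db))
    f_down = None if i0 is None else float(excess.centers[i0])
    f_low = None if i1 is None else float(excess.centers[i1])
    return MaskingResult(
        f_down=f_down,
        f_down_lower=f_low,
        full_band=i0 is None,
        full_band_lower=i1 is None,
        event_id=event_id,
    )


def summarize_masking(results: list[MaskingResult]) -> MaskingSummary:
    """Mean, 1-sigma s.d. and 5/25/50/75/95 percentiles of defined f_down.

    Full-band events carry no finite masking frequency; they are excluded
    from the statistics and reported via ``n_full_band``, never imputed.
    """
    values = np.array([r.f_down for r in results if not r.full_band], dtype=np.float64)
    n_full = sum(r.full_band for r in results)
    if values.size == 0:
        raise ValueError("all events are full-band; no masking frequencies to summarize")
    pcts = {p: float(np.percentile(values, p)) for p in (5, 25, 50, 75, 95)}
    return MaskingSummary(
        mean_hz=float(values.mean()),
        sd_hz=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        percentiles_hz=pcts,
        n=int(values.size),
        n_full_band=int(n_full),
    )


def cutoff_frequency(z: float, cw: float, cb: float) -> float:
    """Shallow-water waveguide cutoff frequency f0 in Hz.

    Below f0 sound cannot propagate in a waveguide of depth ``z`` (m) over a
    faster bottom; quarter-wavelength form

        f0 = cw / (4 z sqrt(1 - (cw/cb)^2))

    with ``cw``/``cb`` the sound speeds (m/s) in water and in the sub-bottom.
    Undefined when cw >= cb (no critical angle, no cutoff).
    """
    if z <= 0:
        raise ValueError("depth must be positive")
    if not 0 < cw < cb:
        raise ValueError("requires 0 < cw < cb for a cutoff to exist")
    ratio = cw / cb
    return cw / (4.0 * z * np.sqrt(1.0 - ratio * ratio))
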