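"""Pipeline configuration and event manifests.

Configuration is YAML; :func:`load_config` validates field-by-field and
raises with the offending key.  All randomness downstream derives from the
single ``seed`` through ``numpy.random.SeedSequence`` spawning, so a config
plus seed pins every byte of the outputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationSpec, ICLISTEN_HF, SOUNDTRAP_HF300

__all__ = ["PipelineConfig", "EventManifest", "load_config", "load_calibration", "validate_manifest"]

#: per-minute call rates by type and treatment in the default study design:
#: contact calls and other calls drop during vessel noise, ultrasonic HFBP
#: calls hold their rate
DEFAULT_RATES_PER_MIN = {
    "CC": {"before": 2.0, "during": 0.6, "after": 1.6},
    "HFBP": {"before": 3.0, "during": 3.0, "after": 3.0},
    "OTHER": {"before": 2.5, "during": 0.8, "after": 2.2},
}

MAX_TREATMENT_S = 300.0
MIN_EVENT_SEPARATION_S = 600.0


@dataclass
class PipelineConfig:
    """Everything the end-to-end experiment needs."""

    seed: int = 0
    n_events: int = 12
    sampling_rate_hz: int = 288_000
    treatment_duration_s: float = 60.0
    vessel_rolloffs_hz: list = field(default_factory=lambda: [30_000.0, 50_000.0, 80_000.0])
    rates_per_min: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATES_PER_MIN.items()})
    nb_dispersion: float = 2.0
    event_sd: float = 0.8
    ambient_level_db_at_1khz: float = 60.0
    ambient_slope_db_per_decade: float = 5.0
    uncertainty_db: float = 3.0
    classifier: dict = field(default_factory=dict)
    write_audio: bool = True

    def validate(self) -> None:
        if self.n_events < 2:
            raise ValueError("n_events must be at least 2")
        if self.sampling_rate_hz not in (256_000, 288_000):
            raise ValueError("sampling_rate_hz must be 256000 or 288000")
        if not 0 < self.treatment_duration_s <= MAX_TREATMENT_S:
            raise ValueError(f"treatment_duration_s must be in (0, {MAX_TREATMENT_S}]")
        if not self.vessel_rolloffs_hz:
            raise ValueError("vessel_rolloffs_hz must not be empty")
        nyq = self.sampling_rate_hz / 2
        for r in self.vessel_rolloffs_hz:
            if not 100.0 < r <= nyq:
                raise ValueError(f"vessel rolloff {r} outside (100, Nyquist {nyq}]")
        for ct, by_treat in self.rates_per_min.items():
            if ct not in ("CC", "HFBP", "OTHER"):
                raise ValueError(f"unknown call type {ct!r} in rates_per_min")
            for tr, rate in by_treat.items():
                if tr not in ("before", "during", "after"):
                    raise ValueError(f"unknown treatment {tr!r} in rates_per_min")
                if rate < 0:
                    raise ValueError("rates must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.uncertainty_db < 0:
            raise ValueError("uncertainty_db must be non-negative")

    @property
    def calibration(self) -> CalibrationSpec:
        return SOUNDTRAP_HF300 if self.sampling_rate_hz == 288_000 else ICLISTEN_HF

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; ``seed`` overrides the file."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    return cfg


def load_calibration(path: str | Path) -> CalibrationSpec:
    """Load a calibration YAML (sensitivity_db, fs, bit_depth, peak_volts, gain_db)."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    return CalibrationSpec(**raw)


@dataclass
class EventManifest:
    """Locations and timing of one recorded noise event."""

    event_id: str
    audio_paths: dict  # treatment -> path
    treatment_durations_s: dict  # treatment -> seconds
    start_time_s: float  # event start on a common clock, for separation checks


def validate_manifest(manifests: list[EventManifest]) -> list[str]:
    """Check the experimental-design constraints; return violations.

    Treatments must not exceed 5 minutes, consecutive events must be more
    than 10 minutes apart, and the referenced audio must exist.  An empty
    list means the manifest is valid.
    """
    violations: list[str] = []
    for m in manifests:
        for tr in ("before", "during", "after"):
            d = m.treatment_durations_s.get(tr)
            if d is None:
                violations.append(f"event {m.event_id}: missing duration for {tr!r}")
            elif d > MAX_TREATMENT_S:
                violations.append(
                    f"event {m.event_id}: {tr} treatment lasts {d:.0f} s "
                    f"(limit {MAX_TREATMENT_S:.0f} s)"
                )
            p = m.audio_paths.get(tr)
            if p is None:
                violations.append(f"event {m.event_id}: missing audio path for {tr!r}")
            elif not Path(p).exists():
                violations.append(f"event {m.event_id}: audio file not found: {p}")
    ordered = sorted(manifests, key=lambda m: m.start_time_s)
    for a, b in zip(ordered, ordered[1:]):
        span = sum(a.treatment_durations_s.get(t, 0.0) for t in ("before", "during", "after"))
        gap = b.start_time_s - (a.start_time_s + span)
        if gap < MIN_EVENT_SEPARATION_S:
            violations.append(
                f"events {a.event_id} and {b.event_id} separated by {gap:.0f} s "
                f"(minimum {MIN_EVENT_SEPARATION_S:.0f} s)"
            )
    return violations
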