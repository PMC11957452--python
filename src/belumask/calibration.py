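"""Hydrophone calibration: digital samples to absolute pressure in µPa.

An autonomous recorder is characterised by its end-to-end sensitivity
S (dB re 1 V/µPa), the ADC full-scale voltage, any additional gain, bit
depth and sampling rate.  A digital sample d in [-1, 1] maps linearly to

    pressure [µPa] = d * peak_volts * 10^(-(S + gain) / 20)

which is invertible, so synthesized pressure series can be round-tripped
through WAV files losslessly apart from quantisation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationSpec",
    "CalibratedClip",
    "SOUNDTRAP_HF300",
    "ICLISTEN_HF",
    "wav_to_pressure",
    "pressure_to_digital",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """End-to-end calibration of a hydrophone/recorder chain."""

    sensitivity_db: float  # dB re 1 V/µPa (negative for hydrophones)
    fs: int  # Hz
    bit_depth: int = 16
    peak_volts: float = 1.0  # ADC full-scale voltage
    gain_db: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.bit_depth not in (16, 24):
            raise ValueError("bit depth must be 16 or 24")
        if not np.isfinite(self.sensitivity_db):
            raise ValueError("sensitivity must be finite")
        if self.peak_volts <= 0:
            raise ValueError("peak voltage must be positive")

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0

    @property
    def digital_to_upa(self) -> float:
        """Pressure in µPa corresponding to digital full scale (d = 1)."""
        return self.peak_volts * 10.0 ** (-(self.sensitivity_db + self.gain_db) / 20.0)


#: SoundTrap HF300 deployment configuration (288 kHz, 16-bit).
SOUNDTRAP_HF300 = CalibrationSpec(
    sensitivity_db=-172.7, fs=288_000, bit_depth=16, name="SoundTrap HF300"
)

#: icListen HF deployment configuration (256 kHz, 24-bit).
ICLISTEN_HF = CalibrationSpec(
    sensitivity_db=-170.0, fs=256_000, bit_depth=24, name="icListen HF"
)


@dataclass
class CalibratedClip:
    """Pressure time series in µPa with its sampling rate and provenance."""

    samples: np.ndarray  # µPa
    fs: int
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("clip must be single-channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("clip contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0

    def segment(self, begin_s: float, end_s: float) -> "CalibratedClip":
        """Extract the half-open interval [begin_s, end_s) as a new clip."""
        i0 = max(0, int(round(begin_s * self.fs)))
        i1 = min(self.samples.size, int(round(end_s * self.fs)))
        if i1 <= i0:
            raise ValueError(f"empty segment [{begin_s}, {end_s})")
        return CalibratedClip(self.samples[i0:i1], self.fs, source=self.source)


def wav_to_pressure(digital: np.ndarray, cal: CalibrationSpec, source: str = "") -> CalibratedClip:
    """Convert digital samples in [-1, 1] to calibrated pressure in µPa."""
    digital = np.asarray(digital, dtype=np.float64)
    if digital.size and np.nanmax(np.abs(digital)) > 1.0 + 1e-9:
        raise ValueError("digital samples must lie within [-1, 1]")
    return CalibratedClip(digital * cal.digital_to_upa, cal.fs, source=source or cal.name)


def pressure_to_digital(clip: CalibratedClip, cal: CalibrationSpec) -> np.ndarray:
    """Inverse of :func:`wav_to_pressure` (no clipping applied)."""
    if clip.fs != cal.fs:
        raise ValueError("clip sampling rate does not match calibration")
    return clip.samples / cal.digital_to_upa
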