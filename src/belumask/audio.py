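"""Minimal PCM WAV read/write for 16- and 24-bit mono recordings.

Hydrophone recorders in this workflow (SoundTrap HF300, icListen HF) write
single-channel PCM WAV at 16 or 24 bits.  Samples are exchanged with the rest
of the package as float64 in [-1, 1], where digital full scale corresponds to
the ADC peak voltage of the calibration spec.
"""
from __future__ import annotations

import wave
from pathlib import Path

import numpy as np

__all__ = ["read_wav", "write_wav"]


def write_wav(path: str | Path, samples: np.ndarray, fs: int, bit_depth: int = 16) -> None:
    """Write float samples in [-1, 1] as mono PCM WAV.

    Values outside [-1, 1] are clipped (the synthesis layer warns before this
    can happen).  Full scale maps to the most negative/positive integer code.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise ValueError("only mono audio is supported")
    if bit_depth not in (16, 24):
        raise ValueError(f"unsupported bit depth: {bit_depth}")
    clipped = np.clip(samples, -1.0, 1.0)
    full_scale = 2 ** (bit_depth - 1) - 1
    ints = np.round(clipped * full_scale).astype(np.int32)
    if bit_depth == 16:
        raw = ints.astype("<i2").tobytes()
    else:
        # 24-bit: little-endian, low three bytes of the int32 representation
        b = ints.astype("<i4").view(np.uint8).reshape(-1, 4)
        raw = b[:, :3].tobytes()
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(bit_depth // 8)
        w.setframerate(fs)
        w.writeframes(raw)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read mono PCM WAV, returning (float samples in [-1, 1], sampling rate)."""
    with wave.open(str(path), "rb") as w:
        if w.getnchannels() != 1:
            raise ValueError("only mono audio is supported")
        width = w.getsampwidth()
        fs = w.getframerate()
        raw = w.readframes(w.getnframes())
    if width == 2:
        ints = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        full_scale = 2**15 - 1
    elif width == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        padded = np.zeros((b.shape[0], 4), dtype=np.uint8)
        padded[:, 1:] = b
        ints = padded.view("<i4").ravel() >> 8  # sign-extend via arithmetic shift
        full_scale = 2**23 - 1
    else:
        raise ValueError(f"unsupported sample width: {width} bytes")
    return ints.astype(np.float64) / full_scale, fs
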