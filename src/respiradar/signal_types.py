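"""Core signal containers shared across the pipeline.

A :class:`RespWaveform` is a uniformly sampled chest-displacement series in
millimetres — the central object every stage consumes or produces. A
:class:`RadarSignal` holds the quadrature (I/Q) pair a continuous-wave radar
front end would deliver, whose phase encodes displacement as ``4*pi*d/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Carrier wavelength of a 24-GHz continuous-wave radar, in mm.
DEFAULT_WAVELENGTH_MM = 12.5


@dataclass
class RespWaveform:
    """Uniformly sampled chest displacement.

    Parameters
    ----------
    samples : ndarray
        Displacement in mm.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Start time in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def copy(self) -> "RespWaveform":
        return RespWaveform(self.samples.copy(), self.fs, self.t0)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV ``time_s,displacement_mm``."""
        df = pd.DataFrame(
            {"time_s": self.times, "displacement_mm": self.samples}
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RespWaveform":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("waveform CSV needs at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
            raise ValueError("waveform CSV is not uniformly sampled")
        return cls(df["displacement_mm"].to_numpy(float), fs=1.0 / dt[0], t0=t[0])


@dataclass
class RadarSignal:
    """Quadrature baseband pair from a CW radar (unitless voltages)."""

    i_samples: np.ndarray
    q_samples: np.ndarray
    fs: float
    wavelength_mm: float = DEFAULT_WAVELENGTH_MM

    def __post_init__(self) -> None:
        self.i_samples = np.asarray(self.i_samples, dtype=float)
        self.q_samples = np.asarray(self.q_samples, dtype=float)
        if self.i_samples.shape != self.q_samples.shape:
            raise ValueError("i and q must have the same length")
        if self.wavelength_mm <= 0:
            raise ValueError("wavelength_mm must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def to_csv(self, path: str | Path) -> None:
        """Write as three-column CSV ``time_s,i,q``."""
        t = np.arange(len(self.i_samples)) / self.fs
        pd.DataFrame({"time_s": t, "i": self.i_samples, "q": self.q_samples}).to_csv(
            path, index=False, float_format="%.8f"
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, wavelength_mm: float = DEFAULT_WAVELENGTH_MM
    ) -> "RadarSignal":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / (t[1] - t[0])
        return cls(df["i"].to_numpy(float), df["q"].to_numpy(float), fs, wavelength_mm)


@dataclass
class Epoch:
    """One fixed 30-s scoring window of a night recording."""

    index: int
    samples: np.ndarray = field(repr=False)
    fs: float
    stage_label: str = "unknown"  # wake | sleep | off_bed | unknown

    duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("index must be >= 0")
        n_expected = int(round(self.duration_s * self.fs))
        if len(self.samples) != n_expected:
            raise ValueError(
                f"epoch must hold exactly {self.duration_s} s of samples "
                f"({n_expected}), got {len(self.samples)}"
            )

    @property
    def start_s(self) -> float:
        return self.index * self.duration_s
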