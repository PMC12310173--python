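"""CW-radar quadrature demodulation, respiration-band filtering, epoching.

Arctangent demodulation with phase unwrapping recovers displacement from the
I/Q pair: d(t) = lambda * unwrap(atan2(Q - mean(Q), I - mean(I))) / (4*pi).
Unwrapping matters because chest excursions of up to 12 mm approach half the
12.5-mm carrier wavelength, where a small-angle (linear) demodulator fails.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signal_types import Epoch, RadarSignal, RespWaveform

EPOCH_S = 30.0


class DegenerateSignalError(ValueError):
    """Raised when the I/Q pair carries no usable phase information."""


def _circle_center(i: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """Algebraic (Kasa) least-squares circle fit of the I/Q trajectory.

    Solves x^2 + y^2 = 2ax + 2by + c in the least-squares sense; exact for
    noise-free points on a circular arc, which is what DC-offset
    compensation of a CW radar constellation needs.
    """
    A = np.column_stack([2 * i, 2 * q, np.ones_like(i)])
    rhs = i**2 + q**2
    try:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return float(i.mean()), float(q.mean())
    return float(sol[0]), float(sol[1])


def demodulate(r: RadarSignal) -> RespWaveform:
    """Arctangent-demodulate an I/Q pair into displacement (mm), mean-removed.

    The constellation's DC offset (circle center) is estimated by a
    least-squares circle fit; the residual phase is unwrapped so excursions
    beyond half a wavelength stay continuous.
    """
    if np.max(np.hypot(r.i_samples, r.q_samples)) < 1e-12:
        raise DegenerateSignalError("all-zero I/Q: phase angle undefined")
    # no phase motion at all: a still target, zero displacement
    if np.ptp(r.i_samples) < 1e-12 and np.ptp(r.q_samples) < 1e-12:
        return RespWaveform(np.zeros_like(r.i_samples), r.fs)
    a, b = _circle_center(r.i_samples, r.q_samples)
    i = r.i_samples - a
    q = r.q_samples - b
    amp = np.hypot(i, q)
    if np.max(amp) < 1e-12:
        raise DegenerateSignalError("degenerate I/Q constellation")
    phi = np.unwrap(np.arctan2(q, i))
    d = r.wavelength_mm * phi / (4.0 * np.pi)
    d -= d.mean()
    return RespWaveform(d, r.fs)


def preprocess(
    w: RespWaveform, band_hz: tuple[float, float] = (0.1, 0.8)
) -> RespWaveform:
    """Zero-phase 4th-order Butterworth band-pass; output is zero-mean.

    The default 0.1-0.8 Hz band covers 6-48 breaths/min while rejecting
    baseline drift and cardiac/noise components.
    """
    lo, hi = band_hz
    nyq = w.fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} must lie strictly inside (0, {nyq})")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=w.fs, output="sos")
    y = sps.sosfiltfilt(sos, w.samples)
    y = y - y.mean()
    return RespWaveform(y, w.fs, w.t0)


def split_epochs(w: RespWaveform) -> list:
    """Cut a waveform into consecutive non-overlapping 30-s epochs.

    A trailing partial epoch is dropped, following fixed-epoch sleep-scoring
    convention. Requires fs * 30 to be integral.
    """
    n_per = EPOCH_S * w.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("fs * 30 s must be an integral number of samples")
    n_per = int(round(n_per))
    n_epochs = len(w.samples) // n_per
    return [
        Epoch(index=k, samples=w.samples[k * n_per : (k + 1) * n_per], fs=w.fs)
        for k in range(n_epochs)
    ]
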