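"""Breath-by-breath feature extraction.

The named features are the ones a sleep technologist would read off a
respiratory effort trace: peak-to-peak and valley-to-valley breath intervals,
per-breath peak amplitudes, their regularity quantified by sample entropy,
and the envelope min/max ratio of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_types import Epoch, RespWaveform

#: Column order of the feature matrix (stable public schema).
FEATURE_NAMES = (
    "pp_interval_mean_s",
    "pp_interval_sd_s",
    "vv_interval_mean_s",
    "vv_interval_sd_s",
    "amplitude_mean_mm",
    "amplitude_sd_mm",
    "sampen_intervals",
    "sampen_amplitudes",
    "envelope_min_max_ratio",
)


@dataclass
class Extrema:
    """Alternating breath peaks and valleys of a displacement trace."""

    peak_times_s: np.ndarray
    peak_values_mm: np.ndarray
    valley_times_s: np.ndarray
    valley_values_mm: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_s)


@dataclass
class BreathMetrics:
    """Interval and amplitude series derived from :class:`Extrema`."""

    pp_intervals_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    vv_intervals_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes_mm: np.ndarray = field(default_factory=lambda: np.empty(0))


def _enforce_alternation(
    times: np.ndarray, values: np.ndarray, kinds: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Of consecutive same-type extrema keep the more extreme one.

    kinds: +1 for peaks, -1 for valleys. Input sorted by time.
    """
    keep_t, keep_v, keep_k = [], [], []
    for t, v, k in zip(times, values, kinds):
        if keep_k and keep_k[-1] == k:
            better = v > keep_v[-1] if k == 1 else v < keep_v[-1]
            if better:
                keep_t[-1], keep_v[-1] = t, v
        else:
            keep_t.append(t)
            keep_v.append(v)
            keep_k.append(k)
    return np.array(keep_t), np.array(keep_v), np.array(keep_k)


def find_extrema(
    w: RespWaveform,
    min_prominence_mm: float = 0.3,
    min_separation_s: float = 1.5,
) -> Extrema:
    """Locate breath peaks and valleys with prominence/separation gating.

    Alternation is enforced afterwards: of two same-type neighbours the more
    extreme survives. Defaults sit below the smallest physiological breath
    (1 mm displacement) but above sensor noise, and cap the detectable rate
    at 40 breaths/min.
    """
    distance = max(1, int(round(min_separation_s * w.fs)))
    pk, _ = sps.find_peaks(w.samples, prominence=min_prominence_mm, distance=distance)
    vl, _ = sps.find_peaks(-w.samples, prominence=min_prominence_mm, distance=distance)
    if len(pk) == 0 and len(vl) == 0:
        z = np.empty(0)
        return Extrema(z, z, z.copy(), z.copy())
    idx = np.concatenate([pk, vl])
    kinds = np.concatenate([np.ones(len(pk), int), -np.ones(len(vl), int)])
    order = np.argsort(idx, kind="stable")
    times = w.t0 + idx[order] / w.fs
    values = w.samples[idx[order]]
    t, v, k = _enforce_alternation(times, values, kinds[order])
    return Extrema(
        peak_times_s=t[k == 1],
        peak_values_mm=v[k == 1],
        valley_times_s=t[k == -1],
        valley_values_mm=v[k == -1],
    )


def breath_metrics(e: Extrema) -> BreathMetrics:
    """Successive-difference intervals and flanking-valley breath amplitudes.

    Per-breath amplitude = peak value minus the mean of its flanking valley
    values (robust to residual baseline drift). Fewer than 2 peaks yields
    empty series, not an error.
    """
    out = BreathMetrics()
    if e.n_peaks >= 2:
        out.pp_intervals_s = np.diff(e.peak_times_s)
    if len(e.valley_times_s) >= 2:
        out.vv_intervals_s = np.diff(e.valley_times_s)
    amps = []
    for t, v in zip(e.peak_times_s, e.peak_values_mm):
        before = e.valley_values_mm[e.valley_times_s < t]
        after = e.valley_values_mm[e.valley_times_s > t]
        flanking = [s[i] for s, i in ((before, -1), (after, 0)) if len(s)]
        if flanking:
            amps.append(v - float(np.mean(flanking)))
    out.amplitudes_mm = np.asarray(amps, dtype=float)
    return out


def sample_entropy(x, m: int = 2, r_fraction: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with r = r_fraction * sd(x).

    Counts ordered template pairs (i < j) under the Chebyshev distance with
    matches defined as distance <= r, self-matches excluded. Length-m
    templates start at 0..n-m, length-(m+1) templates at 0..n-m-1. Returns
    -ln(A/B); conventions for degenerate inputs: 0.0 for zero-variance or
    too-short series or when no length-m pairs match; ln(B) (the counting
    ceiling) when B > 0 but no length-(m+1) pair matches, keeping the value
    finite.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return 0.0
    sd = float(np.std(x))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):  # numerically constant
        return 0.0
    r = r_fraction * sd

    def _count(mm: int) -> int:
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distances between all ordered template pairs
        diff = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
        iu = np.triu_indices(len(templates), k=1)
        return int(np.count_nonzero(diff[iu] <= r))

    b = _count(m)
    if b == 0:
        return 0.0
    a = _count(m + 1)
    if a == 0:
        return float(np.log(b))
    return float(-np.log(a / b))


def epoch_feature_vector(ep: Epoch) -> np.ndarray:
    """Assemble the 9-feature vector of one 30-s epoch (see FEATURE_NAMES).

    Epochs with fewer than two detectable breaths produce the all-zero
    sentinel vector, so classifier input is total over the night.
    """
    w = RespWaveform(np.asarray(ep.samples, float), ep.fs)
    ex = find_extrema(w)
    bm = breath_metrics(ex)
    if len(bm.pp_intervals_s) == 0 and len(bm.amplitudes_mm) == 0:
        return np.zeros(len(FEATURE_NAMES))

    analytic = sps.hilbert(w.samples - w.samples.mean())
    env = np.abs(analytic)
    # trim filter edge effects before the min/max ratio
    k = max(1, int(w.fs))
    env_core = env[k:-k] if len(env) > 2 * k else env
    env_ratio = float(env_core.min() / env_core.max()) if env_core.max() > 0 else 0.0

    def _ms(v: np.ndarray) -> tuple[float, float]:
        if len(v) == 0:
            return 0.0, 0.0
        return float(np.mean(v)), float(np.std(v))

    pp_m, pp_s = _ms(bm.pp_intervals_s)
    vv_m, vv_s = _ms(bm.vv_intervals_s)
    am_m, am_s = _ms(bm.amplitudes_mm)
    return np.array(
        [
            pp_m,
            pp_s,
            vv_m,
            vv_s,
            am_m,
            am_s,
            sample_entropy(bm.pp_intervals_s),
            sample_entropy(bm.amplitudes_mm),
            env_ratio,
        ]
    )


def feature_matrix(epochs) -> np.ndarray:
    """Stack epoch feature vectors into an (n_epochs, n_features) matrix."""
    if not epochs:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([epoch_feature_vector(ep) for ep in epochs])
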