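"""Synthetic respiration, event and radar-signal generator.

Emulates what a 24-GHz continuous-wave radar pointed at a sleeping chest
would see: quasi-periodic chest displacement of 1-12 mm at 12-20 breaths/min,
interrupted by apneas/hypopneas (>=10 s amplitude reductions) and by
periodic-breathing episodes (>=3 alternating apneic and crescendo-decrescendo
ventilatory phases), phase-modulated onto a carrier of ~12.5 mm wavelength.

Every generator is deterministic under a fixed seed and returns its injected
ground truth verbatim, so downstream detectors can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import APNEA, HYPOPNEA, MIN_EVENT_DURATION_S, PBEpisode, RespiratoryEvent
from .signal_types import DEFAULT_WAVELENGTH_MM, RadarSignal, RespWaveform

#: Physiological chest-displacement ceiling (mm) for breathing motion.
MAX_DISPLACEMENT_MM = 12.0

#: Taper length (s) applied at event edges to avoid step discontinuities.
EVENT_TAPER_S = 2.0

#: Peak ventilatory-phase envelope gain relative to baseline breathing
#: (hyperventilation overshoot of the crescendo-decrescendo pattern).
PB_HYPERPNEA_GAIN = 1.3

#: Residual envelope fraction during the apneic phase of a PB cycle.
PB_APNEIC_RESIDUAL = 0.02


@dataclass(frozen=True)
class BreathProfile:
    """Statistical description of one subject's resting breathing.

    rate_jitter / amplitude_jitter are coefficients of variation of the
    per-breath period and peak displacement.
    """

    rate_bpm: float = 15.0
    amplitude_mm: float = 5.0
    rate_jitter: float = 0.05
    amplitude_jitter: float = 0.10

    def __post_init__(self) -> None:
        if not (4.0 < self.rate_bpm < 60.0):
            raise ValueError("rate_bpm must lie in (4, 60)")
        # amplitude 0 is a degenerate test-only case (flat line)
        if not (0.0 <= self.amplitude_mm <= MAX_DISPLACEMENT_MM):
            raise ValueError(f"amplitude_mm must lie in (0, {MAX_DISPLACEMENT_MM}]")
        if self.rate_jitter < 0 or self.amplitude_jitter < 0:
            raise ValueError("jitters must be >= 0")


@dataclass(frozen=True)
class EventSpec:
    """Requested apnea/hypopnea injection."""

    kind: str
    onset_s: float
    duration_s: float
    depth_fraction: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in (APNEA, HYPOPNEA):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_s < MIN_EVENT_DURATION_S:
            raise ValueError("event duration must be >= 10 s")
        if self.depth_fraction is None:
            object.__setattr__(
                self, "depth_fraction", 0.02 if self.kind == APNEA else 0.4
            )
        lo, hi = (0.0, 0.05) if self.kind == APNEA else (0.1, 0.7)
        if not (lo <= self.depth_fraction <= hi):
            raise ValueError(
                f"{self.kind} depth_fraction must lie in [{lo}, {hi}]"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class PBSpec:
    """Requested periodic-breathing episode injection."""

    n_cycles: int = 5
    cycle_length_s: float = 40.0
    apneic_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValueError("periodic breathing requires >= 3 cycles")
        if not (0.0 < self.apneic_fraction < 1.0):
            raise ValueError("apneic_fraction must lie in (0, 1)")
        if self.apneic_duration_s < MIN_EVENT_DURATION_S:
            raise ValueError(
                "apneic phase must last >= 10 s "
                f"(got {self.apneic_duration_s:.1f} s)"
            )

    @property
    def apneic_duration_s(self) -> float:
        return self.apneic_fraction * self.cycle_length_s

    @property
    def ventilatory_duration_s(self) -> float:
        return self.cycle_length_s - self.apneic_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_length_s


# ---------------------------------------------------------------------------
# breathing


def simulate_respiration(
    profile: BreathProfile,
    duration_s: float,
    fs: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> RespWaveform:
    """Concatenated raised-cosine breath cycles.

    Each breath k occupies a period T_k drawn around 60/rate_bpm and rises
    from 0 to a peak A_k and back: d(t) = A_k * (1 - cos(2*pi*u)) / 2 with
    u the within-breath phase. Periods and peaks jitter independently per
    breath with the profile's coefficients of variation.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 4.0:
        raise ValueError("fs must be >= 4 Hz")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(round(duration_s * fs))
    if profile.amplitude_mm == 0.0:
        return RespWaveform(np.zeros(n), fs)

    mean_period = 60.0 / profile.rate_bpm
    # draw more breaths than can possibly fit
    n_breaths = int(math.ceil(duration_s / mean_period * 2)) + 8
    periods = mean_period * (1.0 + profile.rate_jitter * rng.standard_normal(n_breaths))
    periods = np.clip(periods, 0.4 * mean_period, 2.5 * mean_period)
    amps = profile.amplitude_mm * (
        1.0 + profile.amplitude_jitter * rng.standard_normal(n_breaths)
    )
    amps = np.clip(amps, 0.05 * profile.amplitude_mm, MAX_DISPLACEMENT_MM)

    starts = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) / fs
    idx = np.searchsorted(starts, t, side="right") - 1
    u = (t - starts[idx]) / periods[idx]
    d = amps[idx] * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return RespWaveform(d, fs)


def _cosine_gate(
    t: np.ndarray, onset: float, end: float, depth: float, taper_s: float = EVENT_TAPER_S
) -> np.ndarray:
    """Multiplicative envelope gate: 1 outside [onset, end], `depth` inside,
    with cosine tapers of `taper_s` just inside each edge."""
    g = np.ones_like(t)
    taper = min(taper_s, (end - onset) / 2.0)
    inside = (t >= onset) & (t < end)
    g[inside] = depth
    fall = (t >= onset) & (t < onset + taper)
    u = (t[fall] - onset) / taper
    g[fall] = depth + (1.0 - depth) * 0.5 * (1.0 + np.cos(np.pi * u))
    rise = (t >= end - taper) & (t < end)
    u = (t[rise] - (end - taper)) / taper
    g[rise] = depth + (1.0 - depth) * 0.5 * (1.0 - np.cos(np.pi * u))
    return g


def inject_events(
    w: RespWaveform,
    events: Sequence[EventSpec],
    seed: int | np.random.Generator = 0,
) -> tuple[RespWaveform, list]:
    """Scale the breath envelope down to ``depth_fraction`` inside each event.

    Events must be non-overlapping and inside the waveform span. Returns the
    modified waveform and the ground-truth event list verbatim.
    """
    if not events:
        return w.copy(), []
    ordered = sorted(events, key=lambda e: e.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_s > b.onset_s:
            raise ValueError(
                f"events overlap: [{a.onset_s}, {a.end_s}] and "
                f"[{b.onset_s}, {b.end_s}]"
            )
    if ordered[0].onset_s < w.t0 or ordered[-1].end_s > w.t0 + w.duration_s:
        raise ValueError("events must lie inside the waveform span")

    t = w.times
    d = w.samples.copy()
    truth = []
    for ev in ordered:
        d *= _cosine_gate(t, ev.onset_s, ev.end_s, ev.depth_fraction)
        truth.append(
            RespiratoryEvent(kind=ev.kind, onset_s=ev.onset_s, duration_s=ev.duration_s)
        )
    return RespWaveform(d, w.fs, w.t0), truth


def _pb_gate(t: np.ndarray, spec: PBSpec, onset_s: float) -> np.ndarray:
    """Multiplicative envelope for one PB episode starting at ``onset_s``.

    Each cycle: an apneic phase at residual envelope, then a ventilatory
    half-sine-squared hump peaking at PB_HYPERPNEA_GAIN mid-phase. The gate
    tapers in from 1 at episode onset and ramps back to 1 after the last
    ventilatory phase decays.
    """
    g = np.ones_like(t)
    ta = spec.apneic_duration_s
    tv = spec.ventilatory_duration_s
    for k in range(spec.n_cycles):
        c0 = onset_s + k * spec.cycle_length_s
        # apneic phase
        a_mask = (t >= c0) & (t < c0 + ta)
        g[a_mask] = PB_APNEIC_RESIDUAL
        if k == 0:  # taper in from normal breathing
            taper = min(EVENT_TAPER_S, ta / 2)
            m = (t >= c0) & (t < c0 + taper)
            u = (t[m] - c0) / taper
            g[m] = PB_APNEIC_RESIDUAL + (1 - PB_APNEIC_RESIDUAL) * 0.5 * (
                1 + np.cos(np.pi * u)
            )
        # ventilatory hump
        v0 = c0 + ta
        v_mask = (t >= v0) & (t < v0 + tv)
        u = (t[v_mask] - v0) / tv
        hump = PB_HYPERPNEA_GAIN * np.sin(np.pi * u) ** 2
        if k == spec.n_cycles - 1:
            # final ventilatory phase settles back to normal breathing
            # instead of decaying to zero (episode termination)
            hump = np.maximum(hump, u)
        g[v_mask] = np.maximum(PB_APNEIC_RESIDUAL, hump)
    return g


def inject_periodic_breathing(
    w: RespWaveform,
    spec: PBSpec,
    onset_s: float,
    seed: int | np.random.Generator = 0,
) -> tuple[RespWaveform, PBEpisode]:
    """Inject one crescendo-decrescendo periodic-breathing episode.

    Returns the modified waveform and the truth episode whose cycles record
    the paired apneic/ventilatory phase durations.
    """
    end = onset_s + spec.total_duration_s
    if onset_s < w.t0 or end > w.t0 + w.duration_s:
        raise ValueError("episode must lie inside the waveform")
    g = _pb_gate(w.times, spec, onset_s)
    truth = PBEpisode(
        onset_s=onset_s,
        cycles=[(spec.apneic_duration_s, spec.ventilatory_duration_s)] * spec.n_cycles,
    )
    return RespWaveform(w.samples * g, w.fs, w.t0), truth


# ---------------------------------------------------------------------------
# radar


def modulate_radar(
    w: RespWaveform,
    wavelength_mm: float = DEFAULT_WAVELENGTH_MM,
    noise_sd: float = 0.02,
    drift_amp: float = 0.05,
    seed: int | np.random.Generator = 0,
    phi0: float = 0.7,
) -> RadarSignal:
    """Phase-modulate displacement onto a CW carrier's quadrature pair.

    phi(t) = 4*pi*d(t)/lambda + phi0; I = cos(phi) + drift + noise and
    Q = sin(phi) + drift + noise, with independent white Gaussian noise per
    channel and a slow (<0.05 Hz) sinusoidal additive drift emulating
    baseline wander of the RF front end.
    """
    if wavelength_mm <= 0:
        raise ValueError("wavelength_mm must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phi = 4.0 * np.pi * w.samples / wavelength_mm + phi0
    t = w.times
    i = np.cos(phi)
    q = np.sin(phi)
    if drift_amp > 0:
        f_drift = 0.02  # Hz
        i = i + drift_amp * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        q = q + drift_amp * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        i = i + noise_sd * rng.standard_normal(len(t))
        q = q + noise_sd * rng.standard_normal(len(t))
    return RadarSignal(i, q, w.fs, wavelength_mm)


# ---------------------------------------------------------------------------
# whole nights


@dataclass
class NightSpec:
    """Everything needed to synthesize one night recording.

    Wake and off-bed blocks are aligned to the 30-s epoch grid, matching how
    sleep is scored. Events are placed only inside sleep regions, spaced to
    realize ``event_rate_per_h`` over the total sleep time.
    """

    duration_h: float = 8.0
    fs: float = 20.0
    profile: BreathProfile = field(default_factory=BreathProfile)
    event_rate_per_h: float = 0.0
    apnea_fraction: float = 0.6  # share of events injected as apneas
    pb_cycle_length_s: float = 0.0  # 0 => no periodic breathing
    pb_n_episodes: int = 4
    pb_cycles_per_episode: int = 5
    pb_apneic_fraction: float = 0.4
    wake_blocks: tuple = ()  # ((start_s, end_s), ...) epoch-aligned
    off_bed_blocks: tuple = ()
    noise_sd: float = 0.02
    seed: int = 0

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    @property
    def tib_h(self) -> float:
        off = sum(b - a for a, b in self.off_bed_blocks)
        return self.duration_h - off / 3600.0

    @property
    def tst_h(self) -> float:
        wake = sum(b - a for a, b in self.wake_blocks)
        return self.tib_h - wake / 3600.0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "duration_h", "fs", "event_rate_per_h", "apnea_fraction",
            "pb_cycle_length_s", "pb_n_episodes", "pb_cycles_per_episode",
            "pb_apneic_fraction", "noise_sd", "seed")}
        d["profile"] = vars(self.profile) | {}
        d["wake_blocks"] = [list(b) for b in self.wake_blocks]
        d["off_bed_blocks"] = [list(b) for b in self.off_bed_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NightSpec":
        d = dict(d)
        d["profile"] = BreathProfile(**d["profile"])
        d["wake_blocks"] = tuple(tuple(b) for b in d["wake_blocks"])
        d["off_bed_blocks"] = tuple(tuple(b) for b in d["off_bed_blocks"])
        return cls(**d)


def default_wake_schedule(
    duration_h: float, tst_h: float, rng: np.random.Generator, epoch_s: float = 30.0
) -> tuple:
    """Place epoch-aligned wake blocks totalling (duration - tst) hours.

    One block at sleep onset plus 1-3 interior awakenings, mimicking
    fragmented ward sleep.
    """
    wake_s = max(0.0, (duration_h - tst_h) * 3600.0)
    if wake_s < epoch_s:
        return ()
    n_interior = int(rng.integers(1, 4))
    # split wake time: ~40% at sleep onset, rest across interior blocks
    onset_epochs = max(1, int(round(0.4 * wake_s / epoch_s)))
    blocks = [(0.0, onset_epochs * epoch_s)]
    remaining = int(round(wake_s / epoch_s)) - onset_epochs
    total_epochs = int(duration_h * 3600 / epoch_s)
    candidates = np.arange(onset_epochs + 20, total_epochs - 20)
    if remaining > 0 and len(candidates) > 0:
        per = np.full(n_interior, remaining // n_interior, dtype=int)
        per[: remaining % n_interior] += 1
        per = per[per > 0]
        anchors = np.sort(
            rng.choice(candidates, size=min(len(per), len(candidates)),
                       replace=False)
        )
        last_end = blocks[0][1]
        for a, p in zip(anchors, per):
            start = max(a * epoch_s, last_end + 10 * epoch_s)
            end = start + p * epoch_s
            if end > (total_epochs - 2) * epoch_s:
                break
            blocks.append((start, end))
            last_end = end
    return tuple(blocks)


def _sleep_regions(spec: NightSpec, margin_s: float = 60.0) -> list:
    """Contiguous sleep intervals, shrunk by a margin at block boundaries."""
    blocked = sorted(list(spec.wake_blocks) + list(spec.off_bed_blocks))
    regions = []
    cursor = 0.0
    for a, b in blocked:
        if a - cursor > 2 * margin_s:
            regions.append((cursor + (margin_s if cursor > 0 else 0.0), a - margin_s))
        cursor = max(cursor, b)
    if spec.duration_s - cursor > 2 * margin_s:
        regions.append((cursor + margin_s, spec.duration_s - margin_s))
    return regions


def simulate_night(spec: NightSpec) -> tuple[RespWaveform, dict]:
    """Synthesize one night and return (waveform, truth).

    truth keys: ``events`` (list of RespiratoryEvent), ``episodes`` (list of
    PBEpisode), ``stages`` (per-epoch labels), ``tst_h``, ``tib_h``,
    ``spec`` (the NightSpec).
    """
    rng = np.random.default_rng(spec.seed)
    w = simulate_respiration(spec.profile, spec.duration_s, spec.fs, rng)
    t = w.times

    regions = _sleep_regions(spec)
    episodes: list = []
    pb_spans: list = []
    # -- periodic breathing first (events avoid its spans)
    if spec.pb_cycle_length_s > 0 and spec.pb_n_episodes > 0:
        pb = PBSpec(
            n_cycles=spec.pb_cycles_per_episode,
            cycle_length_s=spec.pb_cycle_length_s,
            apneic_fraction=spec.pb_apneic_fraction,
        )
        eligible = [r for r in regions if r[1] - r[0] > pb.total_duration_s + 120.0]
        n_ep = min(spec.pb_n_episodes, len(eligible))
        chosen = rng.choice(len(eligible), size=n_ep, replace=False) if n_ep else []
        for ridx in np.sort(np.asarray(chosen, dtype=int)):
            a, b = eligible[ridx]
            onset = rng.uniform(a + 60.0, b - pb.total_duration_s - 60.0)
            w, ep = inject_periodic_breathing(w, pb, onset, rng)
            episodes.append(ep)
            pb_spans.append((onset - 30.0, onset + pb.total_duration_s + 30.0))

    # -- isolated apnea/hypopnea events
    events: list = []
    if spec.event_rate_per_h > 0:
        n_target = int(round(spec.event_rate_per_h * spec.tst_h))
        free: list = []
        for a, b in regions:
            cuts = sorted(
                [s for s in pb_spans if s[0] < b and s[1] > a], key=lambda s: s[0]
            )
            cursor = a
            for ca, cb in cuts:
                if ca - cursor > 0:
                    free.append((cursor, min(ca, b)))
                cursor = max(cursor, cb)
            if b - cursor > 0:
                free.append((cursor, b))
        free = [(a, b) for a, b in free if b - a > 60.0]
        total_free = sum(b - a for a, b in free)
        specs: list = []
        if n_target > 0 and total_free > 0:
            # evenly spaced slots with jitter guarantees the requested count
            slot = total_free / n_target
            offsets = (np.arange(n_target) + rng.uniform(0.30, 0.65, n_target)) * slot
            bounds = np.cumsum([0.0] + [b - a for a, b in free])
            for off in offsets:
                ridx = int(np.searchsorted(bounds, off, side="right") - 1)
                ridx = min(ridx, len(free) - 1)
                onset = free[ridx][0] + (off - bounds[ridx])
                dur = float(rng.uniform(12.0, min(28.0, max(13.0, slot * 0.40))))
                if onset + dur > free[ridx][1]:
                    onset = free[ridx][1] - dur
                kind = APNEA if rng.uniform() < spec.apnea_fraction else HYPOPNEA
                depth = (
                    float(rng.uniform(0.0, 0.04))
                    if kind == APNEA
                    else float(rng.uniform(0.25, 0.55))
                )
                specs.append(EventSpec(kind, onset, dur, depth))
            # drop any residual overlaps from slot-edge shifts
            specs.sort(key=lambda e: e.onset_s)
            kept = []
            for ev in specs:
                if not kept or ev.onset_s >= kept[-1].end_s + 15.0:
                    kept.append(ev)
            w, events = inject_events(w, kept, rng)

    # -- wake blocks: irregular breathing + in-band body-motion noise
    for a, b in spec.wake_blocks:
        m = (t >= a) & (t < b)
        n_m = int(m.sum())
        if n_m == 0:
            continue
        wake_prof = BreathProfile(
            rate_bpm=spec.profile.rate_bpm,
            amplitude_mm=min(MAX_DISPLACEMENT_MM, spec.profile.amplitude_mm * 1.2),
            rate_jitter=0.40,
            amplitude_jitter=0.50,
        )
        irregular = simulate_respiration(wake_prof, n_m / spec.fs + 1.0, spec.fs, rng)
        # aperiodic body motion: white noise shaped into the respiration
        # band, so its envelope and zero crossings are genuinely irregular
        from scipy import signal as sps

        sos = sps.butter(2, [0.1, 0.8], btype="bandpass", fs=spec.fs, output="sos")
        motion = sps.sosfilt(sos, rng.standard_normal(n_m))
        rms = float(np.sqrt(np.mean(motion**2)))
        if rms > 0:
            motion *= 2.5 / rms
        w.samples[m] = irregular.samples[:n_m] + motion

    # -- off-bed: sensor noise only
    for a, b in spec.off_bed_blocks:
        m = (t >= a) & (t < b)
        w.samples[m] = 0.02 * rng.standard_normal(int(m.sum()))

    # -- per-epoch truth stages
    n_epochs = int(spec.duration_s // 30.0)
    stages = []
    for k in range(n_epochs):
        mid = k * 30.0 + 15.0
        if any(a <= mid < b for a, b in spec.off_bed_blocks):
            stages.append("off_bed")
        elif any(a <= mid < b for a, b in spec.wake_blocks):
            stages.append("wake")
        else:
            stages.append("sleep")

    truth = {
        "events": events,
        "episodes": episodes,
        "stages": stages,
        "tst_h": spec.tst_h,
        "tib_h": spec.tib_h,
        "spec": spec,
    }
    return w, truth


def make_epoch_corpus(
    n_epochs: int = 5000,
    seed: int = 3,
    fs: float = 20.0,
    event_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 30-s epoch corpus for classifier training.

    Each epoch comes from a fresh random breathing profile (12-20 bpm,
    1.5-10 mm). Event epochs contain an injected apnea or hypopnea covering
    at least 10 s of the scored window; normal epochs are undisturbed.
    Returns (features, labels) with labels in {"normal", "event"}, feature
    columns per :mod:`respiradar.breath_features` FEATURE_NAMES.
    """
    from .breath_features import epoch_feature_vector
    from .radar_demod import preprocess
    from .signal_types import Epoch

    rng = np.random.default_rng(seed)
    X, y = [], []
    pad = 10.0  # context seconds on each side of the scored window
    n_pad = int(pad * fs)
    n_win = int(30.0 * fs)
    for k in range(n_epochs):
        profile = BreathProfile(
            rate_bpm=float(rng.uniform(12.0, 20.0)),
            amplitude_mm=float(rng.uniform(1.5, 10.0)),
        )
        is_event = rng.uniform() < event_fraction
        w = simulate_respiration(profile, 30.0 + 2 * pad, fs, rng)
        if is_event:
            dur = float(rng.uniform(11.0, 25.0))
            onset = float(rng.uniform(pad, pad + 30.0 - dur))
            kind = APNEA if rng.uniform() < 0.5 else HYPOPNEA
            depth = (
                float(rng.uniform(0.0, 0.04))
                if kind == APNEA
                else float(rng.uniform(0.25, 0.55))
            )
            w, _ = inject_events(w, [EventSpec(kind, onset, dur, depth)], rng)
        w = preprocess(w)
        ep = Epoch(index=0, samples=w.samples[n_pad : n_pad + n_win], fs=fs)
        X.append(epoch_feature_vector(ep))
        y.append("event" if is_event else "normal")
    return np.vstack(X), np.array(y)
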