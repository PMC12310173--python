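"""Periodic-breathing (Cheyne-Stokes-like) episode detection.

Periodic breathing is a run of at least three consecutive cycles, each an
apneic (or hypopneic) phase followed by a crescendo-decrescendo ventilatory
phase. The cycle length is the summed duration of the paired apneic and
ventilatory phases; here cycle *i* spans from the onset of event *i* to the
onset of event *i+1* (the last cycle's ventilatory phase ends where the
envelope returns toward baseline).

All detected apneas/hypopneas are PB-eligible: a CW radar cannot separate
central from obstructive events, so no such distinction is attempted.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .events import PBEpisode, RespiratoryEvent
from .event_engine import smooth_envelope
from .signal_types import RespWaveform

#: Longest plausible ventilatory phase (s) between two PB events.
MAX_VENTILATORY_S = 90.0

#: Upper bound (s) on the adaptive smoothing window of the
#: crescendo-decrescendo envelope test; short ventilatory segments use a
#: proportionally shorter window so the hump shape survives.
PB_SMOOTH_S = 5.0

#: Fractional tolerance for the near-monotone rise/fall test.
MONOTONE_TOL = 0.10


#: A ventilatory hump must start and end well below its peak; flat
#: normal-breathing gaps between unrelated events fail this.
EDGE_TO_PEAK_MAX = 0.85

#: Within periodic breathing the ventilatory phase is short relative to the
#: flanking events; a gap longer than this multiple of the neighbouring
#: event durations is normal breathing, not a ventilatory phase.
GAP_TO_EVENT_MAX = 2.0

#: End cycles whose length deviates from the episode median by more than
#: this fraction are pruned (an unrelated event chained onto an episode).
CYCLE_DEVIATION_MAX = 0.5


def _crescendo_decrescendo(env_seg: np.ndarray, fs: float = 1.0) -> bool:
    """Single interior maximum with near-monotone flanks (10% tolerance),
    rising from and returning to well below the peak.

    The segment is smoothed with a window of one sixth of its own length
    (capped at PB_SMOOTH_S seconds) to suppress breath-scale ripple without
    flattening short humps.
    """
    if len(env_seg) < 5:
        return False
    win = int(min(PB_SMOOTH_S * fs, max(1, len(env_seg) // 6)))
    env_seg = uniform_filter1d(np.asarray(env_seg, float), size=max(1, win),
                               mode="nearest")
    k = int(np.argmax(env_seg))
    if k == 0 or k == len(env_seg) - 1:
        return False
    peak = env_seg[k]
    if peak <= 0:
        return False
    m = max(1, len(env_seg) // 10)
    edge = max(float(np.mean(env_seg[:m])), float(np.mean(env_seg[-m:])))
    if edge > EDGE_TO_PEAK_MAX * peak:
        return False
    tol = MONOTONE_TOL * peak
    rise = env_seg[: k + 1]
    fall = env_seg[k:]
    # running max may only be undercut by tol on the way up (mirror on the way down)
    rise_ok = np.all(rise >= np.maximum.accumulate(rise) - tol)
    fall_ok = np.all(fall[::-1] >= np.maximum.accumulate(fall[::-1]) - tol)
    return bool(rise_ok and fall_ok)


def detect_pb(w: RespWaveform, events: list) -> list:
    """Group consecutive events whose ventilatory gaps pass the
    crescendo-decrescendo test into episodes of >= 3 cycles.

    ``events`` must come from the same (preprocessed) waveform. The final
    cycle's ventilatory phase ends at the envelope's local minimum after the
    last hump; if that cannot be located, the median of the preceding
    ventilatory durations is used.
    """
    if len(events) < 3:
        return []
    events = sorted(events, key=lambda e: e.onset_s)
    env = smooth_envelope(w)

    def seg(a_s: float, b_s: float) -> np.ndarray:
        ia = max(0, int(round((a_s - w.t0) * w.fs)))
        ib = min(len(env), int(round((b_s - w.t0) * w.fs)))
        return env[ia:ib]

    # qualifying link between event i and i+1
    links = []
    for a, b in zip(events, events[1:]):
        gap = b.onset_s - a.end_s
        links.append(
            0 < gap <= min(MAX_VENTILATORY_S,
                           GAP_TO_EVENT_MAX * max(a.duration_s, b.duration_s))
            and _crescendo_decrescendo(seg(a.end_s, b.onset_s), fs=w.fs)
        )

    episodes = []
    i = 0
    while i < len(events):
        j = i
        while j < len(links) and links[j]:
            j += 1
        # events i..j form a chain of (j - i) complete cycles + final event
        if j - i >= 2:  # >= 3 cycles counting the final event's cycle
            chain = list(range(i, j + 1))
            # prune aperiodic end cycles: an unrelated event chained onto a
            # periodic run shows up as an end cycle far from the median
            while len(chain) > 3:
                d = [
                    events[b].onset_s - events[a].onset_s
                    for a, b in zip(chain, chain[1:])
                ]
                med = float(np.median(d))
                if abs(d[0] - med) > CYCLE_DEVIATION_MAX * med:
                    chain.pop(0)
                elif abs(d[-1] - med) > CYCLE_DEVIATION_MAX * med:
                    chain.pop()
                else:
                    break
            cycles = []
            for a, b in zip(chain[:-1], chain[1:]):
                vent = events[b].onset_s - events[a].end_s
                cycles.append((events[a].duration_s, vent))
            # the first event of an episode is not preceded by a ventilatory
            # hump, so its detected onset lacks the flank advance later
            # events carry; equalize via the event-duration difference
            interior = float(
                np.median([events[k].duration_s for k in chain[1:-1]])
            )
            flank = max(0.0, interior - events[chain[0]].duration_s)
            a0, v0 = cycles[0]
            cycles[0] = (a0, v0 + flank)
            last = events[chain[-1]]
            fallback_vent = float(np.median([c[1] for c in cycles]))
            vent_last = _final_ventilatory_duration(env, w, last, fallback_vent)
            # the final cycle must respect the episode's own periodicity;
            # an envelope trough found near a later unrelated event does not
            med_cycle = float(np.median([a + v for a, v in cycles]))
            if abs(last.duration_s + vent_last - med_cycle) > CYCLE_DEVIATION_MAX * med_cycle:
                vent_last = fallback_vent
            cycles.append((last.duration_s, vent_last))
            episodes.append(PBEpisode(onset_s=events[chain[0]].onset_s, cycles=cycles))
            i = j + 1
        else:
            i += 1
    return episodes


def _final_ventilatory_duration(
    env: np.ndarray, w: RespWaveform, last: RespiratoryEvent, fallback: float
) -> float:
    """End of the last cycle: local envelope minimum after the final hump."""
    i0 = int(round((last.end_s - w.t0) * w.fs))
    i1 = min(len(env), i0 + int(MAX_VENTILATORY_S * w.fs))
    window = env[i0:i1]
    if len(window) < int(3 * w.fs):
        return fallback
    pk = int(np.argmax(window))
    after = window[pk:]
    if len(after) < int(2 * w.fs):
        return fallback
    # first decay below a quarter of the hump peak, then the nearby minimum
    below = np.flatnonzero(after < 0.25 * window[pk])
    if len(below) == 0:
        return fallback
    c = int(below[0])
    tail = after[c : c + int(5 * w.fs)]
    trough = pk + c + int(np.argmin(tail))
    return trough / w.fs


def cycle_lengths(ep: PBEpisode) -> list:
    """Element-wise sums of each cycle's apneic + ventilatory durations."""
    return ep.cycle_lengths_s


def night_pb_mean(episodes: list) -> float:
    """Mean cycle length over all cycles of all episodes; 0 with none.

    The zero convention mirrors zero-inflated cohort reporting: nights free
    of periodic breathing contribute 0 s to patient-level means.
    """
    all_cycles = [c for ep in episodes for c in cycle_lengths(ep)]
    if not all_cycles:
        return 0.0
    return float(np.mean(all_cycles))


def average_nights(*nights) -> dict:
    """Arithmetic mean of per-night indices across available nights.

    Accepts one or more NightSummary objects (None entries are skipped);
    a single night returns its own values.
    """
    avail = [n for n in nights if n is not None]
    if not avail:
        raise ValueError("need at least one night")
    return {
        "rdi_events_per_h": float(np.mean([n.rdi_events_per_h for n in avail])),
        "mean_pb_cycle_s": float(np.mean([n.mean_pb_cycle_s for n in avail])),
        "tst_h": float(np.mean([n.tst_h for n in avail])),
        "sleep_efficiency_pct": float(
            np.mean([n.sleep_efficiency_pct for n in avail])
        ),
        "n_nights": len(avail),
    }
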