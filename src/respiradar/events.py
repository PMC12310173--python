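"""Respiratory event and periodic-breathing episode records.

These are the ground-truth/detection currency passed between the generator,
the event detector and the periodic-breathing analyser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

APNEA = "apnea"
HYPOPNEA = "hypopnea"

#: Minimum duration (s) for a scorable apnea or hypopnea.
MIN_EVENT_DURATION_S = 10.0


@dataclass(frozen=True)
class RespiratoryEvent:
    """One apnea or hypopnea: a >=10-s reduction of breathing amplitude."""

    kind: str  # "apnea" | "hypopnea"
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in (APNEA, HYPOPNEA):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s < MIN_EVENT_DURATION_S:
            raise ValueError(
                f"events must last >= {MIN_EVENT_DURATION_S} s, got {self.duration_s}"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class PBEpisode:
    """A periodic-breathing run of >= 3 apneic/ventilatory cycles.

    ``cycles`` holds ``(apneic_duration_s, ventilatory_duration_s)`` pairs;
    the length of cycle *i* is the sum of its two phase durations.
    """

    onset_s: float
    cycles: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cyc = tuple((float(a), float(v)) for a, v in self.cycles)
        object.__setattr__(self, "cycles", cyc)
        if len(cyc) < 3:
            raise ValueError("periodic breathing requires >= 3 consecutive cycles")
        for a, v in cyc:
            if a <= 0 or v <= 0:
                raise ValueError("phase durations must be positive")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def cycle_lengths_s(self) -> list:
        return [a + v for a, v in self.cycles]

    @property
    def duration_s(self) -> float:
        return float(sum(self.cycle_lengths_s))


# ---------------------------------------------------------------------------
# serialization


def events_to_json(events: Sequence[RespiratoryEvent], path: str | Path) -> None:
    payload = [
        {"kind": e.kind, "onset_s": e.onset_s, "duration_s": e.duration_s}
        for e in events
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def events_from_json(path: str | Path) -> list:
    payload = json.loads(Path(path).read_text())
    return [RespiratoryEvent(**d) for d in payload]


def events_to_tsv(events: Sequence[RespiratoryEvent], path: str | Path) -> None:
    """BED-like three-column table: onset_s, end_s, kind."""
    lines = [f"{e.onset_s:.3f}\t{e.end_s:.3f}\t{e.kind}" for e in events]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def episodes_to_json(episodes: Iterable[PBEpisode], path: str | Path) -> None:
    payload = [{"onset_s": ep.onset_s, "cycles": list(ep.cycles)} for ep in episodes]
    Path(path).write_text(json.dumps(payload, indent=1))


def episodes_from_json(path: str | Path) -> list:
    payload = json.loads(Path(path).read_text())
    return [PBEpisode(onset_s=d["onset_s"], cycles=d["cycles"]) for d in payload]


def episodes_to_tsv(episodes: Iterable[PBEpisode], path: str | Path) -> None:
    """BED-like table: onset_s, end_s, n_cycles, mean_cycle_s."""
    lines = []
    for ep in episodes:
        mean_cycle = ep.duration_s / ep.n_cycles
        lines.append(
            f"{ep.onset_s:.3f}\t{ep.onset_s + ep.duration_s:.3f}"
            f"\t{ep.n_cycles}\t{mean_cycle:.3f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
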