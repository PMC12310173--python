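"""End-to-end orchestration: simulate -> detect -> analyze.

Stages communicate only via documented file formats (CSV waveforms, JSON
truth sidecars and configs, TSV reports); every output directory carries a
manifest with the seed and a parameter hash so a run is reproducible from
the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, cohort_to_frame, generate_cohort
from .cohort_stats import build_report, write_report
from .event_engine import NightSummary, compute_rdi, estimate_sleep, rule_label_events
from .events import events_to_json
from .pb_cycle import detect_pb, night_pb_mean
from .radar_demod import preprocess, split_epochs
from .signal_types import RespWaveform
from .synthgen import simulate_night

log = logging.getLogger("respiradar")


def _stage_at(stages: list, t_s: float) -> str:
    k = int(t_s // 30.0)
    if 0 <= k < len(stages):
        return stages[k]
    return "unknown"


@dataclasses.dataclass
class PipelineConfig:
    """Run-wide settings; everything else defaults per module."""

    out_dir: str = "respiradar_out"
    seed: int = 0
    fs: float = 20.0
    band_hz: tuple = (0.1, 0.8)
    duration_h: float = 8.0
    n_low: int = 25
    n_high: int = 47
    write_waveforms: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)

    def param_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, out: Path, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "param_hash": cfg.param_hash(),
        "version": __version__,
        "config": cfg.to_dict(),
        **extra,
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1))


def run_simulation(cfg: PipelineConfig) -> Path:
    """Generate the cohort table, per-night specs/waveforms and truth files."""
    out = Path(cfg.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}") from exc

    ccfg = CohortConfig(
        n_low=cfg.n_low, n_high=cfg.n_high, duration_h=cfg.duration_h,
        fs=cfg.fs, seed=cfg.seed,
    )
    records = generate_cohort(ccfg)
    frame = cohort_to_frame(records)
    frame.to_csv(out / "cohort.csv", index=False, float_format="%.6f")

    n_files = 0
    specs_payload = {}
    for rec in records:
        for k, spec in enumerate(rec.night_specs):
            night_id = f"{rec.id}_night{k + 1}"
            specs_payload[night_id] = spec.to_dict()
            if cfg.write_waveforms:
                w, truth = simulate_night(spec)
                w.to_csv(out / f"{night_id}.csv")
                events_to_json(truth["events"], out / f"{night_id}_events.json")
                n_files += 1
            log.info("simulated %s: %d events, %d PB episodes scheduled",
                     night_id, int(round(spec.event_rate_per_h * spec.tst_h)),
                     spec.pb_n_episodes)
    (out / "night_specs.json").write_text(json.dumps(specs_payload, indent=1))
    _write_manifest(cfg, out, "simulate",
                    {"n_patients": len(records), "n_waveform_files": n_files})
    return out


def summarize_night(w: RespWaveform, band_hz=(0.1, 0.8)) -> NightSummary:
    """Run the full per-night detection chain on a displacement waveform.

    Events are scored only when their midpoint falls in a sleep-staged
    epoch, matching sleep-scoring convention (respiratory events during
    wake or off-bed time do not count toward the RDI).
    """
    clean = preprocess(w, band_hz)
    epochs = split_epochs(clean)
    tst_h, eff = estimate_sleep(epochs)
    stages = [ep.stage_label for ep in epochs]
    events = [
        e
        for e in rule_label_events(clean)
        if _stage_at(stages, e.onset_s + e.duration_s / 2.0) == "sleep"
    ]
    episodes = detect_pb(clean, events)
    rdi = compute_rdi(len(events), tst_h) if tst_h > 0 else 0.0
    return NightSummary(
        tst_h=tst_h,
        time_in_bed_h=tst_h * 100.0 / eff if eff > 0 else 0.0,
        sleep_efficiency_pct=eff,
        event_count=len(events),
        rdi_events_per_h=rdi,
        mean_pb_cycle_s=night_pb_mean(episodes),
    )


def run_detection(cfg: PipelineConfig, waveform_dir: str | Path | None = None) -> Path:
    """Detect events/PB per night file and write the night-summary table.

    Accepts displacement CSVs (``*_night*.csv``); malformed files are
    skipped with a logged warning and the run continues.
    """
    src = Path(waveform_dir or cfg.out_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in sorted(src.glob("*_night*.csv")):
        if path.name.endswith("_events.csv"):
            continue
        try:
            w = RespWaveform.from_csv(path)
            summary = summarize_night(w, cfg.band_hz)
        except Exception as exc:
            log.warning("skipping %s: %s", path.name, exc)
            continue
        night_id = path.stem
        rows.append({
            "night_id": night_id,
            "patient_id": night_id.split("_night")[0],
            "tst_h": summary.tst_h,
            "sleep_efficiency_pct": summary.sleep_efficiency_pct,
            "event_count": summary.event_count,
            "rdi_events_per_h": summary.rdi_events_per_h,
            "mean_pb_cycle_s": summary.mean_pb_cycle_s,
        })
        log.info("%s: %d events, RDI %.1f, PB mean %.1f s", night_id,
                 summary.event_count, summary.rdi_events_per_h,
                 summary.mean_pb_cycle_s)
    columns = ["night_id", "patient_id", "tst_h", "sleep_efficiency_pct",
               "event_count", "rdi_events_per_h", "mean_pb_cycle_s"]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(out / "night_summaries.csv", index=False, float_format="%.6f")
    _write_manifest(cfg, out, "detect", {"n_nights": len(rows)})
    return out / "night_summaries.csv"


def run_analysis(
    cfg: PipelineConfig,
    night_summaries: str | Path | None = None,
    cohort_table: str | Path | None = None,
) -> Path:
    """Average nights per patient, merge with the cohort, run the stats."""
    out = Path(cfg.out_dir)
    nights = pd.read_csv(night_summaries or out / "night_summaries.csv")
    cohort = pd.read_csv(cohort_table or out / "cohort.csv")

    missing = set(nights["patient_id"]) - set(cohort["id"])
    if missing:
        raise ValueError(f"night summaries reference unknown patient ids: {sorted(missing)}")

    per_patient = (
        nights.groupby("patient_id")[
            ["rdi_events_per_h", "mean_pb_cycle_s", "tst_h", "sleep_efficiency_pct"]
        ]
        .mean()
        .reset_index()
        .rename(columns={"mean_pb_cycle_s": "pb_cycle_s"})
    )
    merged = cohort.drop(
        columns=["rdi_events_per_h", "pb_cycle_s", "tst_h", "sleep_efficiency_pct"]
    ).merge(per_patient, left_on="id", right_on="patient_id", how="inner")

    report = build_report(merged)
    report_dir = out / "report"
    write_report(report, report_dir)
    n_sub = int(merged["ntprobnp_pg_ml"].notna().sum()) if "ntprobnp_pg_ml" in merged else 0
    _write_manifest(cfg, out, "analyze",
                    {"n_patients": len(merged), "ntprobnp_subgroup_n": n_sub})
    return report_dir
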