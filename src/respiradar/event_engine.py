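"""Apnea/hypopnea detection, sleep-time estimation, and the RDI.

Two detection routes are provided:

* :func:`rule_label_events` — a deterministic envelope-threshold scorer
  (AASM-style flow-reduction rules adapted to displacement, with no
  desaturation criterion because the radar carries no oximeter): apnea when
  the breath envelope falls below 10% of its local baseline for >= 10 s,
  hypopnea when it sits in [10%, 70%) for >= 10 s.
* a deep neural decision tree (DNDT) epoch classifier — features are
  soft-binned by a temperature-controlled softmax over learned cut-points,
  leaf membership is the Kronecker product of per-feature bin memberships,
  and leaves map linearly to class logits; all parameters are fitted by
  gradient descent on cross-entropy.

The respiratory disturbance index (RDI) is the event count divided by the
estimated total sleep time in hours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .breath_features import breath_metrics, find_extrema
from .events import APNEA, HYPOPNEA, RespiratoryEvent
from .signal_types import RespWaveform

#: Envelope-vs-baseline thresholds of the rule scorer.
APNEA_RATIO = 0.10
HYPOPNEA_RATIO = 0.70
#: Bridging threshold: two sub-70% runs separated only by envelope that
#: stays below 90% of baseline are one flickering event, not two.
BRIDGE_RATIO = 0.90
MIN_EVENT_S = 10.0
#: Shortest sustained sub-70% stretch a bridged span must contain.
MIN_CORE_S = 6.0
#: Assumed duration (s) of the cosine-shaped amplitude transition at event
#: edges, used to back-correct threshold-crossing boundary bias.
EDGE_TRANSITION_S = 2.0
#: Effective edge width for deep (10%) crossings: the amplitude taper plus
#: the band-pass/Hilbert transition smear that dominates near zero envelope.
DEEP_EDGE_TRANSITION_S = 4.0

#: Time step (s) of the detection grid the envelope ratio is evaluated on.
DETECTION_DT_S = 0.5

#: Trailing window (s) for the local baseline median.
BASELINE_WINDOW_S = 120.0


@dataclass
class NightSummary:
    """Per-night sleep and respiratory indices."""

    tst_h: float
    time_in_bed_h: float
    sleep_efficiency_pct: float
    event_count: int
    rdi_events_per_h: float
    mean_pb_cycle_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tst_h <= self.time_in_bed_h + 1e-9):
            raise ValueError("tst_h must lie in [0, time_in_bed_h]")
        if self.rdi_events_per_h < 0:
            raise ValueError("rdi must be >= 0")


# ---------------------------------------------------------------------------
# envelope + rule-based scoring


def smooth_envelope(w: RespWaveform, smooth_s: float = 1.0) -> np.ndarray:
    """Magnitude of the analytic signal, moving-average smoothed (mm)."""
    env = np.abs(sps.hilbert(w.samples - w.samples.mean()))
    k = max(1, int(round(smooth_s * w.fs)))
    return uniform_filter1d(env, size=k, mode="nearest")


def envelope_ratio(
    w: RespWaveform, dt: float = DETECTION_DT_S
) -> tuple[np.ndarray, float]:
    """Envelope over its trailing local baseline, on a coarse detection grid.

    The envelope is block-averaged to a ``dt`` grid; the baseline at each
    grid point is the median of provisionally normal envelope values
    (>= 70% of the global median) over the trailing 120 s, so events
    themselves do not drag the baseline down. Returns (ratio, dt).
    """
    env = smooth_envelope(w)
    step = int(round(dt * w.fs))
    n_bins = len(env) // step
    e = env[: n_bins * step].reshape(n_bins, step).mean(axis=1)

    global_med = float(np.median(e))
    if global_med <= 0:
        return np.ones(n_bins), dt
    normal = np.where(e >= HYPOPNEA_RATIO * global_med, e, np.nan)
    win = int(round(BASELINE_WINDOW_S / dt))
    baseline = (
        pd.Series(normal).rolling(window=win, min_periods=1).median().to_numpy()
    )
    masked_med = float(np.nanmedian(normal)) if np.isfinite(normal).any() else global_med
    baseline = np.where(np.isfinite(baseline), baseline, masked_med)
    return e / baseline, dt


def _runs(mask: np.ndarray) -> list:
    """(start, stop) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def edge_correction_s(depth: float, threshold: float = HYPOPNEA_RATIO) -> float:
    """Boundary bias of a threshold crossing on a cosine event edge.

    With event amplitude transitioning from baseline to a residual fraction
    ``depth`` over a cosine edge of EDGE_TRANSITION_S seconds, the
    ``threshold`` crossing lands u* seconds inside the true edge; both
    onset and end are pulled inward by this amount.
    """
    depth = float(np.clip(depth, 0.0, threshold - 1e-6))
    c = 2.0 * (threshold - depth) / (1.0 - depth) - 1.0
    edge = EDGE_TRANSITION_S if threshold >= HYPOPNEA_RATIO else DEEP_EDGE_TRANSITION_S
    return (edge / np.pi) * float(np.arccos(np.clip(c, -1.0, 1.0)))


def events_from_ratio(ratio: np.ndarray, dt: float) -> list:
    """Score a pre-computed envelope ratio series into events.

    A run of ratio < 0.7 is an event core; neighbouring cores separated
    only by envelope below 90% of baseline (threshold flicker of a shallow
    hypopnea) merge into one span. A span qualifies when it lasts >= 10 s
    (after boundary correction) and spends >= 6 s in total below 70% of
    baseline; it is an apnea when it holds
    a >= 10-s stretch below 10% of baseline, otherwise a hypopnea. Span
    boundaries are back-corrected for the crossing bias of cosine-shaped
    event edges (see :func:`edge_correction_s`).
    """
    min_len = int(np.ceil(MIN_EVENT_S / dt))
    min_core = int(np.ceil(MIN_CORE_S / dt))
    cores = _runs(ratio < HYPOPNEA_RATIO)
    # bridge cores whose gap stays below the flicker threshold
    spans = []
    for a, b in cores:
        if spans and np.all(ratio[spans[-1][1] : a] < BRIDGE_RATIO):
            spans[-1] = (spans[-1][0], b)
        else:
            spans.append((a, b))
    out = []
    for a, b in spans:
        inner = [(ca, cb) for ca, cb in cores if ca >= a and cb <= b]
        if sum(cb - ca for ca, cb in inner) < min_core:
            continue
        core_mask = ratio[a:b] < HYPOPNEA_RATIO
        depth = float(np.median(ratio[a:b][core_mask]))
        u = edge_correction_s(depth)
        onset = max(0.0, a * dt - u)
        duration = b * dt + u - onset
        if duration < MIN_EVENT_S:  # minimum applies to corrected boundaries
            continue
        sub = ratio[a:b] < APNEA_RATIO
        kind = HYPOPNEA
        for sa, sb in _runs(sub):
            sub_depth = float(np.median(ratio[a + sa : a + sb]))
            u_sub = edge_correction_s(sub_depth, APNEA_RATIO)
            if (sb - sa) * dt + 2.0 * u_sub >= MIN_EVENT_S:
                kind = APNEA
                break
        out.append(RespiratoryEvent(kind=kind, onset_s=onset, duration_s=duration))
    return out


def rule_label_events(w: RespWaveform) -> list:
    """Detect apnea/hypopnea events on a preprocessed waveform."""
    ratio, dt = envelope_ratio(w)
    return events_from_ratio(ratio, dt)


# ---------------------------------------------------------------------------
# deep neural decision tree


@dataclass
class DNDTModel:
    """A forest of small soft decision trees over feature groups.

    Wide feature vectors are partitioned into groups of at most
    ``max_features_per_tree`` features; each group gets one soft tree (the
    full Kronecker leaf space over all features would be exponentially
    large), and class logits are averaged across trees.
    """

    feature_groups: list  # list[list[int]]
    cut_points: list  # per feature index: ndarray of sorted cut points
    temperature: float
    leaf_weights: list  # per tree: (n_leaves, n_classes)
    class_bias: np.ndarray
    classes: list
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    n_features: int
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_groups": [list(map(int, g)) for g in self.feature_groups],
            "cut_points": {str(f): np.asarray(c).tolist() for f, c in self.cut_points},
            "temperature": self.temperature,
            "leaf_weights": [np.asarray(w).tolist() for w in self.leaf_weights],
            "class_bias": self.class_bias.tolist(),
            "classes": list(self.classes),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "n_features": self.n_features,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DNDTModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_groups=d["feature_groups"],
            cut_points=[(int(f), np.array(c)) for f, c in d["cut_points"].items()],
            temperature=d["temperature"],
            leaf_weights=[np.array(w) for w in d["leaf_weights"]],
            class_bias=np.array(d["class_bias"]),
            classes=d["classes"],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_sd=np.array(d["scaler_sd"]),
            n_features=d["n_features"],
            meta=d.get("meta", {}),
        )


_EINSUM_LETTERS = "abcd"


def _bin_probs(xf: np.ndarray, beta: np.ndarray, tau: float) -> np.ndarray:
    """Soft bin memberships of one (standardized) feature column."""
    n_bins = len(beta) + 1
    w = np.arange(1, n_bins + 1, dtype=float)
    b = np.concatenate([[0.0], -np.cumsum(beta)])
    z = (xf[:, None] * w[None, :] + b[None, :]) / tau
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _leaf_memberships(probs: list) -> np.ndarray:
    """Outer product of per-feature bin memberships, flattened per sample."""
    g = len(probs)
    letters = _EINSUM_LETTERS[:g]
    spec = ",".join(f"n{c}" for c in letters) + "->n" + letters
    L = np.einsum(spec, *probs)
    return L.reshape(L.shape[0], -1)


def _forward(model_state: dict, X: np.ndarray) -> tuple:
    """Class logits plus per-tree intermediates needed for the backward pass."""
    tau = model_state["temperature"]
    trees = []
    logits = np.tile(model_state["class_bias"], (X.shape[0], 1))
    n_trees = len(model_state["feature_groups"])
    for gi, group in enumerate(model_state["feature_groups"]):
        probs = [_bin_probs(X[:, f], model_state["cuts"][f], tau) for f in group]
        L = _leaf_memberships(probs)
        logits += L @ model_state["leaf_weights"][gi] / n_trees
        trees.append({"probs": probs, "L": L})
    return logits, trees


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_event_classifier(
    features: np.ndarray,
    labels,
    cfg: dict | None = None,
    seed: int = 0,
) -> DNDTModel:
    """Fit the DNDT on an (n_epochs, n_features) matrix with class labels.

    cfg keys (defaults): n_cuts 3, temperature 0.1, steps 500, lr 0.05,
    max_features_per_tree 3. Cut points are initialized at within-feature
    quantiles and trained jointly with the leaf-to-class weights by Adam on
    the cross-entropy; deterministic under ``seed``.
    """
    cfg = {
        "n_cuts": 3,
        "temperature": 0.1,
        "steps": 500,
        "lr": 0.05,
        "max_features_per_tree": 3,
        **(cfg or {}),
    }
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("training data must contain >= 2 classes")
    y = np.searchsorted(np.array(classes), labels)
    Y = np.eye(len(classes))[y]
    n, d = X.shape

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    gsize = cfg["max_features_per_tree"]
    groups = [list(range(i, min(i + gsize, d))) for i in range(0, d, gsize)]
    n_bins = cfg["n_cuts"] + 1
    tau = cfg["temperature"]

    cuts = {}
    for f in range(d):
        qs = np.quantile(Xs[:, f], np.linspace(0, 1, cfg["n_cuts"] + 2)[1:-1])
        # strictly increasing cut points even for spiky features
        cuts[f] = np.maximum.accumulate(qs) + 1e-3 * np.arange(cfg["n_cuts"])
    leaf_w = [
        0.01 * rng.standard_normal((n_bins ** len(g), len(classes))) for g in groups
    ]
    bias = np.zeros(len(classes))
    state = {
        "feature_groups": groups,
        "cuts": cuts,
        "leaf_weights": leaf_w,
        "class_bias": bias,
        "temperature": tau,
    }

    # flat parameter list for Adam: cuts per feature, leaf weights, bias
    params = [cuts[f] for f in range(d)] + leaf_w + [bias]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    n_trees = len(groups)
    losses = []

    for step in range(1, cfg["steps"] + 1):
        logits, trees = _forward(state, Xs)
        P = _softmax(logits)
        losses.append(float(-np.mean(np.log(P[np.arange(n), y] + 1e-12))))
        G = (P - Y) / n  # (n, C)

        grads_cuts = {f: np.zeros_like(cuts[f]) for f in range(d)}
        grads_leaf = []
        for gi, group in enumerate(groups):
            tr = trees[gi]
            grads_leaf.append(tr["L"].T @ G / n_trees)
            dL = (G @ state["leaf_weights"][gi].T) / n_trees  # (n, leaves)
            g = len(group)
            T = dL.reshape((n,) + (n_bins,) * g)
            letters = _EINSUM_LETTERS[:g]
            for j, f in enumerate(group):
                others = [tr["probs"][k] for k in range(g) if k != j]
                spec = (
                    "n" + letters + ","
                    + ",".join(f"n{letters[k]}" for k in range(g) if k != j)
                    + f"->n{letters[j]}"
                )
                dp = np.einsum(spec, T, *others) if others else T
                pj = tr["probs"][j]
                dz = pj * (dp - (dp * pj).sum(axis=1, keepdims=True)) / tau
                db = dz.sum(axis=0)  # gradient wrt per-bin offsets b
                # b_i = -cumsum(beta)_{i-1}  =>  d/d beta_k = -sum_{i>k} db_i
                tail = np.cumsum(db[::-1])[::-1]  # tail[i] = sum(db[i:])
                grads_cuts[f] += -tail[1:]
        grads_bias = G.sum(axis=0)

        grads = [grads_cuts[f] for f in range(d)] + grads_leaf + [grads_bias]
        for p, gr, m, v in zip(params, grads, m_t, v_t):
            m *= b1
            m += (1 - b1) * gr
            v *= b2
            v += (1 - b2) * gr**2
            mhat = m / (1 - b1**step)
            vhat = v / (1 - b2**step)
            p -= cfg["lr"] * mhat / (np.sqrt(vhat) + eps)

    return DNDTModel(
        feature_groups=groups,
        cut_points=[(f, cuts[f]) for f in range(d)],
        temperature=tau,
        leaf_weights=leaf_w,
        class_bias=bias,
        classes=classes,
        scaler_mean=mu,
        scaler_sd=sd,
        n_features=d,
        meta={"seed": seed, "final_loss": losses[-1], "loss_curve": losses, **cfg},
    )


def predict_epochs(model: DNDTModel, features: np.ndarray):
    """Class label per epoch: argmax of the averaged tree logits."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    Xs = (X - model.scaler_mean) / model.scaler_sd
    state = {
        "feature_groups": model.feature_groups,
        "cuts": dict(model.cut_points),
        "leaf_weights": model.leaf_weights,
        "class_bias": model.class_bias,
        "temperature": model.temperature,
    }
    logits, _ = _forward(state, Xs)
    return np.array(model.classes, dtype=object)[np.argmax(logits, axis=1)]


# ---------------------------------------------------------------------------
# sleep estimation + RDI


def estimate_sleep(
    epochs: list,
    off_bed_rms_mm: float = 0.08,
    wake_jump_fraction: float = 0.15,
    wake_rms_factor: float = 1.5,
) -> tuple[float, float]:
    """Score each epoch off-bed / wake / sleep; return (tst_h, efficiency%).

    Off-bed epochs carry near-zero signal power. Wake epochs show irregular
    breath timing (median absolute successive difference of peak-to-peak
    intervals above ``wake_jump_fraction`` of the epoch's median breath
    period) or gross body motion (RMS above ``wake_rms_factor`` times the
    in-bed night median); a single long inter-breath gap — the signature of
    an apnea, not of wakefulness — leaves the median jump small, so
    event-bearing epochs stay scored as sleep. Labels are written to
    ``epoch.stage_label`` in place.
    """
    if not epochs:
        raise ValueError("need >= 1 epoch")
    rms = np.array([float(np.std(ep.samples)) for ep in epochs])
    in_bed = rms >= off_bed_rms_mm
    med_rms = float(np.median(rms[in_bed])) if in_bed.any() else 0.0

    n_sleep = 0
    for ep, r, bed in zip(epochs, rms, in_bed):
        if not bed:
            ep.stage_label = "off_bed"
            continue
        w = RespWaveform(np.asarray(ep.samples, float), ep.fs)
        bm = breath_metrics(find_extrema(w))
        jumps = np.abs(np.diff(bm.pp_intervals_s))
        # a single long inter-breath gap is an apnea signature, not wake:
        # only continuously breathing but irregular epochs count as wake
        continuous = (
            len(bm.pp_intervals_s) >= 5 and float(np.max(bm.pp_intervals_s)) < 8.0
        )
        irregular = (
            continuous and len(jumps) >= 2
            and float(np.median(jumps))
            > wake_jump_fraction * float(np.median(bm.pp_intervals_s))
        )
        moving = med_rms > 0 and r > wake_rms_factor * med_rms
        if irregular or moving:
            ep.stage_label = "wake"
        else:
            ep.stage_label = "sleep"
            n_sleep += 1

    tst_h = n_sleep * 30.0 / 3600.0
    tib_h = int(in_bed.sum()) * 30.0 / 3600.0
    efficiency = 100.0 * tst_h / tib_h if tib_h > 0 else 0.0
    return tst_h, efficiency


def compute_rdi(event_count: int, tst_h: float) -> float:
    """RDI = events per hour of sleep."""
    if tst_h <= 0:
        raise ValueError("RDI undefined for zero total sleep time")
    if event_count < 0:
        raise ValueError("event_count must be >= 0")
    return event_count / tst_h
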