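"""Metrics, confusion analysis, state-flow mapping and the experiment grid.

Covers the reporting side of the pipeline: confusion matrices,
macro-averaged precision/recall/F1 plus accuracy, the per-state
most-common-prediction ("Sankey") map with its null-state rule, grouping
recommendations derived from that map, and the grid runner that
evaluates both classifiers over every testable dataset variant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .convlstm import ConvLSTMClassifier, ConvLSTMConfig
from .kpca import KPCARidgeClassifier
from .preprocess import (
    DataError,
    FUSIONS,
    SAMPLINGS,
    build_dataset_variant,
    select_top_states,
    split_train_test,
)

NULL_STATE = "null"


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # (K, K) ints; rows true, cols predicted
    labels: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class ClassificationReport:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {"Mac-Prec": self.macro_precision, "Mac-Recall": self.macro_recall,
                "Mac-F1-Score": self.macro_f1, "Acc": self.accuracy}


@dataclass
class StateFlowMap:
    targets: dict[str, str]       # true state -> predicted state or "null"
    theta: float
    top_share: dict[str, float]

    @property
    def null_states(self) -> list[str]:
        return sorted(s for s, t in self.targets.items() if t == NULL_STATE)

    def to_sankey_json(self) -> dict:
        """Nodes/links/weights layout consumable by standard plotting tools."""
        sources = sorted(self.targets)
        sinks = sorted(set(self.targets.values()))
        nodes = [{"name": s, "side": "true"} for s in sources] + \
                [{"name": s, "side": "predicted"} for s in sinks]
        links = [{"source": i, "target": len(sources) + sinks.index(self.targets[s]),
                  "value": self.top_share[s]} for i, s in enumerate(sources)]
        return {"nodes": nodes, "links": links, "theta": self.theta}


@dataclass
class ReportRow:
    sampling: str
    n_states: int
    fusion: str
    model: str
    report: ClassificationReport | None   # None for untestable variants

    def as_record(self) -> dict:
        rec = {"sampling": self.sampling, "n_states": self.n_states,
               "fusion": self.fusion, "model": self.model}
        if self.report is None:
            rec.update({k: float("nan") for k in
                        ("Mac-Prec", "Mac-Recall", "Mac-F1-Score", "Acc")})
        else:
            rec.update(self.report.as_dict())
        return rec


def confusion(true_labels, predicted_labels, vocabulary: list[str]) -> ConfusionMatrix:
    """counts[i][j] = #(true = label i and predicted = label j)."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label arrays differ in length")
    index = {name: i for i, name in enumerate(vocabulary)}
    K = len(vocabulary)
    counts = np.zeros((K, K), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside vocabulary: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=list(vocabulary))


def macro_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Macro precision/recall/F1 and accuracy from a confusion matrix.

    Per-class precision is the diagonal over the column sum (0 for an
    empty column), recall the diagonal over the row sum (0 for an empty
    row), F1 their harmonic mean (0 when both are 0); macro values are
    unweighted class means and macro-F1 is the mean of per-class F1.
    """
    counts = np.asarray(cm.counts, dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return ClassificationReport(
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(diag.sum() / counts.sum()),
    )


def prediction_flow(cm: ConfusionMatrix, theta: float = 0.30) -> StateFlowMap:
    """Per-state most-common prediction with the null-state rule.

    A true state maps to its modal predicted state when that column holds
    at least a share theta of the state's predictions; a state confused
    evenly across many others (top share < theta) maps to "null".  Ties
    break toward the diagonal, then lexicographically.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    counts = np.asarray(cm.counts, dtype=float)
    targets: dict[str, str] = {}
    top_share: dict[str, float] = {}
    for i, state in enumerate(cm.labels):
        row = counts[i]
        total = row.sum()
        if total == 0:
            warnings.warn(f"state {state!r} has no evaluated samples; mapped to null")
            targets[state] = NULL_STATE
            top_share[state] = 0.0
            continue
        best = row.max()
        candidates = [j for j in range(len(row)) if row[j] == best]
        j = i if i in candidates else min(candidates, key=lambda j: cm.labels[j])
        share = best / total
        top_share[state] = float(share)
        targets[state] = cm.labels[j] if share >= theta else NULL_STATE
    return StateFlowMap(targets=targets, theta=theta, top_share=top_share)


@dataclass
class AggregationReport:
    groups: list[list[str]]       # aggregate groups (shared target), size >= 2
    singletons: list[str]         # uniquely identified states
    removals: list[str]           # stand-alone null-mapped states

    @property
    def accounting(self) -> tuple[int, int, int]:
        return (len(self.groups), len(self.removals), len(self.singletons))


def aggregate_recommendations(flow: StateFlowMap) -> AggregationReport:
    """Group states that share a most-common prediction; list null states
    for removal.  n_groups' members + n_null + n_uniquely_identified = K."""
    by_target: dict[str, list[str]] = {}
    removals = []
    for state in sorted(flow.targets):
        target = flow.targets[state]
        if target == NULL_STATE:
            removals.append(state)
        else:
            by_target.setdefault(target, []).append(state)
    groups, singletons = [], []
    for target in sorted(by_target):
        members = by_target[target]
        if len(members) > 1:
            groups.append(members)
        else:
            singletons.extend(members)
    return AggregationReport(groups=groups, singletons=singletons, removals=removals)


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

#: the two cells with too little low-rate data to populate
UNTESTABLE = {("interpolate", 50, "imu-audio-env"), ("subsample", 50, "imu-audio-env")}


@dataclass
class GridConfig:
    state_subset_10: list[str]
    split_ratio: float = 0.7
    split_level: str = "event"
    seed: int = 0
    kpca_gamma: float = 1e-3
    kpca_alpha: float = 1.0
    kpca_reduce: float = 1.0
    convlstm: ConvLSTMConfig = field(default_factory=ConvLSTMConfig)
    models: tuple[str, ...] = ("convlstm", "kpca")


def run_experiment_grid(sessions, grid: GridConfig) -> tuple[list[ReportRow], pd.DataFrame]:
    """Evaluate each model over all 12 grid cells (10 testable + 2 NaN rows).

    Sessions must already be Z-normalized.  Variant build failures are
    recorded as NaN rows rather than raised.
    """
    from dataclasses import replace

    from .kpca import reduce_training_set

    rows: list[ReportRow] = []
    for sampling in SAMPLINGS:
        for n_states in (10, 50):
            for fusion in FUSIONS:
                if (sampling, n_states, fusion) in UNTESTABLE:
                    for model in grid.models:
                        rows.append(ReportRow(sampling, n_states, fusion, model, None))
                    continue
                try:
                    subset = grid.state_subset_10 if n_states == 10 else None
                    variant = build_dataset_variant(sessions, sampling, n_states,
                                                    fusion, subset)
                    split = split_train_test(variant, grid.split_ratio, grid.seed,
                                             grid.split_level)
                except (DataError, ValueError) as exc:
                    warnings.warn(f"variant {sampling}/{n_states}/{fusion} failed: {exc}")
                    for model in grid.models:
                        rows.append(ReportRow(sampling, n_states, fusion, model, None))
                    continue
                Xtr, ytr = split.arrays("train")
                Xte, yte = split.arrays("test")
                for model in grid.models:
                    if model == "convlstm":
                        cfg = replace(grid.convlstm, dense_out=len(split.vocabulary))
                        res = ConvLSTMClassifier(Xtr, ytr, split.vocabulary, cfg).fit()
                        pred = res.predict_indices(Xte)
                    elif model == "kpca":
                        Xr, yr = reduce_training_set(Xtr, ytr, grid.kpca_reduce,
                                                     seed=grid.seed)
                        res = KPCARidgeClassifier(Xr, yr, gamma=grid.kpca_gamma,
                                                  alpha=grid.kpca_alpha).fit()
                        pred = res.predict(Xte)
                    else:
                        raise ValueError(f"unknown model {model!r}")
                    vocab = split.vocabulary
                    cm = confusion([vocab[i] for i in yte],
                                   [vocab[i] for i in pred], vocab)
                    rows.append(ReportRow(sampling, n_states, fusion, model,
                                          macro_report(cm)))
    table = pd.DataFrame([r.as_record() for r in rows])
    return rows, table


def preliminary_state_subset(sessions, k: int = 10, gamma: float = 1e-3,
                             alpha: float = 1.0, seed: int = 0) -> list[str]:
    """Choose the k most distinguishable states via a quick preliminary run.

    Fits the KPCA+Ridge pipeline on the interpolated 50-state IMU variant
    and returns the k states with the highest per-class recall on the
    held-out events.
    """
    variant = build_dataset_variant(sessions, "interpolate", 50, "imu")
    split = split_train_test(variant, 0.7, seed, "event")
    Xtr, ytr = split.arrays("train")
    Xte, yte = split.arrays("test")
    res = KPCARidgeClassifier(Xtr, ytr, gamma=gamma, alpha=alpha).fit()
    pred = res.predict(Xte)
    vocab = split.vocabulary
    cm = confusion([vocab[i] for i in yte], [vocab[i] for i in pred], vocab)
    return select_top_states(cm, k)


def export_sankey(flow: StateFlowMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(flow.to_sankey_json(), indent=2))
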