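"""Evaluation protocol: one-vs-all metrics, balanced repeated holdout, the
per-pair (metric, k) grid search, and the rank-of-true-group distribution.

Per class the multiclass result is binarized one-vs-all and scored by
sensitivity TPR = TP/P, specificity SPC = TN/N, precision PPV = TP/(TP+FP)
and accuracy ACC = (TP+TN)/(P+N); the overall figure of merit is the macro
average accuracy, the unweighted mean of the per-class accuracies.

Cross-validation is balanced repeated holdout: in each of the (default 20)
iterations a reference set of 20 maps per group (280 total) and a *disjoint*
experimental set of the same size are drawn, the experimental maps are
classified with the two-stage pipeline against that reference, and the
characteristic rates are averaged over iterations at the rate level.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import CDDM
from .labels import CANONICAL_ORDER, N_CLASSES, HeartStateLabel
from .pipeline import ClassificationTrace, classify_batch
from .rules import EscalationTables, load_default_tables
from .stage2 import (
    PairParams,
    PairParamsRegistry,
    extract_features,
    knn_vote,
    load_default_registry,
)

METRIC_NAMES = ("ACC", "PPV", "TPR", "SPC")


class UndefinedMetricError(ValueError):
    """Raised when P = 0 or N = 0 makes TPR or SPC undefined for a class."""


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-all counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def one_vs_all_metrics(counts: ConfusionCounts, class_name: str = "") -> dict[str, float]:
    """TPR, SPC, PPV, ACC for one class; PPV uses the 0/0 → 0 convention."""
    if counts.p == 0 or counts.n == 0:
        raise UndefinedMetricError(
            f"class {class_name or '?'}: P={counts.p}, N={counts.n} leaves "
            "sensitivity or specificity undefined"
        )
    ppv = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 0.0
    return {
        "TPR": counts.tp / counts.p,
        "SPC": counts.tn / counts.n,
        "PPV": ppv,
        "ACC": (counts.tp + counts.tn) / counts.total,
    }


def macro_average_accuracy(rows: list[ConfusionCounts], l: int | None = None) -> float:
    """Unweighted mean of per-class one-vs-all accuracies."""
    if l is None:
        l = len(rows)
    if l == 0 or not rows:
        raise ValueError("need at least one class")
    if l != len(rows):
        raise ValueError(f"l={l} does not match {len(rows)} class rows")
    return float(np.mean([(r.tp + r.tn) / r.total for r in rows]))


def counts_from_predictions(
    true_labels: list[HeartStateLabel], predicted: list[HeartStateLabel]
) -> dict[HeartStateLabel, ConfusionCounts]:
    """One-vs-all counts per class from paired label lists."""
    if len(true_labels) != len(predicted):
        raise ValueError("true/predicted length mismatch")
    t = np.array([CANONICAL_ORDER.index(lab) for lab in true_labels])
    p = np.array([CANONICAL_ORDER.index(lab) for lab in predicted])
    out = {}
    for i, lab in enumerate(CANONICAL_ORDER):
        tp = int(np.sum((t == i) & (p == i)))
        fn = int(np.sum((t == i) & (p != i)))
        fp = int(np.sum((t != i) & (p == i)))
        tn = int(np.sum((t != i) & (p != i)))
        out[lab] = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return out


def confusion_matrix(
    true_labels: list[HeartStateLabel], predicted: list[HeartStateLabel]
) -> pd.DataFrame:
    """14×14 count matrix, rows = true class, columns = predicted class."""
    mat = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(true_labels, predicted):
        mat[CANONICAL_ORDER.index(t), CANONICAL_ORDER.index(p)] += 1
    names = [lab.value for lab in CANONICAL_ORDER]
    return pd.DataFrame(mat, index=names, columns=names)


def rank_distribution(traces: list[ClassificationTrace]) -> np.ndarray:
    """Fraction of queries whose true label sits at stage-1 rank r = 1..14."""
    if not traces:
        raise ValueError("no traces")
    counts = np.zeros(N_CLASSES, dtype=float)
    for t in traces:
        if t.true_label is None:
            raise ValueError(f"trace {t.map_id!r} has no true label")
        rank = [lab for lab, _ in t.ranked.entries].index(t.true_label)
        counts[rank] += 1
    return counts / counts.sum()


@dataclass
class EvaluationReport:
    """Aggregated cross-validation result.

    ``per_class`` rows carry the iteration-averaged ACC/PPV/TPR/SPC of the
    two-stage classifier; ``macro`` their unweighted means (macro average
    accuracy first).  ``stage1_macro`` holds the same macro figures for the
    stage-1-only labels, for the one-stage/two-stage comparison.
    """

    per_class: pd.DataFrame
    macro: dict[str, float]
    stage1_macro: dict[str, float]
    confusion: pd.DataFrame
    stage1_confusion: pd.DataFrame
    rank_distribution: np.ndarray
    escalation_rate: float
    n_iterations: int

    @property
    def top3_fraction(self) -> float:
        return float(self.rank_distribution[:3].sum())


def _balanced_split(
    by_label: dict[HeartStateLabel, list[int]],
    per_group: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Disjoint balanced (reference, experimental) index draws."""
    ref: list[int] = []
    exp: list[int] = []
    for lab in CANONICAL_ORDER:
        idx = np.array(by_label[lab])
        perm = rng.permutation(len(idx))
        ref.extend(idx[perm[:per_group]].tolist())
        exp.extend(idx[perm[per_group : 2 * per_group]].tolist())
    return ref, exp


def _check_cohort(maps: list[CDDM], per_group: int, need: int) -> dict:
    by_label: dict[HeartStateLabel, list[int]] = {}
    for i, m in enumerate(maps):
        if m.label is None:
            raise ValueError(f"cohort map {m.map_id!r} has no label")
        by_label.setdefault(m.label, []).append(i)
    for lab in CANONICAL_ORDER:
        have = len(by_label.get(lab, []))
        if have < need:
            raise ValueError(
                f"label {lab.value}: need >= {need} maps, found {have} "
                f"(shortfall {need - have})"
            )
    return by_label


def _rates_frame(
    counts: dict[HeartStateLabel, ConfusionCounts]
) -> pd.DataFrame:
    rows = {
        lab.value: one_vs_all_metrics(c, lab.value) for lab, c in counts.items()
    }
    return pd.DataFrame(rows).T[list(METRIC_NAMES)]


def cross_validate(
    cohort: list[CDDM],
    iterations: int = 20,
    per_group: int = 20,
    m: int = 3,
    tables: EscalationTables | None = None,
    registry: PairParamsRegistry | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Balanced repeated holdout evaluation of the two-stage classifier.

    Each iteration draws disjoint balanced reference and experimental sets
    (``per_group`` maps per class each) and classifies the experimental set
    against the reference.  Rates are averaged over iterations; confusion
    counts and the rank distribution are pooled.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    tables = tables if tables is not None else load_default_tables()
    registry = registry if registry is not None else load_default_registry()
    by_label = _check_cohort(cohort, per_group, need=2 * per_group)
    rng = np.random.default_rng(seed)

    per_iter_final: list[pd.DataFrame] = []
    per_iter_stage1: list[pd.DataFrame] = []
    all_traces: list[ClassificationTrace] = []
    true_all: list[HeartStateLabel] = []
    final_all: list[HeartStateLabel] = []
    stage1_all: list[HeartStateLabel] = []
    n_escalated = 0

    for _ in range(iterations):
        ref_idx, exp_idx = _balanced_split(by_label, per_group, rng)
        assert not set(ref_idx) & set(exp_idx)
        reference = [cohort[i] for i in ref_idx]
        queries = [cohort[i] for i in exp_idx]
        traces = classify_batch(queries, reference, tables, registry, m)
        all_traces.extend(traces)
        truth = [t.true_label for t in traces]
        final = [t.final_label for t in traces]
        stage1 = [t.stage1_label for t in traces]
        true_all.extend(truth)
        final_all.extend(final)
        stage1_all.extend(stage1)
        n_escalated += sum(t.decision.escalate for t in traces)
        per_iter_final.append(_rates_frame(counts_from_predictions(truth, final)))
        per_iter_stage1.append(_rates_frame(counts_from_predictions(truth, stage1)))

    per_class = sum(per_iter_final) / iterations
    per_class_s1 = sum(per_iter_stage1) / iterations
    macro = {name: float(per_class[name].mean()) for name in METRIC_NAMES}
    stage1_macro = {name: float(per_class_s1[name].mean()) for name in METRIC_NAMES}
    return EvaluationReport(
        per_class=per_class,
        macro=macro,
        stage1_macro=stage1_macro,
        confusion=confusion_matrix(true_all, final_all),
        stage1_confusion=confusion_matrix(true_all, stage1_all),
        rank_distribution=rank_distribution(all_traces),
        escalation_rate=n_escalated / len(all_traces),
        n_iterations=iterations,
    )


# ---------------------------------------------------------------------------
# Per-pair (metric, k) grid search
# ---------------------------------------------------------------------------

#: Tie-break order over metrics in the grid search.
SWEEP_METRIC_ORDER = ("cityblock", "euclidean", "chebyshev")


def sweep_pair_params(
    cohort: list[CDDM],
    pair: tuple[HeartStateLabel, HeartStateLabel],
    k_values: range = range(1, 16),
    metrics: tuple[str, ...] = SWEEP_METRIC_ORDER,
    iterations: int = 20,
    per_group: int = 20,
    seed: int = 0,
) -> tuple[PairParams, pd.DataFrame]:
    """Grid search over (metric, k) for one binary duel.

    Returns the best setting (highest mean binary accuracy; ties broken by
    smaller k, then metric order cityblock < euclidean < chebyshev) and the
    full mean-accuracy table, one row per (metric, k).
    """
    a, b = pair
    if a == b:
        raise ValueError("pair must be two distinct labels")
    sub = [m for m in cohort if m.label in (a, b)]
    by_label = _check_cohort_pair(sub, (a, b), need=2 * per_group)
    rng = np.random.default_rng(seed)
    k_list = list(k_values)
    acc = {(met, k): [] for met in metrics for k in k_list}
    for _ in range(iterations):
        ref_idx, exp_idx = _balanced_split_pair(by_label, per_group, rng)
        ref_feats = [(extract_features(sub[i]), sub[i].label) for i in ref_idx]
        exp_feats = [(extract_features(sub[i]), sub[i].label) for i in exp_idx]
        for met in metrics:
            for k in k_list:
                correct = sum(
                    knn_vote(f, ref_feats, k, met) == lab for f, lab in exp_feats
                )
                acc[(met, k)].append(correct / len(exp_feats))
    rows = [
        {"metric": met, "k": k, "mean_accuracy": float(np.mean(acc[(met, k)]))}
        for met in metrics
        for k in k_list
    ]
    table = pd.DataFrame(rows)
    best = max(
        rows,
        key=lambda r: (
            r["mean_accuracy"],
            -r["k"],
            -SWEEP_METRIC_ORDER.index(r["metric"]),
        ),
    )
    params = PairParams(pair=frozenset(pair), metric=best["metric"], k=best["k"])
    return params, table


def sweep_all_pairs(
    cohort: list[CDDM],
    k_values: range = range(1, 16),
    metrics: tuple[str, ...] = SWEEP_METRIC_ORDER,
    iterations: int = 20,
    per_group: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid-search every unordered pair of the 14 groups.

    Returns a registry-format table (group1, group2, metric, k, plus the
    winning mean accuracy) that can be written out and loaded back with
    :class:`~cddmclass.stage2.PairParamsRegistry`.
    """
    rows = []
    for i, a in enumerate(CANONICAL_ORDER):
        for b in CANONICAL_ORDER[i + 1 :]:
            best, table = sweep_pair_params(
                cohort, (a, b), k_values=k_values, metrics=metrics,
                iterations=iterations, per_group=per_group, seed=seed,
            )
            rows.append(
                {
                    "group1": a.value,
                    "group2": b.value,
                    "metric": best.metric,
                    "k": best.k,
                    "mean_accuracy": float(table["mean_accuracy"].max()),
                }
            )
    return pd.DataFrame(rows)


def _check_cohort_pair(
    maps: list[CDDM], pair: tuple[HeartStateLabel, HeartStateLabel], need: int
) -> dict:
    by_label: dict[HeartStateLabel, list[int]] = {}
    for i, m in enumerate(maps):
        by_label.setdefault(m.label, []).append(i)
    for lab in pair:
        have = len(by_label.get(lab, []))
        if have < need:
            raise ValueError(
                f"label {lab.value}: need >= {need} maps, found {have}"
            )
    return by_label


def _balanced_split_pair(
    by_label: dict[HeartStateLabel, list[int]],
    per_group: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    ref: list[int] = []
    exp: list[int] = []
    for lab in sorted(by_label):
        idx = np.array(by_label[lab])
        perm = rng.permutation(len(idx))
        ref.extend(idx[perm[:per_group]].tolist())
        exp.extend(idx[perm[per_group : 2 * per_group]].tolist())
    return ref, exp


# ---------------------------------------------------------------------------
# Published per-group characteristics (worked example for macro averaging)
# ---------------------------------------------------------------------------


def load_reported_group_metrics() -> pd.DataFrame:
    """Packaged per-group ACC/PPV/TPR/SPC of the original clinical study."""
    ref = resources.files("cddmclass.data") / "reported_group_metrics.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", comment="#")
    return table.set_index("group")


def macro_averages(per_class: pd.DataFrame) -> dict[str, float]:
    """Unweighted column means of a per-class metric table."""
    return {col: float(per_class[col].mean()) for col in per_class.columns}
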