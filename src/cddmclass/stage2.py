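"""Stage 2: pairwise k-NN refinement on quadrant statistical-moment features.

Each map is divided into four equal quarters; in every quarter the mean,
variance, kurtosis and skewness of the magnitudes and of the angles are
computed, giving a 32-dimensional feature vector (4 quadrants × 2 channels ×
4 moments).  The binary k-NN duel between two candidate groups uses one of
three Minkowski-family metrics — Euclidean (L2), Cityblock/Manhattan (L1) or
Chebyshev (L∞) — with a per-pair (metric, k) setting kept in a registry; the
packaged defaults carry the settings found by per-pair grid search on the
original clinical cohort, with (cityblock, 1) for every unlisted pair.

Moment conventions (frozen): population variance (divisor N); kurtosis is
non-excess, so a normal sample gives ≈ 3; skewness is the standardized third
moment.  A constant sample has variance 0 and, by convention, skewness 0 and
kurtosis 0 (the standardized moments are 0/0 there).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CDDM, split_quadrants
from .labels import HeartStateLabel, parse_label

N_FEATURES = 32

#: Canonical metric codes and the alias spellings accepted in registry files.
METRICS = ("euclidean", "cityblock", "chebyshev")
_METRIC_ALIASES = {
    "euclidean": "euclidean",
    "eucledian": "euclidean",  # spelling used in some sources
    "l2": "euclidean",
    "cityblock": "cityblock",
    "manhattan": "cityblock",
    "l1": "cityblock",
    "chebyshev": "chebyshev",
    "chebychev": "chebyshev",
    "linf": "chebyshev",
}


def normalize_metric(name: str) -> str:
    try:
        return _METRIC_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; expected one of {list(METRICS)} or an alias"
        ) from None


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, population variance, non-excess kurtosis, skewness)."""
    v = np.asarray(values, dtype=float).ravel()
    mean = v.mean()
    dev = v - mean
    var = float((dev**2).mean())
    if var == 0.0:
        return float(mean), 0.0, 0.0, 0.0
    sd = np.sqrt(var)
    skew = float((dev**3).mean() / sd**3)
    kurt = float((dev**4).mean() / var**2)
    return float(mean), var, kurt, skew


def extract_features(cddm: CDDM) -> np.ndarray:
    """32-dim feature vector.

    Layout (frozen): for each quadrant Q1..Q4 (row-major, top-left first),
    for each channel (magnitude then angle): mean, variance, kurtosis,
    skewness.
    """
    feats: list[float] = []
    for mag_q, ang_q in split_quadrants(cddm):
        for channel in (mag_q, ang_q):
            mean, var, kurt, skew = _moments(channel)
            feats.extend((mean, var, kurt, skew))
    return np.asarray(feats, dtype=float)


def distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Distance between feature vectors under one of the three metrics.

    Euclidean is returned as the root of the summed squared differences
    (ordering-equivalent to the squared form, and a true metric so the
    triangle inequality holds).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    diff = np.abs(x - y)
    metric = normalize_metric(metric)
    if metric == "euclidean":
        return float(np.sqrt((diff**2).sum()))
    if metric == "cityblock":
        return float(diff.sum())
    return float(diff.max())


def knn_vote(
    query: np.ndarray,
    training: list[tuple[np.ndarray, HeartStateLabel]],
    k: int,
    metric: str,
) -> HeartStateLabel:
    """Majority label among the k nearest training points (binary).

    Distance ties are broken by stable training order; an even split of the
    k labels is resolved in favour of the single nearest neighbour.
    """
    if not training:
        raise ValueError("training set is empty")
    if k < 1 or k > len(training):
        raise ValueError(f"k must be in [1, {len(training)}], got {k}")
    labels = {lab for _, lab in training}
    if len(labels) != 2:
        raise ValueError(
            f"binary k-NN requires exactly 2 distinct labels, got {sorted(l.value for l in labels)}"
        )
    dists = np.array([distance(query, feat, metric) for feat, _ in training])
    order = np.argsort(dists, kind="stable")
    top = [training[i][1] for i in order[:k]]
    counts = Counter(top)
    (lab1, n1), *rest = counts.most_common()
    if rest and rest[0][1] == n1:  # even split -> nearest neighbour decides
        return top[0]
    return lab1


@dataclass(frozen=True)
class PairParams:
    """(metric, k) for one unordered pair of groups."""

    pair: frozenset[HeartStateLabel]
    metric: str
    k: int

    def __post_init__(self) -> None:
        if self.pair and len(self.pair) != 2:
            raise ValueError("pair must hold exactly two distinct labels")
        if not 1 <= self.k <= 15:
            raise ValueError(f"k must be in [1, 15], got {self.k}")
        object.__setattr__(self, "metric", normalize_metric(self.metric))


DEFAULT_PAIR_PARAMS = ("cityblock", 1)


class PairParamsRegistry:
    """Per-pair (metric, k) lookup with a default for unlisted pairs.

    The registry file is a tab-separated table with columns ``group1``,
    ``group2``, ``metric``, ``k``; a row with group1 = ``OTHER_PAIRS``
    overrides the default.  Lookup is symmetric in the pair.
    """

    def __init__(
        self,
        entries: dict[frozenset[HeartStateLabel], tuple[str, int]],
        default: tuple[str, int] = DEFAULT_PAIR_PARAMS,
    ):
        self._entries = {
            pair: (normalize_metric(metric), int(k))
            for pair, (metric, k) in entries.items()
        }
        self._default = (normalize_metric(default[0]), int(default[1]))

    def lookup(self, a: HeartStateLabel, b: HeartStateLabel) -> PairParams:
        if a == b:
            raise ValueError(f"pair must be two distinct labels, got {a.value} twice")
        pair = frozenset((a, b))
        metric, k = self._entries.get(pair, self._default)
        return PairParams(pair=pair, metric=metric, k=k)

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "PairParamsRegistry":
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"group1", "group2", "metric", "k"}
        if not required.issubset(table.columns):
            raise ValueError(
                f"{path}: registry needs columns {sorted(required)}, "
                f"got {list(table.columns)}"
            )
        entries: dict[frozenset[HeartStateLabel], tuple[str, int]] = {}
        default = DEFAULT_PAIR_PARAMS
        for row in table.itertuples(index=False):
            metric = normalize_metric(str(row.metric))
            k = int(row.k)
            if str(row.group1).strip().upper() in ("OTHER_PAIRS", "OTHER PAIRS"):
                default = (metric, k)
                continue
            pair = frozenset((parse_label(str(row.group1)), parse_label(str(row.group2))))
            if len(pair) != 2:
                raise ValueError(f"{path}: pair rows need two distinct groups: {row}")
            entries[pair] = (metric, k)
        return cls(entries, default)


def load_default_registry() -> PairParamsRegistry:
    """Packaged per-pair registry (clinical-cohort grid-search settings)."""
    ref = resources.files("cddmclass.data") / "pair_params.tsv"
    with resources.as_file(ref) as path:
        return PairParamsRegistry.from_file(path)


def classify_pair(
    query: CDDM,
    reference: list[CDDM],
    pair: tuple[HeartStateLabel, HeartStateLabel],
    params: PairParams,
) -> HeartStateLabel:
    """Binary k-NN duel between the two groups of ``pair``.

    The training set is every reference map carrying one of the two labels,
    in reference order.
    """
    a, b = pair
    training = [
        (extract_features(ref), ref.label)
        for ref in reference
        if ref.label in (a, b)
    ]
    if len(training) < params.k:
        raise ValueError(
            f"insufficient training maps for pair ({a.value}, {b.value}): "
            f"need >= {params.k}, found {len(training)}"
        )
    return knn_vote(extract_features(query), training, params.k, params.metric)
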