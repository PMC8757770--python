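"""Stage 1: multiclass ranking by the resulting correlation coefficient.

For a query map and each reference map, the Pearson correlation is computed
separately for the flattened magnitude vectors and the flattened angle
vectors, and the two coefficients are multiplied.  This *resulting*
correlation rewards agreement in both the strength and the direction of the
current density field.  Per group, the m largest resulting correlations are
averaged (m = 3 by default); groups are ranked by that score in descending
order and the top-ranked group is the stage-1 class.

Degenerate-variance convention: Pearson correlation is undefined for a
constant vector, so a zero-variance argument yields r = 0 — "no variation"
is read as "no evidence of similarity", which keeps the pipeline total.

Angles are plain reals wrapped into (−π, π]; no circular correlation is
attempted, so fields straddling the ±π branch cut can correlate lower than
their geometric similarity suggests (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CDDM, MapValidationError
from .labels import CANONICAL_ORDER, HeartStateLabel


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between two maps: per-channel Pearson r and their product."""

    r_magnitude: float
    r_angle: float
    r_resulting: float
    against_map_id: str = ""


@dataclass(frozen=True)
class RankedGroups:
    """Stage-1 output: all 14 (label, score) pairs, scores non-increasing."""

    entries: tuple[tuple[HeartStateLabel, float], ...]
    m_used: int

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if sorted(labels, key=CANONICAL_ORDER.index) != sorted(
            CANONICAL_ORDER, key=CANONICAL_ORDER.index
        ):
            raise ValueError("ranking must contain each of the 14 labels exactly once")
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    @property
    def top(self) -> HeartStateLabel:
        return self.entries[0][0]

    def top_k_labels(self, k: int) -> tuple[HeartStateLabel, ...]:
        return tuple(lab for lab, _ in self.entries[:k])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Returns 0.0 if either vector has zero variance (see module docstring).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("pearson requires vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    # clip guards against tiny float excursions outside [-1, 1]
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def resulting_correlation(a: CDDM, b: CDDM) -> CorrelationResult:
    """Product of the magnitude-channel and angle-channel Pearson r."""
    if a.shape != b.shape:
        raise MapValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    r_mag = pearson(a.magnitude.ravel(), b.magnitude.ravel())
    r_ang = pearson(a.angle.ravel(), b.angle.ravel())
    return CorrelationResult(
        r_magnitude=r_mag,
        r_angle=r_ang,
        r_resulting=r_mag * r_ang,
        against_map_id=b.map_id,
    )


def top_m_mean(values: np.ndarray, m: int) -> float:
    """Mean of the min(m, len) largest values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot score an empty group")
    if m < 1:
        raise ValueError("m must be >= 1")
    take = min(m, values.size)
    top = np.sort(values)[-take:]
    return float(top.mean())


def group_score(query: CDDM, group_refs: list[CDDM], m: int = 3) -> float:
    """Average of the m largest resulting correlations against one group."""
    if not group_refs:
        raise ValueError("cannot score an empty reference group")
    rs = np.array([resulting_correlation(query, ref).r_resulting for ref in group_refs])
    return top_m_mean(rs, m)


# ---------------------------------------------------------------------------
# Vectorized internals shared by rank_groups and the batch pipeline.
# ---------------------------------------------------------------------------


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    """Center and scale each row so that z @ z.T / n is the Pearson matrix.

    Zero-variance rows become all-zero rows (correlation 0 with anything,
    matching the degenerate-variance convention).
    """
    mat = np.asarray(mat, dtype=float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, centered / norm, 0.0)
    return z


def resulting_correlation_matrix(
    queries: list[CDDM], refs: list[CDDM]
) -> np.ndarray:
    """len(queries) × len(refs) matrix of resulting correlations."""
    qm = _zscore_rows(np.stack([q.magnitude.ravel() for q in queries]))
    qa = _zscore_rows(np.stack([q.angle.ravel() for q in queries]))
    rm = _zscore_rows(np.stack([r.magnitude.ravel() for r in refs]))
    ra = _zscore_rows(np.stack([r.angle.ravel() for r in refs]))
    prod = (qm @ rm.T) * (qa @ ra.T)
    return np.clip(prod, -1.0, 1.0)


def _group_refs(reference: list[CDDM]) -> dict[HeartStateLabel, list[int]]:
    by_label: dict[HeartStateLabel, list[int]] = {}
    for i, ref in enumerate(reference):
        if ref.label is None:
            raise ValueError(f"reference map {ref.map_id!r} has no label")
        by_label.setdefault(ref.label, []).append(i)
    missing = [lab.value for lab in CANONICAL_ORDER if lab not in by_label]
    if missing:
        raise ValueError(f"reference set is missing label(s): {missing}")
    return by_label


def _rank_from_scores(
    scores: dict[HeartStateLabel, float], m: int
) -> RankedGroups:
    # descending score; ties broken by canonical label order
    ordered = sorted(
        scores.items(), key=lambda kv: (-kv[1], CANONICAL_ORDER.index(kv[0]))
    )
    return RankedGroups(entries=tuple(ordered), m_used=m)


def rank_groups(query: CDDM, reference: list[CDDM], m: int = 3) -> RankedGroups:
    """Score the query against all 14 groups and rank them descending.

    ``reference`` must contain at least one labeled map per group.
    """
    by_label = _group_refs(reference)
    corr = resulting_correlation_matrix([query], reference)[0]
    scores = {lab: top_m_mean(corr[idx], m) for lab, idx in by_label.items()}
    return _rank_from_scores(scores, m)


def rank_groups_batch(
    queries: list[CDDM], reference: list[CDDM], m: int = 3
) -> list[RankedGroups]:
    """Vectorized :func:`rank_groups` over many queries (same result)."""
    by_label = _group_refs(reference)
    corr = resulting_correlation_matrix(queries, reference)
    out = []
    for row in corr:
        scores = {lab: top_m_mean(row[idx], m) for lab, idx in by_label.items()}
        out.append(_rank_from_scores(scores, m))
    return out


def classify_stage1(query: CDDM, reference: list[CDDM], m: int = 3) -> HeartStateLabel:
    """Stage-1 class: the top-ranked group."""
    return rank_groups(query, reference, m).top
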