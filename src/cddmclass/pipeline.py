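"""End-to-end two-stage classification with a full decision trace.

Stage 1 ranks the 14 groups by the resulting correlation coefficient; the
rule engine checks the top three groups against the escalation tables; when
a rule fires, a single binary k-NN duel between the top group and the
matched confusable group decides the final label; otherwise the stage-1
label stands.  Every classification emits a :class:`ClassificationTrace`
carrying the whole evidence chain (ranking, rule fired, pair, duel result),
because which rule fired *is* the method — the trace is the audit surface.

The same reference set serves both stages: stage 1 correlates against all
of it, stage 2 trains on the subset carrying the duel's two labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CDDM
from .labels import CANONICAL_ORDER, HeartStateLabel
from .rules import EscalationDecision, EscalationTables, decide_escalation
from .stage1 import RankedGroups, rank_groups_batch
from .stage2 import PairParams, PairParamsRegistry, extract_features, knn_vote


@dataclass(frozen=True)
class ClassificationTrace:
    """Evidence chain for one query map."""

    map_id: str
    true_label: HeartStateLabel | None
    ranked: RankedGroups
    decision: EscalationDecision
    pair_params_used: PairParams | None
    stage2_label: HeartStateLabel | None
    final_label: HeartStateLabel

    @property
    def stage1_label(self) -> HeartStateLabel:
        return self.ranked.top

    def __post_init__(self) -> None:
        if not self.decision.escalate:
            if self.final_label != self.ranked.top or self.stage2_label is not None:
                raise ValueError("non-escalated trace must keep the stage-1 label")
        else:
            if self.final_label != self.stage2_label:
                raise ValueError("escalated trace must carry the stage-2 label")


class ReferenceIndex:
    """Reference set with cached per-stage representations.

    Caches the standardized stage-1 vectors and the 32-dim stage-2 features
    of every reference map, so batch classification does the expensive work
    once.  Reference order is preserved (it is the distance-tie order).
    """

    def __init__(self, reference: list[CDDM]):
        if not reference:
            raise ValueError("reference set is empty")
        self.maps = list(reference)
        self.labels = [m.label for m in self.maps]
        missing = [
            lab.value for lab in CANONICAL_ORDER if lab not in set(self.labels)
        ]
        if missing:
            raise ValueError(f"reference set is missing label(s): {missing}")
        self._features: np.ndarray | None = None

    @property
    def features(self) -> np.ndarray:
        if self._features is None:
            self._features = np.stack([extract_features(m) for m in self.maps])
        return self._features

    def pair_training(
        self, pair: frozenset[HeartStateLabel]
    ) -> list[tuple[np.ndarray, HeartStateLabel]]:
        feats = self.features
        return [
            (feats[i], lab) for i, lab in enumerate(self.labels) if lab in pair
        ]


def _stage2_duel(
    query: CDDM,
    index: ReferenceIndex,
    decision: EscalationDecision,
    registry: PairParamsRegistry,
) -> tuple[PairParams, HeartStateLabel]:
    a, b = sorted(decision.pair)
    params = registry.lookup(a, b)
    training = index.pair_training(decision.pair)
    if len(training) < params.k:
        raise ValueError(
            f"insufficient training maps for pair ({a.value}, {b.value}): "
            f"need >= {params.k}, found {len(training)}"
        )
    label = knn_vote(extract_features(query), training, params.k, params.metric)
    return params, label


def classify_two_stage(
    query: CDDM,
    reference: list[CDDM] | ReferenceIndex,
    tables: EscalationTables,
    registry: PairParamsRegistry,
    m: int = 3,
) -> ClassificationTrace:
    """Classify one map and return its full trace."""
    return classify_batch([query], reference, tables, registry, m)[0]


def classify_batch(
    queries: list[CDDM],
    reference: list[CDDM] | ReferenceIndex,
    tables: EscalationTables,
    registry: PairParamsRegistry,
    m: int = 3,
) -> list[ClassificationTrace]:
    """Classify many maps; output order equals input order."""
    if not queries:
        return []
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    rankings = rank_groups_batch(queries, index.maps, m)
    traces = []
    for query, ranked in zip(queries, rankings):
        decision = decide_escalation(ranked, tables)
        params: PairParams | None = None
        stage2_label: HeartStateLabel | None = None
        if decision.escalate:
            params, stage2_label = _stage2_duel(query, index, decision, registry)
            final = stage2_label
        else:
            final = ranked.top
        traces.append(
            ClassificationTrace(
                map_id=query.map_id,
                true_label=query.label,
                ranked=ranked,
                decision=decision,
                pair_params_used=params,
                stage2_label=stage2_label,
                final_label=final,
            )
        )
    return traces


def traces_to_table(traces: list[ClassificationTrace]) -> pd.DataFrame:
    """Predictions table: one row per query, full decision summary."""
    rows = []
    for t in traces:
        pair = "" if t.decision.pair is None else "|".join(
            lab.value for lab in sorted(t.decision.pair)
        )
        rows.append(
            {
                "map_id": t.map_id,
                "true_label": "" if t.true_label is None else t.true_label.value,
                "stage1_label": t.stage1_label.value,
                "escalated": int(t.decision.escalate),
                "rule_fired": t.decision.rule_fired.value,
                "pair": pair,
                "stage2_label": "" if t.stage2_label is None else t.stage2_label.value,
                "final_label": t.final_label.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "map_id",
            "true_label",
            "stage1_label",
            "escalated",
            "rule_fired",
            "pair",
            "stage2_label",
            "final_label",
        ],
    )
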