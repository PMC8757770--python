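"""Escalation rules: when does a stage-1 ranking proceed to the k-NN duel?

On the original clinical cohort the correlation ranking showed two failure
modes: a handful of groups attract false positives (low precision: LVH1,
LVH2, LVH3, CAD3, NORM1) and a handful lose their own members to specific
neighbours (low sensitivity: NORM2, MVD_F, MVD_M, NONCOR, LVH2, CAD2).  For
each such group the historically confusable partners are tabulated.  A query
escalates to stage 2 when its top-ranked group is one of these keys AND the
2nd- or 3rd-ranked group is one of that key's confusable partners; the k-NN
duel is then fought between the top group and the matched partner.

Precedence (frozen): the low-precision condition is checked before the
low-sensitivity one (only LVH2 appears in both key sets), and within a
condition a rank-2 match beats a rank-3 match — the higher-correlated group
is the stronger confusion candidate.  Exactly one duel is run per query.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .labels import HeartStateLabel, parse_label
from .stage1 import RankedGroups


class RuleType(enum.Enum):
    NONE = "none"
    LOW_PRECISION = "low_precision"
    LOW_SENSITIVITY = "low_sensitivity"


@dataclass(frozen=True)
class EscalationTables:
    """Confusable-partner tables keyed by the problematic group."""

    low_precision: dict[HeartStateLabel, frozenset[HeartStateLabel]]
    low_sensitivity: dict[HeartStateLabel, frozenset[HeartStateLabel]]

    @classmethod
    def from_file(cls, path: str | Path) -> "EscalationTables":
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"rule_type", "key_label", "candidate_label"}
        if not required.issubset(table.columns):
            raise ValueError(
                f"{path}: rules file needs columns {sorted(required)}, "
                f"got {list(table.columns)}"
            )
        buckets: dict[str, dict[HeartStateLabel, set[HeartStateLabel]]] = {
            "low_precision": {},
            "low_sensitivity": {},
        }
        for row in table.itertuples(index=False):
            rtype = str(row.rule_type).strip().lower()
            if rtype not in buckets:
                raise ValueError(f"{path}: unknown rule_type {row.rule_type!r}")
            key = parse_label(str(row.key_label))
            cand = parse_label(str(row.candidate_label))
            buckets[rtype].setdefault(key, set()).add(cand)
        return cls(
            low_precision={k: frozenset(v) for k, v in buckets["low_precision"].items()},
            low_sensitivity={k: frozenset(v) for k, v in buckets["low_sensitivity"].items()},
        )


def load_default_tables() -> EscalationTables:
    """Packaged confusion tables observed on the original clinical cohort."""
    ref = resources.files("cddmclass.data") / "escalation_rules.tsv"
    with resources.as_file(ref) as path:
        return EscalationTables.from_file(path)


@dataclass(frozen=True)
class EscalationDecision:
    """Outcome of the rule check for one ranking."""

    escalate: bool
    rule_fired: RuleType
    pair: frozenset[HeartStateLabel] | None
    matched_rank: int | None  # 2 or 3 when escalating

    def __post_init__(self) -> None:
        if self.escalate != (self.rule_fired is not RuleType.NONE) or self.escalate != (
            self.pair is not None
        ):
            raise ValueError("inconsistent escalation decision")


NO_ESCALATION = EscalationDecision(
    escalate=False, rule_fired=RuleType.NONE, pair=None, matched_rank=None
)


def decide_escalation(
    ranked: RankedGroups, tables: EscalationTables
) -> EscalationDecision:
    """Apply the two escalation conditions to the top three ranked groups."""
    if len(ranked.entries) != 14:
        raise ValueError("ranking must contain all 14 groups")
    g1, g2, g3 = ranked.top_k_labels(3)
    for rule, table in (
        (RuleType.LOW_PRECISION, tables.low_precision),
        (RuleType.LOW_SENSITIVITY, tables.low_sensitivity),
    ):
        if g1 not in table:
            continue
        candidates = table[g1]
        for rank, g in ((2, g2), (3, g3)):
            if g in candidates:
                return EscalationDecision(
                    escalate=True,
                    rule_fired=rule,
                    pair=frozenset((g1, g)),
                    matched_rank=rank,
                )
    return NO_ESCALATION
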