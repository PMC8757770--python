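"""Heart-state class labels and the alias table used when parsing cohort files.

The classifier distinguishes 14 heart states: two normal groups (healthy
volunteers and sportsmen), myocardial damage, non-coronarogenic diseases,
microvascular (diffuse) disease split by sex, five grades of coronary artery
disease (CAD1 lightest .. CAD5 hardest) and three grades of left ventricular
hypertrophy (LVH1 lightest .. LVH3 hardest).

The literature uses several synonyms for the same groups (IHD for CAD,
DIFFm/DIFFf for the microvascular groups, REUMO for non-coronarogenic
diseases); :func:`parse_label` resolves all of them to the canonical code and
rejects anything else.
"""

from __future__ import annotations

import enum


class HeartStateLabel(enum.Enum):
    """Canonical codes for the 14 heart-state groups.

    Enum definition order is the canonical label order used for deterministic
    tie-breaking throughout the package.
    """

    NORM1 = "NORM1"
    NORM2 = "NORM2"
    MDAM = "MDAM"
    NONCOR = "NONCOR"
    MVD_M = "MVD_M"
    MVD_F = "MVD_F"
    CAD1 = "CAD1"
    CAD2 = "CAD2"
    CAD3 = "CAD3"
    CAD4 = "CAD4"
    CAD5 = "CAD5"
    LVH1 = "LVH1"
    LVH2 = "LVH2"
    LVH3 = "LVH3"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    def __lt__(self, other: "HeartStateLabel") -> bool:
        if not isinstance(other, HeartStateLabel):
            return NotImplemented
        return CANONICAL_ORDER.index(self) < CANONICAL_ORDER.index(other)

    def __repr__(self) -> str:  # keeps traces/tables compact
        return self.value


#: Canonical, frozen ordering of the label set (ties in rankings are broken
#: by position in this tuple).
CANONICAL_ORDER: tuple[HeartStateLabel, ...] = tuple(HeartStateLabel)

N_CLASSES = len(CANONICAL_ORDER)

_DISPLAY_NAMES = {
    HeartStateLabel.NORM1: "Healthy volunteers",
    HeartStateLabel.NORM2: "Sportsmen",
    HeartStateLabel.MDAM: "Myocardial damage",
    HeartStateLabel.NONCOR: "Non-coronarogenic diseases",
    HeartStateLabel.MVD_M: "Microvascular disease (M)",
    HeartStateLabel.MVD_F: "Microvascular disease (F)",
    HeartStateLabel.CAD1: "CAD1",
    HeartStateLabel.CAD2: "CAD2",
    HeartStateLabel.CAD3: "CAD3",
    HeartStateLabel.CAD4: "CAD4",
    HeartStateLabel.CAD5: "CAD5",
    HeartStateLabel.LVH1: "LVH1",
    HeartStateLabel.LVH2: "LVH2",
    HeartStateLabel.LVH3: "LVH3",
}

# Alias -> canonical code.  Keys are normalised (upper-case, alphanumeric only)
# before lookup, so "Microvascular disease (M)" and "MVD_M" both resolve.
_ALIASES: dict[str, HeartStateLabel] = {
    "NORMAL": HeartStateLabel.NORM1,
    "MYOCARDIALDAMAGE": HeartStateLabel.MDAM,
    "NONCORONAROGENICDISEASES": HeartStateLabel.NONCOR,
    "NONCORONAGENICDISEASES": HeartStateLabel.NONCOR,
    "REUMO": HeartStateLabel.NONCOR,
    "DIFFM": HeartStateLabel.MVD_M,
    "DIFFF": HeartStateLabel.MVD_F,
    "MICROVASCULARDISEASEM": HeartStateLabel.MVD_M,
    "MICROVASCULARDISEASEF": HeartStateLabel.MVD_F,
}
for _i in range(1, 6):
    _ALIASES[f"IHD{_i}"] = HeartStateLabel(f"CAD{_i}")


class UnknownLabelError(ValueError):
    """Raised when a label token cannot be resolved to one of the 14 codes."""


def _normalise(token: str) -> str:
    return "".join(ch for ch in token.upper() if ch.isalnum())


def parse_label(token: str) -> HeartStateLabel:
    """Resolve ``token`` (canonical code or known alias) to a label.

    Raises
    ------
    UnknownLabelError
        If the token is not a canonical code and not in the alias table.
    """
    key = _normalise(token)
    for label in HeartStateLabel:
        if key == _normalise(label.value):
            return label
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnknownLabelError(
        f"unknown heart-state label {token!r}; expected one of "
        f"{[lab.value for lab in HeartStateLabel]} or a known alias"
    )
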