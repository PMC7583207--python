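"""Domain types for individuals, relative pairs, and the cohabitation clock.

The analyses in this package model the similarity of two relatives as a
function of how long they have lived together (``t`` years of shared life so
far, while cohabiting) and how long they have lived apart.  The pair of
numbers ``(t, t0)`` — current position on the shared-life clock and the point
at which the pair stopped cohabiting — is relationship-specific:

* twin pairs (MZ/DZ): ``t`` = chronological age, ``t0`` = age at leaving the
  parental home (default 18);
* sibling pairs: ``t`` = the younger sibling's age, ``t0`` = the younger
  sibling's age when the older turned 18 (clamped at 0 for large age gaps);
* parent-offspring: ``t`` = the offspring's age, ``t0`` = 18;
* spouses: ``t`` = years since marriage (mean age of the pair minus the
  conventional marriage age, default 24), ``t0`` = years married at
  separation if known, otherwise the pair is taken to still cohabit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class RelationshipType(str, Enum):
    """Relative-pair categories supported by the models."""

    MZ = "MZ"
    DZ = "DZ"
    SIB = "SIB"
    PO = "PO"
    SPOUSE = "SPOUSE"

    @property
    def kinship2(self) -> float:
        """Doubled kinship coefficient (coefficient of relationship)."""
        return _KINSHIP2[self]


_KINSHIP2 = {
    RelationshipType.MZ: 1.0,
    RelationshipType.DZ: 0.5,
    RelationshipType.SIB: 0.5,
    RelationshipType.PO: 0.5,
    RelationshipType.SPOUSE: 0.0,
}


@dataclass
class IndividualRecord:
    """One person: identity, demographics and the DNAm-age phenotype."""

    individual_id: str
    family_id: str
    study_id: str
    sex: str  # "female" | "male"
    chronological_age: float
    dnam_age: float
    tissue: Optional[str] = None
    cell_proportions: Optional[Sequence[float]] = None
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chronological_age < 0:
            raise ValueError(
                f"individual {self.individual_id}: chronological_age must be >= 0"
            )
        if self.sex not in ("female", "male"):
            raise ValueError(f"individual {self.individual_id}: sex must be female/male")
        if self.cell_proportions is not None:
            for p in self.cell_proportions:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"individual {self.individual_id}: cell proportion {p} outside [0, 1]"
                    )


@dataclass
class RelativePair:
    """An undirected within-family pair.

    For parent-offspring pairs ``offspring`` names which member (``"a"`` or
    ``"b"``) is the child, so the cohabitation clock can be evaluated from
    the offspring's age.
    """

    a: IndividualRecord
    b: IndividualRecord
    relationship: RelationshipType
    separation_time: Optional[float] = None  # spouses only, years married at separation
    offspring: Optional[str] = None  # "a" | "b", PO pairs only

    def __post_init__(self) -> None:
        if self.a.individual_id == self.b.individual_id:
            raise ValueError("pair members must be distinct individuals")
        if self.a.family_id != self.b.family_id:
            raise ValueError(
                f"pair ({self.a.individual_id}, {self.b.individual_id}): "
                "members must share family_id"
            )
        if self.relationship == RelationshipType.PO and self.offspring not in ("a", "b"):
            raise ValueError(
                f"PO pair ({self.a.individual_id}, {self.b.individual_id}): "
                "offspring member must be 'a' or 'b'"
            )

    @property
    def kinship2(self) -> float:
        return self.relationship.kinship2


@dataclass(frozen=True)
class CohabitationClock:
    """Position (t) and switch point (t0) on a pair's shared-life clock."""

    t: float
    t0: float

    @property
    def regime(self) -> str:
        return "cohabiting" if self.t <= self.t0 else "separated"


def compute_cohabitation_clock(
    pair: RelativePair,
    adult_age: float = 18.0,
    marriage_age: float = 24.0,
) -> CohabitationClock:
    """Evaluate the relationship-specific cohabitation clock for a pair.

    Parameters
    ----------
    pair
        The relative pair; both members must have chronological ages.
    adult_age
        Conventional age at leaving the shared childhood home (years).
    marriage_age
        Conventional age at marriage, used to date spouse cohabitation.
    """
    age_a = pair.a.chronological_age
    age_b = pair.b.chronological_age
    for who, age in (("a", age_a), ("b", age_b)):
        if age is None or not math.isfinite(age):
            member = pair.a if who == "a" else pair.b
            raise ValueError(
                f"pair ({pair.a.individual_id}, {pair.b.individual_id}): "
                f"member {member.individual_id} has no usable chronological age"
            )

    rel = pair.relationship
    if rel in (RelationshipType.MZ, RelationshipType.DZ):
        return CohabitationClock(t=age_a, t0=adult_age)
    if rel == RelationshipType.SIB:
        younger, older = min(age_a, age_b), max(age_a, age_b)
        gap = older - younger
        t0 = max(0.0, adult_age - gap)  # younger's age when the older turned adult
        return CohabitationClock(t=younger, t0=t0)
    if rel == RelationshipType.PO:
        off_age = age_a if pair.offspring == "a" else age_b
        return CohabitationClock(t=off_age, t0=adult_age)
    if rel == RelationshipType.SPOUSE:
        t = max(0.0, 0.5 * (age_a + age_b) - marriage_age)
        t0 = pair.separation_time if pair.separation_time is not None else math.inf
        return CohabitationClock(t=t, t0=t0)
    raise ValueError(f"unknown relationship type: {rel!r}")
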