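"""Rule-based functional typing of translated peroxidase amplicons.

Class II peroxidases are typed from two catalytic anchors of the
amplified region: the surface tryptophan responsible for oxidation of
high-redox aromatics (Trp-171 in LiPH8 numbering) and the Mn-binding
acidic aspartate (Asp-175 in MnP1 numbering).  The 2x2 rule table is
total:

    Asp present, Trp absent  -> MNP_LIKE
    Trp present, Asp absent  -> LIP_LIKE_UNTYPICAL
    both present             -> VP_LIKE
    neither                  -> GP_LIKE

"Untypical" reflects that surveyed Trp-carrying litter sequences fall
outside the classic LiP clade; upgrading to canonical LiP is a
phylogenetic decision left to the tree stage.  DyP amplicons are scored
for completeness of the H2O2-binding pocket (Arg-329, Leu-354, Phe-356
in 3MM3 numbering); UPOs carry no known diagnostic residue in the
amplified region and are grouped by partial-protein length instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from peroxscan.anchor_align import AnchorHit

__all__ = [
    "ClassIILabel",
    "UPOGroup",
    "ClassIICall",
    "DyPCall",
    "UPOGroupCall",
    "FamilyCall",
    "UPO_LENGTH_BOUNDS",
    "classify_class2",
    "classify_dyp",
    "classify_upo",
    "summarize_cohort",
]

MNP_LIKE = "MNP_LIKE"
LIP_LIKE_UNTYPICAL = "LIP_LIKE_UNTYPICAL"
VP_LIKE = "VP_LIKE"
GP_LIKE = "GP_LIKE"
ClassIILabel = str

GROUP_I_1 = "GROUP_I_1"
GROUP_II = "GROUP_II"
UNASSIGNED = "UNASSIGNED"
UPOGroup = str

#: partial-protein length windows (aa) in the amplified UPO region
UPO_LENGTH_BOUNDS: Mapping[UPOGroup, tuple[int, int]] = {
    GROUP_I_1: (66, 74),
    GROUP_II: (80, 90),
}


@dataclass(frozen=True)
class ClassIICall:
    label: ClassIILabel
    has_trp171: bool
    has_asp175: bool
    evidence: tuple[AnchorHit, AnchorHit]


@dataclass(frozen=True)
class DyPCall:
    has_arg329: bool
    has_leu354: bool
    has_phe356: bool
    pocket_complete: bool
    length_aa: int
    evidence: tuple[AnchorHit, AnchorHit, AnchorHit]

    def __post_init__(self) -> None:
        expect = self.has_arg329 and self.has_leu354 and self.has_phe356
        if self.pocket_complete != expect:
            raise ValueError("pocket_complete must be the conjunction of the three flags")


@dataclass(frozen=True)
class UPOGroupCall:
    length_aa: int
    group: UPOGroup


@dataclass(frozen=True)
class FamilyCall:
    """The classification verdict for one translated amplicon."""

    record_id: str
    family: str  # CLASS_II | UPO | DYP
    label: str  # subtype label or UPO group
    length_aa: int
    flags: Mapping[str, bool] = field(default_factory=dict)
    site: str | None = None
    forest_type: str | None = None


def classify_class2(trp_hit: AnchorHit, asp_hit: AnchorHit) -> ClassIICall:
    """Type a class II amplicon from its Trp/Asp anchor evidence.

    GAP and ABSENT both count as "residue not present": a partial
    sequence lacking the site lacks the evidence.
    """
    has_trp = trp_hit.matches_expected
    has_asp = asp_hit.matches_expected
    if has_asp and not has_trp:
        label = MNP_LIKE
    elif has_trp and not has_asp:
        label = LIP_LIKE_UNTYPICAL
    elif has_trp and has_asp:
        label = VP_LIKE
    else:
        label = GP_LIKE
    return ClassIICall(label, has_trp, has_asp, (trp_hit, asp_hit))


def classify_dyp(arg_hit: AnchorHit, leu_hit: AnchorHit, phe_hit: AnchorHit, length_aa: int) -> DyPCall:
    """Score the three-residue H2O2-binding pocket of a DyP amplicon."""
    flags = (arg_hit.matches_expected, leu_hit.matches_expected, phe_hit.matches_expected)
    return DyPCall(
        has_arg329=flags[0],
        has_leu354=flags[1],
        has_phe356=flags[2],
        pocket_complete=all(flags),
        length_aa=length_aa,
        evidence=(arg_hit, leu_hit, phe_hit),
    )


def classify_upo(length_aa: int, bounds: Mapping[UPOGroup, tuple[int, int]] = UPO_LENGTH_BOUNDS) -> UPOGroupCall:
    """Group a UPO amplicon by partial-protein length alone."""
    if length_aa < 1:
        raise ValueError("length must be >= 1")
    for group, (lo, hi) in bounds.items():
        if lo <= length_aa <= hi:
            return UPOGroupCall(length_aa, group)
    return UPOGroupCall(length_aa, UNASSIGNED)


def summarize_cohort(calls: Sequence[FamilyCall]) -> pd.DataFrame:
    """Per-family counts and percentages of labels and residue flags.

    Percentages are rounded to the nearest integer and every row states
    its denominator explicitly (the number of calls in that family), so
    the table never hides which cohort a percentage refers to.
    """
    if not calls:
        raise ValueError("empty cohort")
    rows = []
    by_family: dict[str, list[FamilyCall]] = {}
    for c in calls:
        by_family.setdefault(c.family, []).append(c)
    for family in sorted(by_family):
        group = by_family[family]
        denom = len(group)
        label_counts = Counter(c.label for c in group)
        for label in sorted(label_counts):
            n = label_counts[label]
            rows.append(
                {"family": family, "kind": "label", "name": label,
                 "count": n, "denominator": denom, "percent": round(100 * n / denom)}
            )
        flag_names = sorted({k for c in group for k in c.flags})
        for name in flag_names:
            n = sum(1 for c in group if c.flags.get(name))
            rows.append(
                {"family": family, "kind": "flag", "name": name,
                 "count": n, "denominator": denom, "percent": round(100 * n / denom)}
            )
    return pd.DataFrame(rows, columns=["family", "kind", "name", "count", "denominator", "percent"])
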