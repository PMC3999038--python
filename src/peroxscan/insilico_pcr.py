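"""Degenerate-primer in-silico PCR: site finding and amplicon extraction.

A primer binds where it aligns ungapped with at most ``max_mismatch``
positions whose IUPAC base sets are disjoint; inosine and ``N`` never
count as mismatches, and the 3'-terminal two positions must match
regardless of the tolerance (polymerase extension requires an annealed
3' end).  Amplicons are primer-inclusive, matching gel-estimated sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Literal, NamedTuple

import yaml

from peroxscan.sequence_core import (
    DegeneratePrimer,
    NucRecord,
    bases_compatible,
    reverse_complement,
)

__all__ = [
    "Family",
    "PrimerPair",
    "Amplicon",
    "PrimerSite",
    "find_sites",
    "amplify",
    "builtin_primer_pairs",
    "load_primer_pairs",
]

Family = Literal["CLASS_II", "UPO", "DYP"]
FAMILIES: tuple[Family, ...] = ("CLASS_II", "UPO", "DYP")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse degenerate primer set with its expected product-size window."""

    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    family: Family
    size_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        lo, hi = self.size_window
        if lo < len(self.forward) + len(self.reverse):
            raise ValueError("size window smaller than the combined primer length")
        if hi <= lo:
            raise ValueError("size window must satisfy max_bp > min_bp")


@dataclass(frozen=True)
class Amplicon:
    """One in-silico PCR product, primer footprints included.

    ``start``/``end`` are 0-based half-open coordinates on the plus
    strand of the template; ``seq`` is reported on the strand defined by
    the forward primer.
    """

    template_id: str
    start: int
    end: int
    strand: str
    seq: str
    family: Family

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("amplicon coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.seq)


class PrimerSite(NamedTuple):
    position: int  # 0-based start of the matched window on the plus strand
    strand: str
    mismatches: int


def _scan(template: str, pattern: str, max_mismatch: int, anchor: range) -> Iterator[tuple[int, int]]:
    """Yield (position, mismatches) of ungapped matches of ``pattern`` in ``template``.

    ``anchor`` indexes pattern positions that must match exactly.
    """
    L = len(pattern)
    for pos in range(len(template) - L + 1):
        window = template[pos : pos + L]
        mm = 0
        ok = True
        for k in range(L):
            if not bases_compatible(pattern[k], window[k]):
                if k in anchor:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            yield pos, mm


def find_sites(template: NucRecord, primer: DegeneratePrimer, max_mismatch: int = 0) -> list[PrimerSite]:
    """Locate primer binding sites on both strands of a template.

    On the plus strand the primer's 3' end is the last two pattern
    positions; on the minus strand the reverse-complemented pattern is
    scanned, so the 3'-anchor becomes its first two positions.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    L = len(primer)
    sites = [
        PrimerSite(pos, "+", mm)
        for pos, mm in _scan(template.seq, primer.seq, max_mismatch, range(L - 2, L))
    ]
    rc = reverse_complement(primer.seq)
    sites += [
        PrimerSite(pos, "-", mm)
        for pos, mm in _scan(template.seq, rc, max_mismatch, range(0, 2))
    ]
    return sorted(sites)


def amplify(template: NucRecord, pair: PrimerPair, max_mismatch: int = 0) -> list[Amplicon]:
    """Extract every convergent forward/reverse product within the size window.

    All forward-site x reverse-site combinations are paired; overlapping
    or nested products are all reported and left to the size filter.
    """
    fwd_sites = find_sites(template, pair.forward, max_mismatch)
    rev_sites = find_sites(template, pair.reverse, max_mismatch)
    lo, hi = pair.size_window
    lf, lr = len(pair.forward), len(pair.reverse)
    out: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.strand == "+" and r.strand == "-":
                start, end = f.position, r.position + lr
                strand = "+"
            elif f.strand == "-" and r.strand == "+":
                start, end = r.position, f.position + lf
                strand = "-"
            else:
                continue
            length = end - start
            if length < lf + lr or not (lo <= length <= hi):
                continue
            seq = template.seq[start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            out.append(
                Amplicon(
                    template_id=template.id,
                    start=start,
                    end=end,
                    strand=strand,
                    seq=seq,
                    family=pair.family,
                )
            )
    return sorted(out, key=lambda a: (a.start, a.end, a.strand))


def load_primer_pairs(path) -> dict[str, PrimerPair]:
    """Load primer pairs from a YAML mapping family -> primers + window."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pairs: dict[str, PrimerPair] = {}
    for family, spec in raw.items():
        pairs[family] = PrimerPair(
            forward=DegeneratePrimer(spec["forward"]["name"], spec["forward"]["seq"], spec["forward"].get("motif")),
            reverse=DegeneratePrimer(spec["reverse"]["name"], spec["reverse"]["seq"], spec["reverse"].get("motif")),
            family=family,
            size_window=tuple(spec["size_window"]),
        )
    return pairs


def builtin_primer_pairs() -> dict[str, PrimerPair]:
    """The three published degenerate primer pairs of the survey.

    Size windows are centered on the expected product sizes (~400 bp for
    class II and DyP, ~210 bp for UPO).
    """
    with resources.as_file(resources.files("peroxscan.data") / "primers.yaml") as p:
        return load_primer_pairs(p)
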