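"""Pairwise/progressive protein alignment and catalytic-anchor mapping.

Catalytic positions are specified in *reference numbering* (e.g. the
surface tryptophan homologous to Trp-171 of Phanerochaete chrysosporium
LiPH8, or the Mn-binding aspartate homologous to Asp-175 of MnP1), not
as columns of any particular multiple alignment: a query is aligned to
the annotated reference and each anchor is read off the column that the
reference position occupies.  This keeps the classification reproducible
without the original survey alignment.

Alignments are affine-gap global alignments under BLOSUM62 (gap open
10, extend 0.5) with free terminal gaps, since queries are partial
amplicon translations matched against full-length references.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from peroxscan.phylogeny import MSA, nj_join_order
from peroxscan.sequence_core import ProtRecord

__all__ = [
    "GAP",
    "ABSENT",
    "AlignParams",
    "AnchorSpec",
    "AnchorHit",
    "PairwiseAlignment",
    "global_align",
    "percent_identity",
    "map_anchors",
    "progressive_msa",
    "assign_best_reference",
]

#: query has a gap in the anchor's column
GAP = "GAP"
#: anchor column lies outside the aligned span of a partial query
ABSENT = "ABSENT"


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring: substitution table name plus affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class AnchorSpec:
    """Catalytic positions of one reference protein, in its own numbering.

    ``anchors`` maps 1-based reference positions to (expected residue,
    role label), e.g. ``{171: ("W", "catalytic Trp"), 175: ("D", "Mn-binding Asp")}``.
    """

    ref_id: str
    family: str
    anchors: Mapping[int, tuple[str, str]]
    numbering_source: str = ""
    #: residues additionally accepted per position (e.g. E at an acidic anchor)
    tolerated: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        for pos, (res, _role) in self.anchors.items():
            if pos < 1:
                raise ValueError(f"anchor position {pos} not 1-based")
            if len(res) != 1 or not res.isalpha():
                raise ValueError(f"expected residue {res!r} is not a single letter")

    def accepts(self, pos: int, residue: str) -> bool:
        expected = self.anchors[pos][0]
        extra = (self.tolerated or {}).get(pos, "")
        return residue == expected or residue in extra


@dataclass(frozen=True)
class AnchorHit:
    """The query residue observed at one reference anchor column."""

    position: int
    expected: str
    query_residue: str  # amino-acid letter, GAP, or ABSENT
    matches_expected: bool
    query_index: int | None = None  # 1-based position in the query, if present

    def __post_init__(self) -> None:
        if self.matches_expected and self.query_residue != self.expected:
            # tolerated alternatives are reported via matches_expected by the caller
            if self.query_residue in (GAP, ABSENT):
                raise ValueError("a GAP/ABSENT hit cannot match the expected residue")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows plus the alignment score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(x == y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap/gap column")


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load(params.matrix)
    a.open_internal_gap_score = -params.gap_open
    a.extend_internal_gap_score = -params.gap_extend
    # terminal gaps free: queries are partial amplicons against full references
    a.end_gap_score = 0.0
    return a


def global_align(a: ProtRecord | str, b: ProtRecord | str, params: AlignParams = DEFAULT_PARAMS) -> PairwiseAlignment:
    """Optimal affine-gap global alignment; first-optimal traceback is deterministic."""
    sa = a.seq if isinstance(a, ProtRecord) else a
    sb = b.seq if isinstance(b, ProtRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(params).align(sa.replace("*", "X"), sb.replace("*", "X"))[0]
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=aln.score)


def _span(row: str) -> tuple[int, int]:
    """Half-open column span of the non-terminal-gap content of a row."""
    first = len(row) - len(row.lstrip("-"))
    last = len(row.rstrip("-"))
    return first, last


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical / compared columns; terminal-gap and internal-gap columns excluded."""
    a, b = aln.aligned_a, aln.aligned_b
    lo = max(_span(a)[0], _span(b)[0])
    hi = min(_span(a)[1], _span(b)[1])
    compared = identical = 0
    for k in range(lo, hi):
        if a[k] == "-" or b[k] == "-":
            continue
        compared += 1
        if a[k] == b[k]:
            identical += 1
    if compared == 0:
        raise ValueError("no comparable (non-gap, overlapping) column")
    return 100.0 * identical / compared


def map_anchors(
    query: ProtRecord,
    spec: AnchorSpec,
    reference: ProtRecord,
    params: AlignParams = DEFAULT_PARAMS,
) -> list[AnchorHit]:
    """Read the query residues occupying the reference's anchor columns.

    Returns one hit per anchor, sorted by position: the residue when the
    query covers the column, GAP for an internal deletion, ABSENT when
    the anchor falls outside the aligned span of a partial query.
    """
    max_pos = max(spec.anchors)
    if max_pos > len(reference.seq):
        raise ValueError(
            f"anchor position {max_pos} beyond reference {reference.id!r} length {len(reference.seq)}"
        )
    aln = global_align(query, reference, params)
    qrow, rrow = aln.aligned_a, aln.aligned_b
    qlo, qhi = _span(qrow)

    # reference position (1-based) of each column
    ref_pos_to_col: dict[int, int] = {}
    rp = 0
    for col, ch in enumerate(rrow):
        if ch != "-":
            rp += 1
            ref_pos_to_col[rp] = col

    hits: list[AnchorHit] = []
    for pos in sorted(spec.anchors):
        expected = spec.anchors[pos][0]
        col = ref_pos_to_col[pos]
        if not (qlo <= col < qhi):
            hits.append(AnchorHit(pos, expected, ABSENT, False))
            continue
        qres = qrow[col]
        if qres == "-":
            hits.append(AnchorHit(pos, expected, GAP, False))
            continue
        qidx = col - qrow[:col].count("-") + 1 - 0  # 1-based index in query
        hits.append(AnchorHit(pos, expected, qres, spec.accepts(pos, qres), qidx))
    return hits


# ---------------------------------------------------------------------------
# Progressive MSA


def _profile_align(
    pa: list[str], pb: list[str], params: AlignParams
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles (sum-of-pairs mean scoring)."""
    mat = substitution_matrices.load(params.matrix)
    open_, ext = params.gap_open, params.gap_extend

    def col(profile: list[str], k: int) -> list[str]:
        return [row[k] for row in profile if row[k] != "-"]

    la, lb = len(pa[0]), len(pb[0])
    cols_a = [col(pa, k) for k in range(la)]
    cols_b = [col(pb, k) for k in range(lb)]

    def score(ca: list[str], cb: list[str]) -> float:
        if not ca or not cb:
            return 0.0
        s = 0.0
        for x in ca:
            for y in cb:
                s += mat[x, y]
        return s / (len(ca) * len(cb))

    NEG = -1e18
    # M: ends in column/column; X: gap in profile b (consume a); Y: gap in profile a
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = 0.0  # free terminal gaps
    for j in range(1, lb + 1):
        Y[0, j] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score(cols_a[i - 1], cols_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            og = 0.0 if j == lb else -open_
            eg = 0.0 if j == lb else -ext
            X[i, j] = max(M[i - 1, j] + og, X[i - 1, j] + eg)
            og = 0.0 if i == la else -open_
            eg = 0.0 if i == la else -ext
            Y[i, j] = max(M[i, j - 1] + og, Y[i, j - 1] + eg)

    # traceback, preferring column/column over gap-in-b over gap-in-a
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    i, j = la, lb
    tabs = {"M": M, "X": X, "Y": Y}
    state = max(("M", "X", "Y"), key=lambda s: tabs[s][la, lb])
    while i > 0 or j > 0:
        if i == 0:  # left border: only b-columns remain
            out_a.append(None)
            out_b.append(j - 1)
            j -= 1
            continue
        if j == 0:
            out_a.append(i - 1)
            out_b.append(None)
            i -= 1
            continue
        if state == "M":
            out_a.append(i - 1)
            out_b.append(j - 1)
            i, j = i - 1, j - 1
            state = max(("M", "X", "Y"), key=lambda t: tabs[t][i, j])
        elif state == "X":
            og = 0.0 if j == lb else -open_
            eg = 0.0 if j == lb else -ext
            prev = "M" if M[i - 1, j] + og >= X[i - 1, j] + eg else "X"
            out_a.append(i - 1)
            out_b.append(None)
            i -= 1
            state = prev
        else:
            og = 0.0 if i == la else -open_
            eg = 0.0 if i == la else -ext
            prev = "M" if M[i, j - 1] + og >= Y[i, j - 1] + eg else "Y"
            out_a.append(None)
            out_b.append(j - 1)
            j -= 1
            state = prev
    out_a.reverse()
    out_b.reverse()

    merged_a = ["".join(row[k] if k is not None else "-" for k in out_a) for row in pa]
    merged_b = ["".join(row[k] if k is not None else "-" for k in out_b) for row in pb]
    return merged_a, merged_b


def progressive_msa(records: Sequence[ProtRecord], params: AlignParams = DEFAULT_PARAMS) -> MSA:
    """Progressive multiple alignment along an NJ guide tree.

    Pairwise p-distances (1 - identity) from global alignments feed a
    neighbor-joining guide order; profiles are merged bottom-up.  Two
    records reduce to :func:`global_align`.
    """
    if len(records) < 2:
        raise ValueError("progressive MSA needs at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if len(records) == 2:
        aln = global_align(records[0], records[1], params)
        return MSA(tuple(ids), (aln.aligned_a, aln.aligned_b))

    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(global_align(records[i], records[j], params))
            dm[i, j] = dm[j, i] = 1.0 - pid / 100.0

    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([r.id], [r.seq]) for i, r in enumerate(records)
    }
    next_id = n
    for a, b in nj_join_order(dm):
        ids_a, rows_a = profiles.pop(a)
        ids_b, rows_b = profiles.pop(b)
        ma, mb = _profile_align(rows_a, rows_b, params)
        profiles[next_id] = (ids_a + ids_b, ma + mb)
        next_id += 1
    (final_ids, final_rows), = profiles.values()
    final = sorted(zip(final_ids, final_rows), key=lambda t: ids.index(t[0]))
    return MSA(tuple(t[0] for t in final), tuple(t[1] for t in final))


def assign_best_reference(
    query: ProtRecord,
    panel: Sequence[ProtRecord],
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[str, float]:
    """Best-identity reference in a panel (ties to lexicographic id; 1-decimal identity)."""
    if not panel:
        raise ValueError("empty reference panel")
    best_id, best_pid = None, -1.0
    for ref in sorted(panel, key=lambda r: r.id):
        pid = percent_identity(global_align(query, ref, params))
        if pid > best_pid + 1e-9:
            best_id, best_pid = ref.id, pid
    return best_id, round(best_pid, 1)
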