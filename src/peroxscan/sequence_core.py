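"""Nucleotide/protein sequence model, degenerate IUPAC alphabet and translation.

Templates are cDNA, so ``U`` is normalized to ``T`` on ingest.  Inosine
(``I``), which base-pairs promiscuously and is used by the survey primers
at fully degenerate codon positions, is treated as a universal-match
wildcard during hybridization and emitted as ``N`` when a primer is
expanded to concrete sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "ExpansionOverflowError",
    "FrameError",
    "IUPAC_SETS",
    "NUC_ALPHABET",
    "AA_ALPHABET",
    "NucRecord",
    "ProtRecord",
    "DegeneratePrimer",
    "expand_degenerate",
    "reverse_complement",
    "translate",
    "bases_compatible",
    "read_fasta",
    "write_fasta",
]


class AlphabetError(ValueError):
    """A sequence contains a character outside its declared alphabet."""


class ExpansionOverflowError(ValueError):
    """Degenerate expansion would exceed the requested cap."""


class FrameError(ValueError):
    """Nothing remains to translate in the requested frame."""


#: IUPAC ambiguity codes -> concrete base sets.  Inosine is intentionally
#: absent: it is symbolic (universal match) and never enumerated.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

NUC_ALPHABET = frozenset(IUPAC_SETS) | {"I", "U"}
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N", "I": "I",
}


def _validate_nuc(seq: str) -> str:
    if not seq:
        raise AlphabetError("empty nucleotide sequence")
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - NUC_ALPHABET
    if bad:
        raise AlphabetError(f"invalid nucleotide character(s): {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class NucRecord:
    """A nucleotide record (cDNA template or amplicon) with optional site/treatment metadata."""

    id: str
    seq: str
    meta: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate_nuc(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProtRecord:
    """A translated protein record.

    ``source_frame``/``source_strand`` record the reading frame the
    pipeline chose at translation time; ``partial`` flags fragments in
    which an internal stop marker is tolerated.
    """

    id: str
    seq: str
    source_frame: int = 0
    source_strand: str = "+"
    partial: bool = False
    meta: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError("empty protein sequence")
        seq = self.seq.upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise AlphabetError(f"invalid amino-acid character(s): {sorted(bad)}")
        if not self.partial and "*" in seq[:-1]:
            raise AlphabetError("internal stop in non-partial protein record")
        if self.source_frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if self.source_strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate oligonucleotide written 5'->3' in IUPAC codes plus inosine."""

    name: str
    seq: str
    motif: str | None = None

    def __post_init__(self) -> None:
        seq = _validate_nuc(self.seq.replace(" ", ""))
        object.__setattr__(self, "seq", seq)
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        if self.motif is not None and len(self.motif) > math.ceil(len(seq) / 3):
            raise ValueError("motif longer than the primer can encode")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def cardinality(self) -> int:
        """Number of concrete expansions (inosine kept symbolic, counted as 1)."""
        n = 1
        for c in self.seq:
            if c != "I":
                n *= len(IUPAC_SETS[c])
        return n


def expand_degenerate(primer: DegeneratePrimer, max_expansions: int = 4096) -> set[str]:
    """Enumerate every concrete sequence a degenerate primer denotes.

    Each IUPAC code is substituted by every member of its base set;
    inosine positions are emitted as the wildcard ``N``.  Raises
    :class:`ExpansionOverflowError` when the product of per-position
    cardinalities exceeds ``max_expansions``.
    """
    if max_expansions < 1:
        raise ValueError("max_expansions must be positive")
    if primer.cardinality > max_expansions:
        raise ExpansionOverflowError(
            f"{primer.name}: {primer.cardinality} expansions exceed cap {max_expansions}"
        )
    choices = [("N",) if c == "I" else tuple(sorted(IUPAC_SETS[c])) for c in primer.seq]
    return {"".join(p) for p in product(*choices)}


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H; S, W, N, I self)."""
    seq = _validate_nuc(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def bases_compatible(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC symbols overlap (inosine matches anything)."""
    if a == "I" or b == "I":
        return True
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def _translate_codon(codon: str) -> str:
    """Translate one codon; ambiguous positions yield a residue only if all expansions agree."""
    table = standard_dna_table.forward_table
    sets = [("A", "C", "G", "T") if c == "I" else tuple(IUPAC_SETS[c]) for c in codon]
    n_comb = len(sets[0]) * len(sets[1]) * len(sets[2])
    if n_comb == 1:
        c = sets[0][0] + sets[1][0] + sets[2][0]
        return table.get(c, "*")
    aas = {table.get("".join(c), "*") for c in product(*sets)}
    return aas.pop() if len(aas) == 1 else "X"


def translate(seq: str, frame: int = 0, strand: str = "+", *, id: str = "", partial: bool = True) -> ProtRecord:
    """Translate a nucleotide sequence under the standard genetic code.

    The trailing incomplete codon is dropped.  A codon containing an
    ambiguity code (or inosine) translates to a specific amino acid only
    when every concrete expansion encodes the same residue, else ``X``.
    """
    seq = _validate_nuc(seq)
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    if frame not in (0, 1, 2):
        raise FrameError("frame must be 0, 1 or 2")
    coding = seq[frame:]
    if len(coding) < 3:
        raise FrameError(f"nothing to translate in frame {frame}")
    aa = "".join(_translate_codon(coding[i : i + 3]) for i in range(0, len(coding) - len(coding) % 3, 3))
    return ProtRecord(id=id or "translation", seq=aa, source_frame=frame, source_strand=strand, partial=partial)


def read_fasta(path) -> list[NucRecord]:
    """Read nucleotide FASTA; record ids are taken to the first whitespace."""
    records = [NucRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return records


def read_fasta_protein(path) -> list[ProtRecord]:
    """Read protein FASTA (partial records permitted)."""
    return [ProtRecord(id=r.id, seq=str(r.seq), partial=True) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[NucRecord | ProtRecord], path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)
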