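"""Ground-truthed synthetic amplicon pools for end-to-end pipeline testing.

The generator emulates the structure of a degenerate-primer peroxidase
transcript survey: per-site amplicon pools of the three target families
(class II peroxidase ~400 bp, UPO ~210 bp, DyP ~400 bp), partial
proteins in the published length ranges (UPO group I.1 66-74 aa, group
II 80-90 aa, DyP 128-144 aa, class II ~133 aa), catalytic residues
implanted or ablated according to a per-record plan, point-mutation
noise, injected exact and synonymous duplicates (within and across
sites), and non-target decoys lacking primer sites.

Synthetic catalytic anchors live at fixed positions in *synthetic
reference numbering* (deliberately decoupled from the real 171/175 and
329/354/356 coordinates, which belong to database reference proteins
that are not fabricated here).  Every emitted record has exactly one
ground-truth row, so each pipeline stage can be scored without any
external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from peroxscan.anchor_align import AnchorSpec
from peroxscan.insilico_pcr import PrimerPair, amplify, builtin_primer_pairs
from peroxscan.residue_classifier import (
    GP_LIKE,
    GROUP_I_1,
    GROUP_II,
    LIP_LIKE_UNTYPICAL,
    MNP_LIKE,
    VP_LIKE,
)
from peroxscan.sequence_core import (
    DegeneratePrimer,
    NucRecord,
    ProtRecord,
    expand_degenerate,
    reverse_complement,
    translate,
)

__all__ = [
    "SimConfig",
    "TruthRow",
    "SyntheticTruth",
    "SimResult",
    "SYNTH_ANCHORS",
    "make_reference_panel",
    "mutate",
    "generate_pools",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: synthetic anchor positions (1-based, in the full translated amplicon)
SYNTH_ANCHORS: Mapping[str, Mapping[int, tuple[str, str]]] = {
    "CLASS_II": {40: ("W", "catalytic Trp (LiP-type)"), 52: ("D", "Mn-binding Asp")},
    "DYP": {40: ("R", "H2O2-pocket Arg"), 65: ("L", "H2O2-pocket Leu"), 67: ("F", "H2O2-pocket Phe")},
    "UPO": {},
}

#: translated amplicon length (aa) per family; a range where variable
CLASS2_LEN = 133
DYP_LEN_RANGE = (128, 144)
UPO_I1_LEN_RANGE = (66, 74)
UPO_II_LEN_RANGE = (80, 90)

#: protein position after which length-adjusting indels are placed
VAR_POS = {"CLASS_II": 100, "DYP": 100, "UPO": 40}

_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _c = _b1 + _b2 + _b3
            _aa = translate(_c + "AAA", 0, "+").seq[0]
            if _aa != "*":
                _CODONS_BY_AA.setdefault(_aa, []).append(_c)

# forest types of the nine surveyed sites (maple, aspen, 4x beech, 2x spruce, oak)
DEFAULT_FOREST_TYPES = ("Maple", "Aspen", "Beech", "Beech", "Beech", "Beech", "Spruce", "Spruce", "Oak")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated survey."""

    seed: int = 0
    n_sites: int = 9
    forest_types: tuple[str, ...] = DEFAULT_FOREST_TYPES
    pool_size: int = 6  # target records per site per family
    decoys_per_site: int = 2
    n_refs: int = 4  # reference-panel size per family
    ref_divergence: float = 0.12  # aa substitution rate ancestor -> reference
    env_mutation_rate: float = 0.02  # aa substitution rate reference -> amplicon
    duplicate_rate: float = 0.12  # fraction of records re-emitted as duplicates
    cross_site_fraction: float = 0.5  # of duplicates, fraction placed in another site
    synonymous_fraction: float = 0.5  # of duplicates, fraction re-encoded synonymously
    # class II subtype plan: most records MnP-like, a few Trp-only and GP-like
    class2_fractions: Mapping[str, float] = field(
        default_factory=lambda: {MNP_LIKE: 0.90, LIP_LIKE_UNTYPICAL: 0.04, VP_LIKE: 0.0, GP_LIKE: 0.06}
    )
    # marginal presence probabilities of the DyP pocket residues
    dyp_presence: Mapping[str, float] = field(
        default_factory=lambda: {"R": 0.99, "L": 0.99, "F": 0.91}
    )
    upo_group_i1_fraction: float = 0.9
    flank_length: tuple[int, int] = (20, 50)

    def __post_init__(self) -> None:
        for r in (self.ref_divergence, self.env_mutation_rate, self.duplicate_rate,
                  self.cross_site_fraction, self.synonymous_fraction, self.upo_group_i1_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if len(self.forest_types) < self.n_sites:
            raise ValueError("need a forest type per site")
        if abs(sum(self.class2_fractions.values()) - 1) > 1e-9:
            raise ValueError("class II fractions must sum to 1")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one emitted record."""

    record_id: str
    family: str
    site: str
    forest_type: str
    source_ref: str
    label: str  # intended subtype / UPO group
    group: str  # richness-table group
    protein: str  # true translated amplicon (frame 0 on the forward strand)
    length_aa: int
    flags: Mapping[str, bool]
    n_mutations: int
    duplicate_of: str | None = None


class SyntheticTruth:
    """record id -> :class:`TruthRow`, with a tabular view."""

    def __init__(self, rows: Sequence[TruthRow]):
        self._rows = {r.record_id: r for r in rows}
        if len(self._rows) != len(rows):
            raise ValueError("duplicate record ids in truth")

    def __getitem__(self, record_id: str) -> TruthRow:
        return self._rows[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self._rows.values():
            d = asdict(r)
            d["flags"] = ";".join(f"{k}={int(v)}" for k, v in sorted(r.flags.items()))
            recs.append(d)
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class SimResult:
    pools: Mapping[str, tuple[NucRecord, ...]]  # site -> templates (targets + decoys)
    panels: Mapping[str, tuple[ProtRecord, ...]]  # family -> reference panel proteins
    panel_nuc: Mapping[str, tuple[NucRecord, ...]]  # family -> back-translated references
    anchor_refs: Mapping[str, tuple[ProtRecord, AnchorSpec]]
    truth: SyntheticTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# low-level helpers


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float, protect: set[int]) -> tuple[str, int]:
    """Substitute residues at ``rate`` (uniform over alternatives), skipping 1-based ``protect``."""
    out = list(seq)
    n = 0
    for i in range(len(out)):
        if (i + 1) in protect:
            continue
        if rng.random() < rate:
            alternatives = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = rng.choice(alternatives)
            n += 1
    return "".join(out), n


def _resize_protein(rng: np.random.Generator, seq: str, target: int, var_pos: int) -> str:
    """Insert or delete residues just after ``var_pos`` to reach ``target`` length."""
    delta = target - len(seq)
    if delta == 0:
        return seq
    if delta > 0:
        ins = _random_protein(rng, delta)
        return seq[:var_pos] + ins + seq[var_pos:]
    if var_pos - delta > len(seq):
        raise ValueError("deletion would run past the end of the sequence")
    return seq[:var_pos] + seq[var_pos - delta :]


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def _concrete(rng: np.random.Generator, primer: DegeneratePrimer) -> str:
    """One concrete expansion of a degenerate primer (N from inosine randomized)."""
    exp = sorted(expand_degenerate(primer, 4096))
    pick = exp[rng.integers(len(exp))]
    return "".join(rng.choice(list("ACGT")) if c == "N" else c for c in pick)


def _amplicon_dna(rng: np.random.Generator, protein: str, pair: PrimerPair) -> str:
    """Back-translate and stamp concrete primer footprints; reject internal stops."""
    lf, lr = len(pair.forward), len(pair.reverse)
    for _ in range(200):
        dna = _back_translate(rng, protein)
        fwd = _concrete(rng, pair.forward)
        rev = _concrete(rng, pair.reverse)
        dna = fwd + dna[lf : len(dna) - lr] + reverse_complement(rev)
        aa = translate(dna, 0, "+").seq
        if "*" not in aa:
            return dna
    raise RuntimeError("could not stamp primer footprints without creating a stop codon")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# public operations


def mutate(
    record: NucRecord,
    rate: float,
    indel_rate: float = 0.0,
    preserve: set[int] | None = None,
    seed: int = 0,
) -> NucRecord:
    """Point-mutate a nucleotide record, optionally with in-frame codon indels.

    Substitutions hit each position with probability ``rate`` (uniform
    over the three alternatives); 0-based positions in ``preserve`` are
    never altered.  Indels insert or delete whole codons between codon
    boundaries (frame-preserving) and never touch codons that intersect
    preserved positions.
    """
    if not 0 <= rate <= 1 or not 0 <= indel_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    preserve = preserve or set()
    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    for i in range(len(seq)):
        if i in preserve:
            continue
        if rng.random() < rate:
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    if indel_rate > 0:
        out: list[str] = []
        n_codons = len(seq) // 3
        protected_codons = {p // 3 for p in preserve}
        for c in range(n_codons):
            codon = seq[3 * c : 3 * c + 3]
            if c in protected_codons:
                out.extend(codon)
                continue
            r = rng.random()
            if r < indel_rate / 2:
                continue  # codon deletion
            out.extend(codon)
            if indel_rate / 2 <= r < indel_rate:
                out.extend(rng.choice(list("ACGT"), size=3))  # codon insertion
        out.extend(seq[3 * n_codons :])
        seq = out
    return NucRecord(id=record.id, seq="".join(seq), meta=record.meta)


def make_reference_panel(config: SimConfig, rng: np.random.Generator | None = None):
    """Build per-family ancestors, anchor references and diverged panels.

    Returns (ancestors, anchor_refs, panels, panel_nuc): the family
    ancestor proteins, their :class:`AnchorSpec`-annotated anchor
    references, the diverged reference panels, and back-translated
    nucleotide versions of the panel members (primer footprints stamped
    so in-silico PCR recovers them).  Deterministic under the config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pairs = builtin_primer_pairs()
    ancestors: dict[str, str] = {}
    anchor_refs: dict[str, tuple[ProtRecord, AnchorSpec]] = {}
    panels: dict[str, tuple[ProtRecord, ...]] = {}
    panel_nuc: dict[str, tuple[NucRecord, ...]] = {}
    lengths = {"CLASS_II": CLASS2_LEN, "DYP": DYP_LEN_RANGE[1], "UPO": UPO_II_LEN_RANGE[1]}
    for family in ("CLASS_II", "UPO", "DYP"):
        anchors = SYNTH_ANCHORS[family]
        anc = list(_random_protein(rng, lengths[family]))
        for pos, (res, _role) in anchors.items():
            anc[pos - 1] = res
        ancestors[family] = "".join(anc)
        ref_id = f"{family}_anchor_ref"
        spec = AnchorSpec(
            ref_id=ref_id,
            family=family,
            anchors=dict(anchors),
            numbering_source="synthetic reference numbering",
        )
        anchor_refs[family] = (ProtRecord(id=ref_id, seq=ancestors[family], partial=True), spec)
        protect = set(anchors)
        members: list[ProtRecord] = []
        members_nuc: list[NucRecord] = []
        for k in range(config.n_refs):
            prot, _ = _mutate_protein(rng, ancestors[family], config.ref_divergence, protect)
            rid = f"{family}_ref{k:02d}"
            members.append(ProtRecord(id=rid, seq=prot, partial=True))
            dna = _amplicon_dna(rng, prot, pairs[family])
            members_nuc.append(NucRecord(id=rid, seq=dna))
        panels[family] = tuple(members)
        panel_nuc[family] = tuple(members_nuc)
    return ancestors, anchor_refs, panels, panel_nuc


def _plan_class2(rng: np.random.Generator, fractions: Mapping[str, float]) -> tuple[str, dict[str, bool]]:
    labels = sorted(fractions)
    probs = np.array([fractions[l] for l in labels])
    label = labels[rng.choice(len(labels), p=probs / probs.sum())]
    flags = {
        MNP_LIKE: {"trp": False, "asp": True},
        LIP_LIKE_UNTYPICAL: {"trp": True, "asp": False},
        VP_LIKE: {"trp": True, "asp": True},
        GP_LIKE: {"trp": False, "asp": False},
    }[label]
    return label, flags


def _apply_class2_plan(rng: np.random.Generator, prot: str, flags: Mapping[str, bool]) -> str:
    out = list(prot)
    trp_pos, asp_pos = 40, 52
    out[trp_pos - 1] = "W" if flags["trp"] else rng.choice([a for a in AMINO_ACIDS if a not in "W"])
    out[asp_pos - 1] = "D" if flags["asp"] else rng.choice([a for a in AMINO_ACIDS if a not in "DE"])
    return "".join(out)


def _apply_dyp_plan(rng: np.random.Generator, prot: str, flags: Mapping[str, bool]) -> str:
    out = list(prot)
    for pos, res, key in ((40, "R", "arg"), (65, "L", "leu"), (67, "F", "phe")):
        if flags[key]:
            out[pos - 1] = res
        else:
            # Phe ablation drawn as the conservative Phe->Tyr exchange; others uniform
            out[pos - 1] = "Y" if res == "F" else rng.choice([a for a in AMINO_ACIDS if a != res])
    return "".join(out)


def generate_pools(config: SimConfig) -> SimResult:
    """Generate per-site template pools with complete ground truth.

    Each pool mixes mutated target amplicons embedded in random flanks
    (so in-silico PCR has work to do), injected exact and synonymous
    duplicates within and across sites, and decoys without primer
    sites.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pairs = builtin_primer_pairs()
    ancestors, anchor_refs, panels, panel_nuc = make_reference_panel(config, rng)

    sites = [f"site{k + 1:02d}" for k in range(config.n_sites)]
    forest = {s: config.forest_types[k] for k, s in enumerate(sites)}
    pools: dict[str, list[NucRecord]] = {s: [] for s in sites}
    truth_rows: list[TruthRow] = []
    counter = 0

    def emit(site: str, family: str, dna: str, source_ref: str, label: str, group: str,
             flags: Mapping[str, bool], n_mut: int, duplicate_of: str | None = None) -> str:
        nonlocal counter
        counter += 1
        rid = f"{family}_{site}_{counter:04d}"
        protein = translate(dna, 0, "+").seq
        template = _embed(rng, rid, dna, family)
        template = NucRecord(id=rid, seq=template, meta={"site": site, "forest_type": forest[site], "family": family})
        pools[site].append(template)
        truth_rows.append(
            TruthRow(
                record_id=rid, family=family, site=site, forest_type=forest[site],
                source_ref=source_ref, label=label, group=group, protein=protein,
                length_aa=len(protein), flags=dict(flags), n_mutations=n_mut,
                duplicate_of=duplicate_of,
            )
        )
        return rid

    def _embed(rng: np.random.Generator, rid: str, dna: str, family: str) -> str:
        lo, hi = config.flank_length
        for _ in range(30):
            left = _random_dna(rng, int(rng.integers(lo, hi + 1)))
            right = _random_dna(rng, int(rng.integers(lo, hi + 1)))
            template = NucRecord(id=rid, seq=left + dna + right)
            prods = amplify(template, pairs[family], max_mismatch=0)
            if len(prods) == 1 and prods[0].seq == dna:
                return template.seq
        # flankless fallback: the amplicon is the template
        return dna

    emitted: list[tuple[str, str, str]] = []  # (record_id, site, family) for duplicate donors
    dna_by_id: dict[str, str] = {}

    for site in sites:
        for family in ("CLASS_II", "UPO", "DYP"):
            anchors = SYNTH_ANCHORS[family]
            protect = set(anchors)
            for _ in range(config.pool_size):
                ref = panels[family][rng.integers(len(panels[family]))]
                prot, n_mut = _mutate_protein(rng, ref.seq, config.env_mutation_rate, protect)
                if family == "CLASS_II":
                    label, flags = _plan_class2(rng, config.class2_fractions)
                    prot = _apply_class2_plan(rng, prot, flags)
                    group = "MnP long" if (label == MNP_LIKE and rng.random() < 0.25) else {
                        MNP_LIKE: "MnP short/unclassified",
                        LIP_LIKE_UNTYPICAL: "LiP",
                        VP_LIKE: "VP",
                        GP_LIKE: "GP",
                    }[label]
                    target_len = CLASS2_LEN
                elif family == "DYP":
                    flags = {k: bool(rng.random() < p) for k, p in
                             (("arg", config.dyp_presence["R"]), ("leu", config.dyp_presence["L"]),
                              ("phe", config.dyp_presence["F"]))}
                    prot = _apply_dyp_plan(rng, prot, flags)
                    label = "POCKET_COMPLETE" if all(flags.values()) else "POCKET_INCOMPLETE"
                    group = "DyP"
                    target_len = int(rng.integers(DYP_LEN_RANGE[0], DYP_LEN_RANGE[1] + 1))
                else:  # UPO
                    if rng.random() < config.upo_group_i1_fraction:
                        label = GROUP_I_1
                        target_len = int(rng.integers(UPO_I1_LEN_RANGE[0], UPO_I1_LEN_RANGE[1] + 1))
                    else:
                        label = GROUP_II
                        target_len = int(rng.integers(UPO_II_LEN_RANGE[0], UPO_II_LEN_RANGE[1] + 1))
                    flags = {}
                    group = "UPO"
                prot = _resize_protein(rng, prot, target_len, VAR_POS[family])
                dna = _amplicon_dna(rng, prot, pairs[family])
                rid = emit(site, family, dna, ref.id, label, group, flags, n_mut)
                emitted.append((rid, site, family))
                dna_by_id[rid] = dna

    # duplicate injection: re-emit some records, same or another site,
    # byte-identical or synonymously re-encoded
    n_dup = int(round(config.duplicate_rate * len(emitted)))
    if n_dup:
        donor_idx = rng.choice(len(emitted), size=n_dup, replace=False)
        for di in sorted(donor_idx):
            rid, site, family = emitted[di]
            row = next(t for t in truth_rows if t.record_id == rid)
            dna = dna_by_id[rid]
            if rng.random() < config.cross_site_fraction and config.n_sites > 1:
                others = [s for s in sites if s != site]
                target_site = others[rng.integers(len(others))]
            else:
                target_site = site
            if rng.random() < config.synonymous_fraction:
                dna2 = _resynonymize(rng, dna, family)
            else:
                dna2 = dna
            emit(target_site, family, dna2, row.source_ref, row.label, row.group,
                 row.flags, row.n_mutations, duplicate_of=rid)

    # decoys: random sequences with no primer-compatible window
    for site in sites:
        for k in range(config.decoys_per_site):
            for _ in range(50):
                dna = _random_dna(rng, int(rng.integers(350, 451)))
                rec = NucRecord(id=f"decoy_{site}_{k:02d}", seq=dna,
                                meta={"site": site, "forest_type": forest[site], "family": "DECOY"})
                if all(not amplify(rec, p, max_mismatch=0) for p in pairs.values()):
                    pools[site].append(rec)
                    break
            else:
                raise RuntimeError("could not draw a decoy without primer sites")

    return SimResult(
        pools={s: tuple(v) for s, v in pools.items()},
        panels=panels,
        panel_nuc=panel_nuc,
        anchor_refs=anchor_refs,
        truth=SyntheticTruth(truth_rows),
        config=config,
    )


def _resynonymize(rng: np.random.Generator, dna: str, family: str) -> str:
    """Re-encode interior codons synonymously, keeping primer footprints and protein."""
    pairs = builtin_primer_pairs()
    lf, lr = len(pairs[family].forward), len(pairs[family].reverse)
    n_codons = len(dna) // 3
    first = math.ceil(lf / 3) + 1  # first codon fully clear of the forward footprint
    last = n_codons - (math.ceil(lr / 3) + 1)
    out = list(dna)
    prot = translate(dna, 0, "+").seq
    for c in range(first, last):
        out[3 * c : 3 * c + 3] = rng.choice(_CODONS_BY_AA[prot[c]])
    return "".join(out)
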