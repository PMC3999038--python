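"""End-to-end orchestration: simulate/load -> PCR -> translate -> classify -> tree -> report.

A run is driven by a :class:`RunConfig`; all stage outputs are written
atomically into the output directory together with a JSON manifest that
records the package version, every parameter and every seed, so an
identical config reproduces a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from peroxscan import __version__ as _pkg_version
from peroxscan.anchor_align import (
    ABSENT,
    AlignParams,
    AnchorSpec,
    map_anchors,
    progressive_msa,
)
from peroxscan.insilico_pcr import Amplicon, PrimerPair, amplify, builtin_primer_pairs
from peroxscan.phylogeny import bootstrap_support, write_newick
from peroxscan.reporting import dereplicate, richness_table, shared_across_sites
from peroxscan.residue_classifier import (
    FamilyCall,
    classify_class2,
    classify_dyp,
    classify_upo,
    summarize_cohort,
)
from peroxscan.sequence_core import FrameError, NucRecord, ProtRecord, translate
from peroxscan.synthetic_data import SimConfig, SimResult, generate_pools

__all__ = [
    "RunConfig",
    "EmptyInputError",
    "StageError",
    "run_pipeline",
    "choose_frame",
    "amplify_pools",
    "classify_amplicons",
    "load_anchor_specs",
    "dump_anchor_specs",
]

#: richness-table group implied by each residue/length label when no
#: clade information is available (MnP long requires tree placement)
LABEL_TO_GROUP = {
    "MNP_LIKE": "MnP short/unclassified",
    "LIP_LIKE_UNTYPICAL": "LiP",
    "VP_LIKE": "VP",
    "GP_LIKE": "GP",
    "POCKET_COMPLETE": "DyP",
    "POCKET_INCOMPLETE": "DyP",
    "GROUP_I_1": "UPO",
    "GROUP_II": "UPO",
    "UNASSIGNED": "UPO",
}


class EmptyInputError(ValueError):
    """A FASTA input contained zero records."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``sim`` (synthetic pools generated in-process) or
    ``template_fastas`` (site label -> FASTA path, with anchor
    references supplied via ``anchor_yaml``/``anchor_ref_fasta``) must
    be provided.
    """

    out_dir: str
    sim: SimConfig | None = None
    template_fastas: Mapping[str, str] | None = None
    anchor_yaml: str | None = None
    anchor_ref_fasta: str | None = None
    families: tuple[str, ...] = ("CLASS_II", "UPO", "DYP")
    max_mismatch: int = 0
    align: AlignParams = field(default_factory=AlignParams)
    bootstrap_replicates: int = 100
    tree_seed: int = 42
    min_support: int = 50
    tree_max_taxa: int = 25
    build_trees: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.template_fastas is None):
            raise ValueError("provide exactly one of sim / template_fastas")


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def choose_frame(amplicon_seq: str, record_id: str = "") -> ProtRecord:
    """Translate an amplicon in its most plausible reading frame.

    Frame 0 on the forward strand continues the forward primer's encoded
    motif and is preferred; if it contains an internal stop, the
    stop-free forward frame with the longest translation is used, and as
    a last resort the frame-0 translation is kept (flagged partial).
    """
    first = translate(amplicon_seq, 0, "+", id=record_id)
    if "*" not in first.seq[:-1]:
        return first
    candidates = []
    for frame in (1, 2):
        try:
            t = translate(amplicon_seq, frame, "+", id=record_id)
        except FrameError:
            continue
        if "*" not in t.seq[:-1]:
            candidates.append(t)
    if candidates:
        return max(candidates, key=lambda t: len(t.seq))
    return first


def amplify_pools(
    pools: Mapping[str, Sequence[NucRecord]],
    pairs: Mapping[str, PrimerPair],
    max_mismatch: int = 0,
) -> list[tuple[NucRecord, Amplicon]]:
    """Run every primer pair over every template; amplicon records get suffixed ids."""
    out: list[tuple[NucRecord, Amplicon]] = []
    for site in sorted(pools):
        templates = pools[site]
        if not templates:
            raise EmptyInputError(f"site {site!r} has no templates")
        for tmpl in templates:
            for fam in sorted(pairs):
                products = amplify(tmpl, pairs[fam], max_mismatch)
                for k, amp in enumerate(products):
                    meta = dict(tmpl.meta or {})
                    meta.setdefault("site", site)
                    rec = NucRecord(id=f"{tmpl.id}_amp{k}" if len(products) > 1 else tmpl.id,
                                    seq=amp.seq, meta=meta)
                    out.append((rec, amp))
    return out


def classify_amplicons(
    amplicons: Sequence[tuple[NucRecord, Amplicon]],
    anchor_refs: Mapping[str, tuple[ProtRecord, AnchorSpec]],
    align: AlignParams = AlignParams(),
) -> tuple[list[FamilyCall], dict[str, ProtRecord]]:
    """Translate and type each amplicon; returns calls plus translations by record id."""
    calls: list[FamilyCall] = []
    translations: dict[str, ProtRecord] = {}
    for rec, amp in amplicons:
        prot = choose_frame(rec.seq, rec.id)
        translations[rec.id] = prot
        family = amp.family
        site = (rec.meta or {}).get("site")
        forest = (rec.meta or {}).get("forest_type")
        length = len(prot.seq.rstrip("*"))
        if family == "CLASS_II":
            ref, spec = anchor_refs[family]
            hits = map_anchors(prot, spec, ref, align)
            trp = next(h for h in hits if h.expected == "W")
            asp = next(h for h in hits if h.expected == "D")
            c2 = classify_class2(trp, asp)
            calls.append(FamilyCall(rec.id, family, c2.label, length,
                                    {"trp171": c2.has_trp171, "asp175": c2.has_asp175},
                                    site, forest))
        elif family == "DYP":
            ref, spec = anchor_refs[family]
            hits = map_anchors(prot, spec, ref, align)
            arg = next(h for h in hits if h.expected == "R")
            leu = next(h for h in hits if h.expected == "L")
            phe = next(h for h in hits if h.expected == "F")
            dy = classify_dyp(arg, leu, phe, length)
            label = "POCKET_COMPLETE" if dy.pocket_complete else "POCKET_INCOMPLETE"
            calls.append(FamilyCall(rec.id, family, label, length,
                                    {"arg329": dy.has_arg329, "leu354": dy.has_leu354,
                                     "phe356": dy.has_phe356, "pocket_complete": dy.pocket_complete},
                                    site, forest))
        elif family == "UPO":
            up = classify_upo(length)
            calls.append(FamilyCall(rec.id, family, up.group, length, {}, site, forest))
        else:
            raise ValueError(f"unknown family {family!r}")
    return calls, translations


def load_anchor_specs(yaml_path, ref_fasta) -> dict[str, tuple[ProtRecord, AnchorSpec]]:
    """Load anchor configuration (family -> spec) plus its reference FASTA."""
    from peroxscan.sequence_core import read_fasta_protein

    refs = {r.id: r for r in read_fasta_protein(ref_fasta)}
    with open(yaml_path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, tuple[ProtRecord, AnchorSpec]] = {}
    for family, spec in raw.items():
        anchors = {int(p): (v["residue"], v.get("role", "")) for p, v in spec["anchors"].items()}
        aspec = AnchorSpec(ref_id=spec["ref_id"], family=family, anchors=anchors,
                           numbering_source=spec.get("numbering_source", ""))
        if spec["ref_id"] not in refs:
            raise ValueError(f"anchor reference {spec['ref_id']!r} missing from FASTA")
        out[family] = (refs[spec["ref_id"]], aspec)
    return out


def dump_anchor_specs(anchor_refs: Mapping[str, tuple[ProtRecord, AnchorSpec]]) -> str:
    """Serialize anchor specifications to the YAML layout ``load_anchor_specs`` reads."""
    doc = {}
    for family, (ref, spec) in sorted(anchor_refs.items()):
        doc[family] = {
            "ref_id": spec.ref_id,
            "numbering_source": spec.numbering_source,
            "anchors": {pos: {"residue": res, "role": role}
                        for pos, (res, role) in sorted(spec.anchors.items())},
        }
    return yaml.safe_dump(doc, sort_keys=True)


def _calls_frame(calls: Sequence[FamilyCall], translations: Mapping[str, ProtRecord]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=["record_id", "family", "label", "length_aa",
                                     "site", "forest_type", "protein"])
    rows = []
    for c in calls:
        row = {
            "record_id": c.record_id, "family": c.family, "label": c.label,
            "length_aa": c.length_aa, "site": c.site, "forest_type": c.forest_type,
            "protein": translations[c.record_id].seq,
        }
        for k, v in sorted(c.flags.items()):
            row[f"flag_{k}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("record_id").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow and write the report bundle.

    Returns the mapping of artifact names to written paths.  Outputs:
    calls.tsv, summary.tsv, dedup.tsv, shared.tsv, richness.tsv, one
    Newick tree per family with >= 3 unique types (when enabled), and
    manifest.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = {f: builtin_primer_pairs()[f] for f in config.families}

    # --- acquire inputs -------------------------------------------------
    sim_result: SimResult | None = None
    try:
        if config.sim is not None:
            sim_result = generate_pools(config.sim)
            pools = {s: list(v) for s, v in sim_result.pools.items()}
            anchor_refs = dict(sim_result.anchor_refs)
        else:
            from peroxscan.sequence_core import read_fasta

            pools = {}
            for site, path in sorted(config.template_fastas.items()):
                records = read_fasta(path)
                if not records:
                    raise EmptyInputError(f"no records in {path}")
                pools[site] = [
                    NucRecord(id=r.id, seq=r.seq, meta={"site": site}) for r in records
                ]
            if config.anchor_yaml is None or config.anchor_ref_fasta is None:
                raise ValueError("template input requires anchor_yaml and anchor_ref_fasta")
            anchor_refs = load_anchor_specs(config.anchor_yaml, config.anchor_ref_fasta)
    except (EmptyInputError, ValueError):
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("input", e)

    # --- stages ---------------------------------------------------------
    try:
        amplicons = amplify_pools(pools, pairs, config.max_mismatch)
    except EmptyInputError:
        raise
    except Exception as e:
        raise StageError("pcr", e)
    try:
        calls, translations = classify_amplicons(amplicons, anchor_refs, config.align)
    except Exception as e:
        raise StageError("classify", e)

    amp_records = [rec for rec, _ in amplicons]
    try:
        if amp_records:
            dedup = dereplicate(amp_records, level="PROTEIN", translations=translations)
            shared = shared_across_sites(dedup)
        else:
            from peroxscan.reporting import DedupReport

            dedup = DedupReport(total=0, unique_dna=0, unique_protein=0,
                                level="PROTEIN", clusters=())
            shared = []
    except Exception as e:
        raise StageError("dereplicate", e)

    try:
        summary = summarize_cohort(calls) if calls else pd.DataFrame()
        rich_rows = [
            {"group": LABEL_TO_GROUP[c.label], "forest_type": c.forest_type or "unknown",
             "protein": translations[c.record_id].seq}
            for c in calls
        ]
        richness = richness_table(rich_rows) if rich_rows else pd.DataFrame()
    except Exception as e:
        raise StageError("report", e)

    trees: dict[str, str] = {}
    if config.build_trees:
        try:
            by_family: dict[str, dict[str, str]] = {}
            for c in calls:
                fam = by_family.setdefault(c.family, {})
                prot = translations[c.record_id].seq
                if prot not in fam:  # unique protein types only
                    fam[prot] = c.record_id
            for family, uniq in sorted(by_family.items()):
                items = sorted((rid, prot) for prot, rid in uniq.items())[: config.tree_max_taxa]
                if len(items) < 3:
                    continue
                records = [ProtRecord(id=rid, seq=prot, partial=True) for rid, prot in items]
                msa = progressive_msa(records, config.align)
                tree = bootstrap_support(msa, config.bootstrap_replicates, config.tree_seed)
                trees[family] = write_newick(tree, min_support=config.min_support)
        except Exception as e:
            raise StageError("tree", e)

    # --- write bundle ---------------------------------------------------
    paths: dict[str, Path] = {}

    def put(name: str, text: str) -> None:
        p = out_dir / name
        _atomic_write(p, text)
        paths[name] = p

    calls_df = _calls_frame(calls, translations)
    put("calls.tsv", calls_df.to_csv(sep="\t", index=False))
    put("summary.tsv", summary.to_csv(sep="\t", index=False))
    dedup_df = pd.DataFrame(
        [
            {"representative": c.representative, "n_members": len(c.member_ids),
             "members": ",".join(c.member_ids), "sites": ",".join(sorted(c.sites))}
            for c in dedup.clusters
        ]
    )
    put("dedup.tsv", dedup_df.to_csv(sep="\t", index=False))
    shared_df = pd.DataFrame(
        [
            {"representative": c.representative, "n_sites": len(c.sites),
             "sites": ",".join(sorted(c.sites)), "members": ",".join(c.member_ids)}
            for c in shared
        ]
    )
    put("shared.tsv", shared_df.to_csv(sep="\t", index=False))
    put("richness.tsv", richness.to_csv(sep="\t"))
    for family, nwk in sorted(trees.items()):
        put(f"tree_{family}.nwk", nwk + "\n")
    if sim_result is not None:
        put("truth.tsv", sim_result.truth.to_dataframe().to_csv(sep="\t", index=False))

    manifest = {
        "package": "peroxscan",
        "version": _pkg_version,
        "config": _jsonable(config),
        "n_templates": sum(len(v) for v in pools.values()),
        "n_amplicons": len(amp_records),
        "n_calls": len(calls),
        "unique_dna": dedup.unique_dna,
        "unique_protein": dedup.unique_protein,
        "artifacts": sorted(paths),
    }
    put("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
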