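"""Dereplication, cross-site sharing, richness tables and activity units.

Amplicon surveys report unique sequence *types*: synonymous codon usage
makes nucleotide-level counts an upper bound on protein-level counts
(the survey pattern "76 unique on DNA, 71 on protein").  Enzyme
activities are converted from photometric slopes through the molar
extinction coefficient into enzyme units (1 U = 1 umol substrate per
minute), normalized to grams of dry litter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from peroxscan.sequence_core import NucRecord, ProtRecord, translate

__all__ = [
    "Cluster",
    "DedupReport",
    "AssayMeasurement",
    "RICHNESS_GROUPS",
    "dereplicate",
    "shared_across_sites",
    "richness_table",
    "activity_mU_per_gDM",
    "mip_activity",
    "MipActivity",
]

#: peroxidase groups of the richness table, in display order
RICHNESS_GROUPS = (
    "MnP short/unclassified",
    "MnP long",
    "LiP",
    "VP",
    "GP",
    "DyP",
    "UPO",
)


@dataclass(frozen=True)
class Cluster:
    """One unique sequence type: its representative, members and sites."""

    representative: str  # lexicographically smallest member id
    member_ids: tuple[str, ...]
    sites: frozenset[str]
    sequence: str


@dataclass(frozen=True)
class DedupReport:
    total: int
    unique_dna: int
    unique_protein: int
    level: str  # level the clusters below were built at
    clusters: tuple[Cluster, ...]

    def __post_init__(self) -> None:
        if not self.unique_protein <= self.unique_dna <= self.total:
            raise ValueError("expected unique_protein <= unique_dna <= total")


def _site_of(rec: NucRecord) -> str | None:
    return (rec.meta or {}).get("site")


def _cluster(keyed: list[tuple[str, str, str | None]]) -> tuple[Cluster, ...]:
    groups: dict[str, list[tuple[str, str | None]]] = {}
    for key, rid, site in keyed:
        groups.setdefault(key, []).append((rid, site))
    clusters = []
    for key, members in groups.items():
        ids = tuple(sorted(m[0] for m in members))
        sites = frozenset(m[1] for m in members if m[1] is not None)
        clusters.append(Cluster(representative=ids[0], member_ids=ids, sites=sites, sequence=key))
    return tuple(sorted(clusters, key=lambda c: c.representative))


def dereplicate(
    records: Sequence[NucRecord],
    level: str = "DNA",
    translations: Mapping[str, ProtRecord] | None = None,
) -> DedupReport:
    """Collapse exact-duplicate amplicons into unique types.

    DNA level clusters on the upper-cased nucleotide string; protein
    level on the translation in the frame annotated by the pipeline
    (``translations``), defaulting to frame 0 on the plus strand.  Site
    metadata is unioned per cluster.
    """
    if level not in ("DNA", "PROTEIN"):
        raise ValueError("level must be 'DNA' or 'PROTEIN'")
    if not records:
        raise ValueError("no records to dereplicate")

    def prot_seq(rec: NucRecord) -> str:
        if translations and rec.id in translations:
            return translations[rec.id].seq
        return translate(rec.seq, 0, "+").seq

    dna_keys = [(r.seq, r.id, _site_of(r)) for r in records]
    prot_keys = [(prot_seq(r), r.id, _site_of(r)) for r in records]
    unique_dna = len({k for k, _, _ in dna_keys})
    unique_protein = len({k for k, _, _ in prot_keys})
    clusters = _cluster(dna_keys if level == "DNA" else prot_keys)
    return DedupReport(
        total=len(records),
        unique_dna=unique_dna,
        unique_protein=unique_protein,
        level=level,
        clusters=clusters,
    )


def shared_across_sites(report: DedupReport) -> list[Cluster]:
    """Clusters detected in at least two distinct sites."""
    return [c for c in report.clusters if len(c.sites) >= 2]


def richness_table(
    calls: Iterable[Mapping],
    groups: Sequence[str] = RICHNESS_GROUPS,
    forest_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Unique protein types per (peroxidase group, forest type).

    Each call must carry ``group``, ``forest_type`` and ``protein``
    (the translated sequence used for uniqueness).  Unknown group labels
    raise; forest-type columns default to those observed.
    """
    rows = list(calls)
    seen: dict[tuple[str, str], set[str]] = {}
    observed_ft: list[str] = []
    for c in rows:
        g, ft, prot = c["group"], c["forest_type"], c["protein"]
        if g not in groups:
            raise ValueError(f"unknown peroxidase group label {g!r}")
        if ft not in observed_ft:
            observed_ft.append(ft)
        seen.setdefault((g, ft), set()).add(prot)
    cols = list(forest_types) if forest_types is not None else sorted(observed_ft)
    if forest_types is not None:
        unknown = set(observed_ft) - set(cols)
        if unknown:
            raise ValueError(f"unknown forest type label(s) {sorted(unknown)}")
    data = {ft: [len(seen.get((g, ft), ())) for g in groups] for ft in cols}
    return pd.DataFrame(data, index=list(groups), columns=cols)


@dataclass(frozen=True)
class AssayMeasurement:
    """One photometric rate measurement and its assay geometry.

    slope: absorbance change per minute; epsilon in M^-1 cm^-1; cuvette
    path in cm; assay and extract-aliquot volumes in mL; extraction as
    (grams of sample, mL of water); dry-matter fraction of the sample.
    """

    slope: float
    epsilon: float
    path_cm: float = 1.0
    assay_volume_mL: float = 1.0
    extract_volume_mL: float = 0.05
    extraction_g: float = 10.0
    extraction_mL: float = 100.0
    dry_matter_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_cm", "assay_volume_mL", "extract_volume_mL",
                     "extraction_g", "extraction_mL", "dry_matter_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")
        if self.dry_matter_fraction > 1:
            raise ValueError("dry_matter_fraction must be <= 1")


def activity_mU_per_gDM(m: AssayMeasurement) -> float:
    """Convert a photometric slope into mU per gram dry matter.

    Beer–Lambert gives the substrate turnover rate slope/(epsilon x path)
    in mol L^-1 min^-1; scaled to umol/min in the assay volume (enzyme
    units), from the extract aliquot up to the whole extract, and
    normalized by grams of dry matter.
    """
    rate_M_per_min = m.slope / (m.epsilon * m.path_cm)
    umol_per_min_in_assay = rate_M_per_min * (m.assay_volume_mL / 1000.0) * 1e6
    u_per_mL_extract = umol_per_min_in_assay / m.extract_volume_mL
    u_total = u_per_mL_extract * m.extraction_mL
    g_dm = m.extraction_g * m.dry_matter_fraction
    return u_total / g_dm * 1000.0  # U -> mU


class MipActivity(NamedTuple):
    activity_mU: float
    clamped: bool


def mip_activity(total_with_peroxide: float, laccase_without_peroxide: float) -> MipActivity:
    """Mn-independent peroxidase activity: peroxide-dependent total minus laccase.

    A negative difference is physically meaningless and clamps to zero
    with an explicit flag.
    """
    if total_with_peroxide < 0 or laccase_without_peroxide < 0:
        raise ValueError("activities must be non-negative")
    diff = total_with_peroxide - laccase_without_peroxide
    if diff < 0:
        return MipActivity(0.0, True)
    return MipActivity(diff, False)
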