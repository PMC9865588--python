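"""Gene-level burden, cross-patient sharing, literature-list intersection,
per-patient profiles and candidate-gene assembly.

Burden is per-gene evidence, not a partition: a variant annotated to a
gene contributes to that gene's count on every track it passes.  Sharing
records count, for each pathogenic variant, the cohort patients carrying
at least one alternative allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

from .filters import FilterConfig, filter_rare
from .models import AnnotatedVariant, CohortTable, GeneList, VariantKey
from .pathogenicity import ClassifierConfig, PathogenicityCall, normalize_clinvar_label

logger = logging.getLogger(__name__)

UNANNOTATED = "UNANNOTATED"


@dataclass(frozen=True)
class GeneBurden:
    gene: str
    n_clinvar_track: int
    n_score_track: int
    n_any: int
    variant_keys: tuple[VariantKey, ...]  # any-track variants on this gene

    def __post_init__(self) -> None:
        assert self.n_any == len(self.variant_keys)
        assert self.n_any <= self.n_clinvar_track + self.n_score_track


@dataclass(frozen=True)
class SharingRecord:
    variant_key: VariantKey
    gene: str
    carriers: tuple[str, ...]

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def _gene_of(variant: AnnotatedVariant) -> str:
    if not variant.gene:
        logger.warning("variant %s has no gene symbol; assigned to %s", variant.key, UNANNOTATED)
        return UNANNOTATED
    return variant.gene


def gene_burden_counts(
    table: CohortTable, calls: dict[VariantKey, PathogenicityCall]
) -> list[GeneBurden]:
    """Per-gene pathogenic-variant counts, sorted by any-track burden
    (descending), ties broken lexicographically by symbol."""
    per_gene: dict[str, dict[str, list[VariantKey]]] = {}
    for v in table.variants:
        call = calls[v.key]
        if not call.any_track:
            continue
        bucket = per_gene.setdefault(_gene_of(v), {"clinvar": [], "score": [], "any": []})
        if call.clinvar_track:
            bucket["clinvar"].append(v.key)
        if call.score_track:
            bucket["score"].append(v.key)
        bucket["any"].append(v.key)
    burdens = [
        GeneBurden(
            gene=gene,
            n_clinvar_track=len(b["clinvar"]),
            n_score_track=len(b["score"]),
            n_any=len(b["any"]),
            variant_keys=tuple(b["any"]),
        )
        for gene, b in per_gene.items()
    ]
    burdens.sort(key=lambda b: (-b.n_any, b.gene))
    return burdens


def sharing_matrix(
    table: CohortTable,
    calls: dict[VariantKey, PathogenicityCall] | None = None,
) -> list[SharingRecord]:
    """Carrier lists per (pathogenic) variant, most-shared first.

    With ``calls`` given, only any-track pathogenic variants are listed;
    without, every variant in the table is.
    """
    records = []
    for v in table.variants:
        if calls is not None and not calls[v.key].any_track:
            continue
        records.append(
            SharingRecord(variant_key=v.key, gene=_gene_of(v), carriers=tuple(table.carriers(v.key)))
        )
    records.sort(key=lambda r: (-r.n_carriers, r.variant_key))
    return records


def sharing_histogram(records: list[SharingRecord]) -> dict[int, int]:
    """carrier count -> number of variants with that many carriers."""
    return dict(sorted(Counter(r.n_carriers for r in records).items()))


def intersect_gene_list(
    table: CohortTable, gene_list: GeneList, uppercase: bool = False
) -> CohortTable:
    """Restrict the cohort to variants whose gene symbol is on the list.

    Matching is case-sensitive unless ``uppercase=True`` normalizes both
    sides.  The per-gene tally is logged.
    """
    listed = {g.upper() for g in gene_list.genes} if uppercase else set(gene_list.genes)

    def hit(v: AnnotatedVariant) -> bool:
        if not v.gene:
            return False
        return (v.gene.upper() if uppercase else v.gene) in listed

    keep = [i for i, v in enumerate(table.variants) if hit(v)]
    tally = Counter(table.variants[i].gene for i in keep)
    logger.info("gene-list intersection (%s): %d variants; per gene: %s",
                gene_list.name, len(keep), dict(tally))
    return table.subset(keep)


@dataclass(frozen=True)
class PatientProfile:
    """Variants carried by one patient: strict dual-track pathogenic calls
    plus a relaxed "rescue" re-screen (any single criterion component)."""

    patient_id: str
    pathogenic: tuple[VariantKey, ...]  # any-track
    rescue: tuple[VariantKey, ...]      # >=1 single criterion component


def _single_criterion(v: AnnotatedVariant, config: ClassifierConfig) -> bool:
    p = v.patho
    return (
        (p.clinvar_label is not None
         and normalize_clinvar_label(p.clinvar_label) in config.clinvar_whitelist)
        or (p.cadd_phred is not None and p.cadd_phred > config.cadd_min)
        or (p.revel is not None and p.revel >= config.revel_min)
    )


def patient_profile(
    table: CohortTable,
    calls: dict[VariantKey, PathogenicityCall],
    patient_id: str,
    config: ClassifierConfig | None = None,
) -> PatientProfile:
    """Pathogenic and near-miss variants carried by one patient.

    The rescue list relaxes the score track's conjunction: a rare variant
    qualifies if it satisfies at least one criterion component in
    isolation (whitelisted ClinVar label OR CADD above threshold OR REVEL
    at/above threshold).
    """
    config = config or ClassifierConfig()
    if patient_id not in table.patient_ids:
        raise KeyError(f"unknown patient id {patient_id!r}")
    j = table.patient_ids.index(patient_id)
    pathogenic, rescue = [], []
    for v, row in zip(table.variants, table.genotypes):
        if row[j] < 1:
            continue
        if calls[v.key].any_track:
            pathogenic.append(v.key)
        if _single_criterion(v, config):
            rescue.append(v.key)
    return PatientProfile(patient_id, tuple(pathogenic), tuple(rescue))


def candidate_gene_set(
    table: CohortTable,
    calls: dict[VariantKey, PathogenicityCall],
    gene_list: GeneList | None = None,
    mode: str = "union",
) -> GeneList:
    """Assemble the candidate genes for functional annotation.

    ``mode="union"`` (default): genes carrying at least one any-track
    pathogenic variant, united with literature-list genes carrying at
    least one rare variant in the cohort.  ``mode="pathogenic_only"``
    drops the second component.
    """
    pathogenic_genes = {
        _gene_of(v) for v in table.variants if calls[v.key].any_track
    }
    if mode == "pathogenic_only" or gene_list is None:
        genes = pathogenic_genes
    elif mode == "union":
        list_hits = {v.gene for v in table.variants if v.gene and v.gene in gene_list}
        genes = pathogenic_genes | list_hits
    else:
        raise ValueError(f"unknown candidate mode {mode!r}")
    return GeneList(name="candidate_genes", genes=frozenset(genes - {UNANNOTATED}))


def rare_then_intersect_commutes(
    table: CohortTable, gene_list: GeneList, config: FilterConfig | None = None
) -> bool:
    """Diagnostic: gene-list intersection commutes with the rarity filter."""
    config = config or FilterConfig()
    a = intersect_gene_list(filter_rare(table, config), gene_list)
    b = filter_rare(intersect_gene_list(table, gene_list), config)
    return a.equals(b)
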