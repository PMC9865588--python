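"""End-to-end orchestration: consequence filter -> rarity filter ->
dual-track classification -> burden/sharing -> literature-list
intersection -> candidate genes -> (optional mouse mapping) -> ORA.

Every stage's output is written even when empty, so downstream tooling
has a stable contract; the machine-readable run summary records the
in/out count of each stage (non-increasing along the filter cascade) and
echoes the configuration.  Re-running on identical inputs and
configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as svio
from .burden import (
    GeneBurden,
    PatientProfile,
    SharingRecord,
    candidate_gene_set,
    gene_burden_counts,
    intersect_gene_list,
    patient_profile,
    sharing_histogram,
    sharing_matrix,
)
from .enrichment import OraConfig, OraReport, map_to_mouse, run_ora, write_ora_table
from .filters import FilterConfig, filter_consequence, filter_rare
from .models import CohortTable, GeneList, GeneSetCollection
from .pathogenicity import (
    ClassifierConfig,
    PathogenicityCall,
    calls_to_rows,
    classify_cohort,
    summarize_tracks,
    TrackSummary,
)
from .models import VariantKey

logger = logging.getLogger(__name__)

STAGE_EXIT_CODES = {
    "read": 2,
    "filter": 3,
    "classify": 4,
    "burden": 5,
    "intersect": 6,
    "enrich": 7,
    "write": 8,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit code."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ora: OraConfig = field(default_factory=OraConfig)
    candidate_mode: str = "union"

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        """Load a structured-text config; sections filter / classifier /
        ora / candidate_mode, keys mirroring the dataclass fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fkw = dict(raw.get("filter", {}))
        if "allowed_consequences" in fkw:
            fkw["allowed_consequences"] = frozenset(fkw["allowed_consequences"])
        ckw = dict(raw.get("classifier", {}))
        if "clinvar_whitelist" in ckw:
            ckw["clinvar_whitelist"] = frozenset(ckw["clinvar_whitelist"])
        return PipelineConfig(
            filter=FilterConfig(**fkw),
            classifier=ClassifierConfig(**ckw),
            ora=OraConfig(**dict(raw.get("ora", {}))),
            candidate_mode=raw.get("candidate_mode", "union"),
        )


def _config_echo(config: PipelineConfig) -> dict:
    def plain(obj):
        d = dataclasses.asdict(obj)
        return {k: sorted(v) if isinstance(v, frozenset) else v for k, v in d.items()}

    return {
        "filter": plain(config.filter),
        "classifier": plain(config.classifier),
        "ora": plain(config.ora),
        "candidate_mode": config.candidate_mode,
    }


@dataclass(frozen=True)
class RunSummary:
    """Counts per stage plus a config echo; JSON-serializable."""

    n_input: int
    n_after_consequence: int
    n_after_rarity: int
    n_clinvar_track: int
    n_score_track: int
    n_both_tracks: int
    n_any_track: int
    n_genes_clinvar: int
    n_genes_score: int
    n_genes_any: int
    n_singletons: int
    max_carriers: int
    n_list_variants: int
    n_candidate_genes: int
    n_mapped_mouse: int
    n_unmapped_mouse: int
    n_sets_tested: int
    n_significant_sets: int
    config: dict
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.n_input >= self.n_after_consequence >= self.n_after_rarity
        assert self.n_any_track == (
            self.n_clinvar_track + self.n_score_track - self.n_both_tracks
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    summary: RunSummary
    rare_table: CohortTable
    calls: dict[VariantKey, PathogenicityCall]
    tracks: TrackSummary
    burdens: list[GeneBurden]
    sharing: list[SharingRecord]
    list_hits: Optional[CohortTable]
    candidates: GeneList
    profiles: dict[str, PatientProfile]
    mouse_query: Optional[GeneList]
    unmapped: list[str]
    ora: Optional[OraReport]


def run_pipeline(
    cohort: CohortTable,
    gene_list: Optional[GeneList] = None,
    collection: Optional[GeneSetCollection] = None,
    mapping: Optional[dict[str, str]] = None,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full prioritization cascade on an annotated cohort.

    ``gene_list``, ``collection`` and ``mapping`` are optional: without a
    collection the ORA stage is skipped; without a mapping the query goes
    to ORA on human symbols; the mapping is applied only when both are
    given.
    """
    config = config or PipelineConfig()
    try:
        by_consequence = filter_consequence(cohort, config.filter)
        rare = filter_rare(by_consequence, config.filter)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("filter", str(exc)) from exc
    logger.info(
        "cascade: %d input -> %d consequence -> %d rare",
        cohort.n_variants, by_consequence.n_variants, rare.n_variants,
    )

    try:
        calls = classify_cohort(rare, config.classifier)
        tracks = summarize_tracks(rare, calls)
    except Exception as exc:  # pragma: no cover
        raise StageError("classify", str(exc)) from exc

    try:
        burdens = gene_burden_counts(rare, calls)
        sharing = sharing_matrix(rare, calls)
        profiles = {
            p.patient_id: patient_profile(rare, calls, p.patient_id, config.classifier)
            for p in rare.patients
        }
    except Exception as exc:  # pragma: no cover
        raise StageError("burden", str(exc)) from exc

    try:
        list_hits = intersect_gene_list(rare, gene_list) if gene_list is not None else None
        candidates = candidate_gene_set(rare, calls, gene_list, mode=config.candidate_mode)
    except Exception as exc:  # pragma: no cover
        raise StageError("intersect", str(exc)) from exc

    mouse_query: Optional[GeneList] = None
    unmapped: list[str] = []
    ora: Optional[OraReport] = None
    if collection is not None and len(candidates) > 0:
        try:
            query = candidates
            if mapping is not None:
                mouse_query, unmapped = map_to_mouse(candidates, mapping)
                query = mouse_query
            ora = run_ora(query, collection, config.ora)
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc

    histogram = sharing_histogram(sharing)
    summary = RunSummary(
        n_input=cohort.n_variants,
        n_after_consequence=by_consequence.n_variants,
        n_after_rarity=rare.n_variants,
        n_clinvar_track=tracks.n_clinvar,
        n_score_track=tracks.n_score,
        n_both_tracks=tracks.n_both,
        n_any_track=tracks.n_union,
        n_genes_clinvar=tracks.n_genes_clinvar,
        n_genes_score=tracks.n_genes_score,
        n_genes_any=tracks.n_genes_union,
        n_singletons=histogram.get(1, 0),
        max_carriers=max(histogram) if histogram else 0,
        n_list_variants=list_hits.n_variants if list_hits is not None else 0,
        n_candidate_genes=len(candidates),
        n_mapped_mouse=len(mouse_query) if mouse_query is not None else 0,
        n_unmapped_mouse=len(unmapped),
        n_sets_tested=ora.m if ora is not None else 0,
        n_significant_sets=(
            sum(r.significant for r in ora.results) if ora is not None else 0
        ),
        config=_config_echo(config),
        seed=seed,
    )
    result = PipelineResult(
        summary=summary, rare_table=rare, calls=calls, tracks=tracks,
        burdens=burdens, sharing=sharing, list_hits=list_hits,
        candidates=candidates, profiles=profiles, mouse_query=mouse_query,
        unmapped=unmapped, ora=ora,
    )
    if outdir is not None:
        try:
            write_outputs(result, outdir)
        except Exception as exc:  # pragma: no cover
            raise StageError("write", str(exc)) from exc
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage artifact (always, even when empty)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    svio.write_annotated_table(result.rare_table, outdir / "variants_rare.tsv")
    with open(outdir / "pathogenicity_calls.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tclinvar_track\tscore_track\tany_track\tboth_tracks\n")
        for row in calls_to_rows(result.rare_table, result.calls):
            fh.write("\t".join(str(row[c]) for c in (
                "chrom", "pos", "ref", "alt", "gene",
                "clinvar_track", "score_track", "any_track", "both_tracks")) + "\n")
    with open(outdir / "gene_burden.tsv", "w") as fh:
        fh.write("gene\tn_clinvar_track\tn_score_track\tn_any\n")
        for b in result.burdens:
            fh.write(f"{b.gene}\t{b.n_clinvar_track}\t{b.n_score_track}\t{b.n_any}\n")
    with open(outdir / "sharing.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tn_carriers\tcarriers\n")
        for r in result.sharing:
            chrom, pos, ref, alt = r.variant_key
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{r.gene}\t{r.n_carriers}\t"
                     f"{','.join(r.carriers)}\n")
    with open(outdir / "sharing_histogram.tsv", "w") as fh:
        fh.write("n_carriers\tn_variants\n")
        for n_carriers, count in sharing_histogram(result.sharing).items():
            fh.write(f"{n_carriers}\t{count}\n")
    if result.list_hits is not None:
        svio.write_annotated_table(result.list_hits, outdir / "ais_list_variants.tsv")
    with open(outdir / "candidate_genes.txt", "w") as fh:
        for gene in sorted(result.candidates.genes):
            fh.write(gene + "\n")
    with open(outdir / "patient_profiles.tsv", "w") as fh:
        fh.write("patient_id\tn_pathogenic\tn_rescue\tpathogenic_genes\n")
        for pid in result.rare_table.patient_ids:
            profile = result.profiles[pid]
            genes = ",".join(
                result.rare_table.variant(k).gene or "UNANNOTATED"
                for k in profile.pathogenic
            )
            fh.write(f"{pid}\t{len(profile.pathogenic)}\t{len(profile.rescue)}\t{genes}\n")
    if result.ora is not None:
        write_ora_table(result.ora, outdir / "ora.tsv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report(result))


def render_report(result: PipelineResult) -> str:
    """Deterministic human-readable run report."""
    s = result.summary
    lines = [
        "severe-AIS rare-variant prioritization report",
        "=" * 45,
        "",
        "Filter cascade",
        f"  variants in:                {s.n_input}",
        f"  after consequence filter:   {s.n_after_consequence}",
        f"  after rarity filter:        {s.n_after_rarity}",
        "",
        "Pathogenicity tracks (variants / genes)",
        f"  ClinVar track:     {s.n_clinvar_track} / {s.n_genes_clinvar}",
        f"  CADD+REVEL track:  {s.n_score_track} / {s.n_genes_score}",
        f"  both tracks:       {s.n_both_tracks}",
        f"  either track:      {s.n_any_track} / {s.n_genes_any}",
        "",
        "Dual-evidence variants (both tracks)",
    ]
    dual = [v for v in result.rare_table.variants if result.calls[v.key].both_tracks]
    header = f"  {'locus':<22}{'gene':<10}{'ClinVar':<46}{'CADD':>6}{'REVEL':>7}  carriers"
    lines.append(header)
    for v in dual:
        locus = f"{v.chrom}:{v.pos}{v.ref}>{v.alt}"
        lines.append(
            f"  {locus:<22}{v.gene or 'UNANNOTATED':<10}"
            f"{v.patho.clinvar_label or '-':<46}"
            f"{v.patho.cadd_phred:>6}{v.patho.revel:>7}"
            f"  {','.join(result.rare_table.carriers(v.key))}"
        )
    lines += ["", "Top gene burdens (any track)"]
    lines.append(f"  {'gene':<12}{'ClinVar':>8}{'scores':>8}{'any':>6}")
    for b in result.burdens[:10]:
        lines.append(f"  {b.gene:<12}{b.n_clinvar_track:>8}{b.n_score_track:>8}{b.n_any:>6}")
    lines += ["", "Sharing histogram (pathogenic variants)"]
    lines.append("  carriers  variants")
    for n_carriers, count in sharing_histogram(result.sharing).items():
        lines.append(f"  {n_carriers:>8}  {count}")
    if result.list_hits is not None:
        lines += ["", f"AIS literature-gene variants: {s.n_list_variants}"]
        for v in result.list_hits.variants:
            lines.append(
                f"  {v.chrom}:{v.pos}{v.ref}>{v.alt}  {v.gene}"
                f"  carriers={','.join(result.list_hits.carriers(v.key))}"
            )
    lines += ["", f"Candidate genes: {s.n_candidate_genes}"]
    if s.n_mapped_mouse or s.n_unmapped_mouse:
        lines.append(
            f"  mapped to mouse: {s.n_mapped_mouse} (unmapped: {s.n_unmapped_mouse})"
        )
    if result.ora is not None:
        lines += [
            "",
            f"Over-representation analysis: m={result.ora.m} sets, "
            f"N={result.ora.n_background} background genes, n={result.ora.n_query} query",
            f"  significant at q<{result.ora.q_threshold:g}: {s.n_significant_sets}",
            f"  {'set':<14}{'K':>5}{'k':>4}{'p':>12}{'q':>12}",
        ]
        for r in result.ora.results[:5]:
            lines.append(
                f"  {r.set_name:<14}{r.K:>5}{r.k:>4}{r.p:>12.3e}{r.q:>12.3e}"
                + ("  *" if r.significant else "")
            )
    return "\n".join(lines) + "\n"
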