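"""Synthetic severe-AIS exome cohorts with planted, recoverable structure.

The study this pipeline targets (11 unrelated severe-scoliosis patients,
heterozygous nonsynonymous SNVs, four East-Asian population-frequency
panels, ClinVar/CADD/REVEL annotations) did not share its raw data, so
the generator emits cohorts with the same *statistical shape* plus a
truth file, making every pipeline stage testable without any download.

Default plants reproduce the study-scale identities by construction:

* 87 ClinVar-track variants on 76 genes (one gene carrying 8),
* 136 score-track variants on 130 genes (one gene carrying 3),
* 7 dual-evidence variants, hence 216 any-track variants, 213 of them
  private to one patient (one variant shared by 4 patients, two by 2),
* 206 candidate genes, 200 of which map to mouse symbols,
* one (K=83, k=9) planted gene set among 326 tested sets on a
  12000-gene universe.

All randomness flows from one seeded generator in a fixed draw order, so
a seed fully determines the emitted files byte-for-byte.  Planted
variants draw annotations strictly inside their track's acceptance
region (e.g. CADD in [22, 38] and REVEL in [0.78, 0.98] for score-track
plants; frequencies at most 0.009) so classification recovers them
exactly under either rarity-threshold mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as svio
from .models import (
    AnnotatedVariant,
    CohortTable,
    GeneList,
    GeneSetCollection,
    PathoAnnotations,
    PatientRecord,
    PopulationFrequencies,
    VALID_CHROMS,
    VariantKey,
)
from .pathogenicity import PathogenicityCall

DEFAULT_LABEL_FREQUENCIES = {
    "Pathogenic": 0.30,
    "Likely_pathogenic": 0.20,
    "Pathogenic/Likely_pathogenic": 0.10,
    "Conflicting_interpretations_of_pathogenicity": 0.30,
    "association": 0.10,
}
BENIGN_LABELS = ("Benign", "Likely_benign", "Uncertain_significance", None)
BENIGN_LABEL_PROBS = (0.25, 0.20, 0.30, 0.25)
MISSING_FREQ_PROB = {"twb": 0.35, "kgp_eas": 0.45, "gnomad_eas": 0.15, "exac_eas": 0.15}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort (defaults = study shape)."""

    n_patients: int = 11
    n_female: int = 8
    age_range: tuple[int, int] = (14, 25)
    cobb_range: tuple[float, float] = (41.0, 90.0)
    # planted structure
    planted_burden: tuple[tuple[str, int, str], ...] = (
        ("GENE_A", 8, "clinvar"),
        ("GENE_B", 3, "score"),
    )
    planted_dual: int = 7
    planted_shared: tuple[tuple[int, str], ...] = ((4, "score"), (2, "score"), (2, "clinvar"))
    # background pathogenic variants (private, one per patient draw)
    n_background_clinvar: int = 71
    n_background_clinvar_genes: int = 67
    n_background_score: int = 124
    n_background_score_genes: int = 120
    # rare benign variants planted in literature-list genes
    n_list_rare: int = 11
    n_list_genes: int = 10
    n_list_pathogenic_overlap: int = 3
    # non-qualifying filler exercising the filters
    n_benign_rare: int = 50
    n_common: int = 40
    n_synonymous: int = 60
    # annotation draw parameters
    maf_rare_max: float = 0.009
    cadd_pathogenic: tuple[float, float] = (22.0, 38.0)
    revel_pathogenic: tuple[float, float] = (0.78, 0.98)
    cadd_benign: tuple[float, float] = (0.5, 19.0)
    revel_benign: tuple[float, float] = (0.01, 0.70)
    clinvar_label_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_FREQUENCIES)
    )
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_female > self.n_patients:
            raise ValueError("n_female exceeds n_patients")
        for n_carriers, track in self.planted_shared:
            if n_carriers > self.n_patients:
                raise ValueError(
                    f"shared plant wants {n_carriers} carriers but the cohort has "
                    f"only {self.n_patients} patients"
                )
            if track not in ("clinvar", "score"):
                raise ValueError(f"unknown track {track!r} in shared plant")
        for gene, n, track in self.planted_burden:
            if track not in ("clinvar", "score"):
                raise ValueError(f"unknown track {track!r} in burden plant for {gene}")
        if self.n_background_clinvar_genes > self.n_background_clinvar:
            raise ValueError("more ClinVar background genes than variants")
        if self.n_background_score_genes > self.n_background_score:
            raise ValueError("more score background genes than variants")
        if self.n_list_pathogenic_overlap > self.n_list_genes:
            raise ValueError("list/pathogenic overlap exceeds the number of list genes")
        if not (0 < self.maf_rare_max < 0.01):
            raise ValueError("maf_rare_max must keep plants below the 0.01 threshold")


@dataclass(frozen=True)
class TruthRecord:
    variant_key: VariantKey
    gene: str
    track: str  # "clinvar" | "score" | "both" | "none"
    carriers: tuple[str, ...]
    role: str


class _Sim:
    """Stateful helpers around one deterministic random stream."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.used_loci: set[tuple[str, int]] = set()

    def locus(self) -> tuple[str, int, str, str]:
        while True:
            chrom = str(self.rng.choice(VALID_CHROMS[:23]))  # autosomes + X
            pos = int(self.rng.integers(100_000, 240_000_000))
            if (chrom, pos) not in self.used_loci:
                self.used_loci.add((chrom, pos))
                break
        ref, alt = self.rng.choice(list("ACGT"), size=2, replace=False)
        return chrom, pos, str(ref), str(alt)

    def rare_freqs(self) -> PopulationFrequencies:
        values = {}
        for source, p_miss in MISSING_FREQ_PROB.items():
            if self.rng.random() < p_miss:
                values[source] = None
            else:
                values[source] = round(float(self.rng.uniform(1e-5, self.cfg.maf_rare_max)), 6)
        return PopulationFrequencies(**values)

    def common_freqs(self) -> PopulationFrequencies:
        values = {}
        hot = self.rng.choice(list(MISSING_FREQ_PROB))
        for source, p_miss in MISSING_FREQ_PROB.items():
            if source == hot:
                values[source] = round(float(self.rng.uniform(0.02, 0.5)), 4)
            elif self.rng.random() < p_miss:
                values[source] = None
            else:
                values[source] = round(float(self.rng.uniform(1e-5, 0.5)), 4)
        return PopulationFrequencies(**values)

    def whitelist_label(self) -> str:
        labels = list(self.cfg.clinvar_label_frequencies)
        probs = np.array(list(self.cfg.clinvar_label_frequencies.values()))
        return str(self.rng.choice(labels, p=probs / probs.sum()))

    def benign_label(self) -> Optional[str]:
        i = self.rng.choice(len(BENIGN_LABELS), p=BENIGN_LABEL_PROBS)
        return BENIGN_LABELS[i]

    def pathogenic_scores(self) -> tuple[float, float]:
        cadd = round(float(self.rng.uniform(*self.cfg.cadd_pathogenic)), 1)
        revel = round(float(self.rng.uniform(*self.cfg.revel_pathogenic)), 3)
        return cadd, revel

    def benign_scores(self) -> tuple[Optional[float], Optional[float]]:
        cadd = round(float(self.rng.uniform(*self.cfg.cadd_benign)), 1)
        revel = round(float(self.rng.uniform(*self.cfg.revel_benign)), 3)
        if self.rng.random() < 0.2:
            cadd = None
        if self.rng.random() < 0.2:
            revel = None
        return cadd, revel

    def patho(self, track: str) -> PathoAnnotations:
        if track == "clinvar":
            cadd, revel = self.benign_scores()
            return PathoAnnotations(self.whitelist_label(), cadd, revel)
        if track == "score":
            cadd, revel = self.pathogenic_scores()
            return PathoAnnotations(self.benign_label(), cadd, revel)
        if track == "both":
            cadd, revel = self.pathogenic_scores()
            return PathoAnnotations(self.whitelist_label(), cadd, revel)
        cadd, revel = self.benign_scores()
        return PathoAnnotations(self.benign_label(), cadd, revel)

    def patients(self) -> list[PatientRecord]:
        cfg = self.cfg
        sexes = ["F"] * cfg.n_female + ["M"] * (cfg.n_patients - cfg.n_female)
        self.rng.shuffle(sexes)
        records = []
        for i in range(cfg.n_patients):
            n_curves = int(self.rng.integers(1, 4))
            curves = tuple(
                (
                    f"T{int(self.rng.integers(1, 13))}-L{int(self.rng.integers(1, 5))}",
                    round(float(self.rng.uniform(*cfg.cobb_range)), 0),
                )
                for _ in range(n_curves)
            )
            records.append(
                PatientRecord(
                    patient_id=f"Pt{i + 1}",
                    sex=sexes[i],
                    age=int(self.rng.integers(cfg.age_range[0], cfg.age_range[1] + 1)),
                    curves=curves,
                )
            )
        return records


def _chrom_sort_key(v: AnnotatedVariant) -> tuple[int, int]:
    order = {c: i for i, c in enumerate(VALID_CHROMS)}
    return order[v.chrom], v.pos


def generate_cohort(config: SimConfig | None = None) -> tuple[CohortTable, list[TruthRecord]]:
    """Generate one cohort and its planted truth, deterministically.

    Unsatisfiable plant specifications fail in :class:`SimConfig`
    validation before any output is produced.
    """
    cfg = config or SimConfig()
    sim = _Sim(cfg)
    patients = sim.patients()
    patient_ids = [p.patient_id for p in patients]

    entries: list[tuple[AnnotatedVariant, tuple[str, ...], str, str]] = []
    # (variant, carriers, truth track, role)

    def singleton_carrier() -> tuple[str, ...]:
        return (patient_ids[int(sim.rng.integers(cfg.n_patients))],)

    def add(gene: str, track: str, role: str, carriers: Optional[tuple[str, ...]] = None,
            consequence: tuple[str, ...] = ("nonsynonymous SNV",),
            freqs: Optional[PopulationFrequencies] = None) -> None:
        chrom, pos, ref, alt = sim.locus()
        entries.append(
            (
                AnnotatedVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    consequence=consequence,
                    freqs=freqs if freqs is not None else sim.rare_freqs(),
                    patho=sim.patho(track),
                ),
                carriers if carriers is not None else singleton_carrier(),
                track,
                role,
            )
        )

    # planted gene burdens
    for gene, n, track in cfg.planted_burden:
        for _ in range(n):
            add(gene, track, f"burden:{gene}")
    # planted dual-evidence variants, one gene each
    for i in range(cfg.planted_dual):
        add(f"GENE_D{i + 1}", "both", "dual")
    # planted shared variants, one gene each
    for i, (n_carriers, track) in enumerate(cfg.planted_shared):
        carriers = tuple(
            str(x) for x in sim.rng.choice(patient_ids, size=n_carriers, replace=False)
        )
        add(f"GENE_S{i + 1}", track, f"shared:{n_carriers}", carriers=carriers)

    # private background pathogenic variants
    def background_genes(prefix: str, n_variants: int, n_genes: int,
                         replace_with: Sequence[str] = ()) -> list[str]:
        genes = [f"{prefix}{i + 1:03d}" for i in range(n_genes)]
        for i, symbol in enumerate(replace_with):
            genes[n_genes - 1 - i] = symbol
        # surplus variants double up the first genes
        return genes + genes[: n_variants - n_genes]

    ais_panel = sorted(svio.load_ais_gene_list().genes)
    list_gene_pool = [str(g) for g in sim.rng.choice(ais_panel, size=cfg.n_list_genes, replace=False)]
    overlap_genes = list_gene_pool[: cfg.n_list_pathogenic_overlap]

    for gene in background_genes("BGC", cfg.n_background_clinvar, cfg.n_background_clinvar_genes):
        add(gene, "clinvar", "background_clinvar")
    for gene in background_genes(
        "BGS", cfg.n_background_score, cfg.n_background_score_genes, replace_with=overlap_genes
    ):
        add(gene, "score", "background_score")

    # rare benign variants in literature-panel genes (one gene doubled when
    # n_list_rare exceeds n_list_genes)
    list_assignment = list_gene_pool + list_gene_pool[: cfg.n_list_rare - cfg.n_list_genes]
    for gene in list_assignment:
        add(gene, "none", "list_rare")

    # filler: rare benign, common, synonymous
    for i in range(cfg.n_benign_rare):
        consequence = (
            ("nonsynonymous SNV", "synonymous SNV") if i < 5 else ("nonsynonymous SNV",)
        )
        add(f"BEN{i + 1:03d}", "none", "benign_rare", consequence=consequence)
    for i in range(cfg.n_common):
        add(f"COM{i + 1:03d}", "none", "common", freqs=sim.common_freqs())
    for i in range(cfg.n_synonymous):
        add(f"SYN{i + 1:03d}", "none", "synonymous", consequence=("synonymous SNV",))

    entries.sort(key=lambda e: _chrom_sort_key(e[0]))
    variants = [e[0] for e in entries]
    genotypes = np.zeros((len(variants), cfg.n_patients), dtype=np.int8)
    col = {pid: j for j, pid in enumerate(patient_ids)}
    for i, (_, carriers, _, _) in enumerate(entries):
        for pid in carriers:
            genotypes[i, col[pid]] = 1  # heterozygous: one copy per carrier
    table = CohortTable(variants, patients, genotypes)
    truth = [
        TruthRecord(v.key, v.gene or "", track, carriers, role)
        for v, carriers, track, role in entries
    ]
    return table, truth


def write_cohort(
    table: CohortTable, truth: list[TruthRecord], outdir: str | Path
) -> dict[str, Path]:
    """Emit cohort TSV, patient metadata and truth TSV (text only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "patients": outdir / "patients.tsv",
        "truth": outdir / "truth.tsv",
    }
    svio.write_annotated_table(table, paths["cohort"])
    svio.write_patient_table(table.patients, paths["patients"])
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\ttrack\tcarriers\trole\n")
        for t in truth:
            chrom, pos, ref, alt = t.variant_key
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{t.gene}\t{t.track}\t"
                f"{','.join(t.carriers)}\t{t.role}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# gene-set collection and ortholog-mapping fixtures
# ---------------------------------------------------------------------------

def generate_collection(
    query: GeneList,
    background_size: int = 12000,
    planted_size: int = 83,
    planted_overlap: int = 9,
    n_decoy_sets: int = 325,
    set_size_range: tuple[int, int] = (20, 300),
    seed: int = 0,
    planted_name: str = "PLANTED",
) -> GeneSetCollection:
    """A GMT-style collection with one planted enriched set plus decoys.

    The background is the query plus synthetic filler symbols; the
    planted set overlaps the query in exactly ``planted_overlap`` genes,
    while decoy sets are drawn uniformly from the background.
    """
    rng = np.random.default_rng(seed)
    query_genes = sorted(query.genes)
    if planted_overlap > min(planted_size, len(query_genes)):
        raise ValueError("planted overlap exceeds set or query size")
    n_filler = background_size - len(query_genes)
    if n_filler < planted_size - planted_overlap:
        raise ValueError("background too small for the planted set")
    background = query_genes + [f"UNIV{i + 1:05d}" for i in range(n_filler)]
    non_query = background[len(query_genes):]
    planted = set(rng.choice(query_genes, size=planted_overlap, replace=False)) | set(
        rng.choice(non_query, size=planted_size - planted_overlap, replace=False)
    )
    sets = {planted_name: frozenset(str(g) for g in planted)}
    sizes = rng.integers(set_size_range[0], set_size_range[1] + 1, size=n_decoy_sets)
    for i in range(n_decoy_sets):
        members = rng.choice(background, size=int(sizes[i]), replace=False)
        sets[f"DECOY_{i + 1:03d}"] = frozenset(str(g) for g in members)
    return GeneSetCollection(sets, frozenset(background))


def generate_mapping(
    genes: GeneList, n_unmapped: int = 6, seed: int = 0
) -> tuple[dict[str, str], list[str]]:
    """Human->mouse symbol mapping covering all but ``n_unmapped`` genes.

    The mouse symbol is the capitalized human symbol, the usual
    human/mouse nomenclature relationship.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(genes.genes)
    if n_unmapped > len(ordered):
        raise ValueError("cannot leave more genes unmapped than exist")
    unmapped = sorted(str(g) for g in rng.choice(ordered, size=n_unmapped, replace=False))
    mapping = {g: g.capitalize() for g in ordered if g not in set(unmapped)}
    return mapping, unmapped


# ---------------------------------------------------------------------------
# truth-recovery verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    n_planted: dict[str, int]          # per intended track (clinvar/score/both)
    n_recovered: dict[str, int]
    unrecovered: tuple[VariantKey, ...]
    n_benign: int
    n_benign_clean: int                # benign truths with no track called
    shared_expected: dict[VariantKey, int]
    shared_observed: dict[VariantKey, int]

    @property
    def recovery_fraction(self) -> float:
        total = sum(self.n_planted.values())
        return sum(self.n_recovered.values()) / total if total else 1.0

    @property
    def shared_recovered(self) -> bool:
        return self.shared_expected == self.shared_observed


def _track_matches(intended: str, call: PathogenicityCall) -> bool:
    if intended == "both":
        return call.both_tracks
    if intended == "clinvar":
        return call.clinvar_track and not call.score_track
    if intended == "score":
        return call.score_track and not call.clinvar_track
    return not call.any_track


def verify_recovery(
    truth: list[TruthRecord],
    table: CohortTable,
    calls: dict[VariantKey, PathogenicityCall],
) -> RecoveryReport:
    """Compare pipeline classifications and carrier counts to the truth.

    Truth records absent from ``table`` (e.g. filtered-out common or
    synonymous variants) count as recovered only for benign intents.
    """
    n_planted: dict[str, int] = {"clinvar": 0, "score": 0, "both": 0}
    n_recovered: dict[str, int] = {"clinvar": 0, "score": 0, "both": 0}
    unrecovered: list[VariantKey] = []
    n_benign = n_benign_clean = 0
    shared_expected: dict[VariantKey, int] = {}
    shared_observed: dict[VariantKey, int] = {}
    in_table = {v.key for v in table.variants}
    for t in truth:
        present = t.variant_key in in_table
        if t.track == "none":
            n_benign += 1
            if not present or _track_matches("none", calls[t.variant_key]):
                n_benign_clean += 1
            continue
        n_planted[t.track] += 1
        if present and _track_matches(t.track, calls[t.variant_key]):
            n_recovered[t.track] += 1
        else:
            unrecovered.append(t.variant_key)
        if t.role.startswith("shared:"):
            shared_expected[t.variant_key] = len(t.carriers)
            if present:
                shared_observed[t.variant_key] = table.carrier_count(t.variant_key)
    return RecoveryReport(
        n_planted=n_planted,
        n_recovered=n_recovered,
        unrecovered=tuple(unrecovered),
        n_benign=n_benign,
        n_benign_clean=n_benign_clean,
        shared_expected=shared_expected,
        shared_observed=shared_observed,
    )
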