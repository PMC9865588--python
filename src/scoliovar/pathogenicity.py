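"""Dual-track pathogenicity classification.

Each rare variant is scored on two independent evidence tracks:

* **ClinVar track** — the curated clinical-significance label, after
  normalization, belongs to a whitelist of qualifying categories
  (association; conflicting interpretations of pathogenicity; likely
  pathogenic; pathogenic; pathogenic/likely pathogenic).
* **Score track** — the variant's CADD Phred score is strictly greater
  than 20 (top 1% most deleterious substitutions) AND its REVEL score is
  at least 0.75 (a high-specificity missense cutoff).

Absent evidence is never pathogenic evidence: a missing label fails the
ClinVar track and a missing score fails the score track.  The union
("any track") and intersection ("both tracks", the dual-evidence set) of
the two tracks drive downstream gene burden and sharing summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import CohortTable, PathoAnnotations, VariantKey

DEFAULT_CLINVAR_WHITELIST = frozenset(
    {
        "association",
        "conflicting interpretations of pathogenicity",
        "likely pathogenic",
        "pathogenic",
        "pathogenic/likely pathogenic",
    }
)


@dataclass(frozen=True)
class ClassifierConfig:
    clinvar_whitelist: frozenset[str] = field(default=DEFAULT_CLINVAR_WHITELIST)
    cadd_min: float = 20.0   # strict: score must exceed this
    revel_min: float = 0.75  # inclusive: score may equal this

    def __post_init__(self) -> None:
        if not self.clinvar_whitelist:
            raise ValueError("clinvar_whitelist must be non-empty")
        if self.cadd_min <= 0:
            raise ValueError(f"cadd_min must be positive, got {self.cadd_min}")
        if not (0.0 < self.revel_min < 1.0):
            raise ValueError(f"revel_min must be in (0, 1), got {self.revel_min}")


@dataclass(frozen=True)
class PathogenicityCall:
    clinvar_track: bool
    score_track: bool

    @property
    def any_track(self) -> bool:
        return self.clinvar_track or self.score_track

    @property
    def both_tracks(self) -> bool:
        return self.clinvar_track and self.score_track


def normalize_clinvar_label(raw: str) -> str:
    """Normalize a ClinVar label: lowercase, underscores to spaces,
    whitespace collapsed; compound "/"-joined labels kept verbatim."""
    return " ".join(raw.replace("_", " ").lower().split())


def classify_clinvar(patho: PathoAnnotations, config: ClassifierConfig | None = None) -> bool:
    config = config or ClassifierConfig()
    if patho.clinvar_label is None:
        return False
    return normalize_clinvar_label(patho.clinvar_label) in config.clinvar_whitelist


def classify_scores(patho: PathoAnnotations, config: ClassifierConfig | None = None) -> bool:
    config = config or ClassifierConfig()
    return (
        patho.cadd_phred is not None
        and patho.cadd_phred > config.cadd_min
        and patho.revel is not None
        and patho.revel >= config.revel_min
    )


def classify_variant(patho: PathoAnnotations, config: ClassifierConfig | None = None) -> PathogenicityCall:
    config = config or ClassifierConfig()
    return PathogenicityCall(
        clinvar_track=classify_clinvar(patho, config),
        score_track=classify_scores(patho, config),
    )


def classify_cohort(
    table: CohortTable, config: ClassifierConfig | None = None
) -> dict[VariantKey, PathogenicityCall]:
    """One deterministic call per variant, keyed by variant identity."""
    config = config or ClassifierConfig()
    return {v.key: classify_variant(v.patho, config) for v in table.variants}


@dataclass(frozen=True)
class TrackSummary:
    """Variant and distinct-gene counts per track, union and intersection."""

    n_clinvar: int
    n_score: int
    n_both: int
    n_union: int
    n_genes_clinvar: int
    n_genes_score: int
    n_genes_union: int

    def __post_init__(self) -> None:
        assert self.n_union == self.n_clinvar + self.n_score - self.n_both


def summarize_tracks(
    table: CohortTable, calls: dict[VariantKey, PathogenicityCall]
) -> TrackSummary:
    clinvar_keys = {k for k, c in calls.items() if c.clinvar_track}
    score_keys = {k for k, c in calls.items() if c.score_track}

    def genes(keys: set[VariantKey]) -> set[str]:
        return {table.variant(k).gene for k in keys if table.variant(k).gene}

    return TrackSummary(
        n_clinvar=len(clinvar_keys),
        n_score=len(score_keys),
        n_both=len(clinvar_keys & score_keys),
        n_union=len(clinvar_keys | score_keys),
        n_genes_clinvar=len(genes(clinvar_keys)),
        n_genes_score=len(genes(score_keys)),
        n_genes_union=len(genes(clinvar_keys | score_keys)),
    )


def calls_to_rows(
    table: CohortTable, calls: dict[VariantKey, PathogenicityCall]
) -> list[dict]:
    """Flatten calls for TSV emission (four booleans per variant)."""
    rows = []
    for v in table.variants:
        c = calls[v.key]
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene or "UNANNOTATED",
                "clinvar_track": int(c.clinvar_track),
                "score_track": int(c.score_track),
                "any_track": int(c.any_track),
                "both_tracks": int(c.both_tracks),
            }
        )
    return rows
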