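"""Core data model for annotated exome cohorts.

The central container is :class:`CohortTable`: a list of annotated
single-nucleotide variants plus a patient x variant allele-count matrix.
Variant identity is the tuple ``(chrom, pos, ref, alt)`` on GRCh38
(1-based, fully closed coordinates); the gene symbol is annotation, not
identity.  Population allele frequencies and pathogenicity annotations
(ClinVar label, CADD Phred, REVEL) are consumed, never computed, and an
absent annotation is always distinguishable from an observed 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

VALID_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
NUCLEOTIDES = frozenset("ACGT")

#: identity key of a variant within a cohort
VariantKey = tuple[str, int, str, str]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and validate against GRCh38 naming."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in VALID_CHROMS:
        raise ValueError(f"invalid chromosome label: {chrom!r}")
    return c


@dataclass(frozen=True)
class PopulationFrequencies:
    """Alternative-allele frequencies in four population panels.

    ``None`` means the variant is absent from (unobserved in) that panel,
    which is *not* the same as a frequency of 0.0.
    """

    twb: Optional[float] = None          # Taiwan Biobank
    kgp_eas: Optional[float] = None      # 1000 Genomes, East Asian
    gnomad_eas: Optional[float] = None   # gnomAD, East Asian
    exac_eas: Optional[float] = None     # ExAC, East Asian

    SOURCES = ("twb", "kgp_eas", "gnomad_eas", "exac_eas")

    def __post_init__(self) -> None:
        for name, value in self.items():
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"frequency {name}={value} outside [0, 1]")

    def items(self) -> Iterator[tuple[str, Optional[float]]]:
        for name in self.SOURCES:
            yield name, getattr(self, name)

    def get(self, source: str) -> Optional[float]:
        if source not in self.SOURCES:
            raise KeyError(source)
        return getattr(self, source)


@dataclass(frozen=True)
class PathoAnnotations:
    """Per-variant pathogenicity evidence consumed from the annotation step."""

    clinvar_label: Optional[str] = None
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD Phred score must be >= 0, got {self.cadd_phred}")
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError(f"REVEL score must be in [0, 1], got {self.revel}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated SNV row.

    ``consequence`` is the set of transcript-level consequence labels the
    row carries (a variant may be annotated on several transcripts); it is
    stored as a tuple to stay hashable and order-stable.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    transcript_hgvs: Optional[str] = None
    consequence: tuple[str, ...] = ("nonsynonymous SNV",)
    freqs: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    patho: PathoAnnotations = field(default_factory=PathoAnnotations)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"SNV alleles must be single A/C/G/T bases, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")
        if not self.consequence:
            raise ValueError("variant carries no consequence label")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PatientRecord:
    """Cohort-member metadata.

    Clinical fields are optional (a genotype table alone does not carry
    them); when present they are validated against the cohort inclusion
    criteria: severe scoliosis means every curve's Cobb angle exceeds 40
    degrees, and recruitment is adolescent-to-young-adult (10-40 years).
    """

    patient_id: str
    sex: Optional[str] = None
    age: Optional[int] = None
    curves: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age is not None and not (10 <= self.age <= 40):
            raise ValueError(f"age {self.age} outside plausible range 10-40")
        for location, angle in self.curves:
            if angle <= 40:
                raise ValueError(
                    f"Cobb angle {angle} at {location} violates the >40 degree "
                    f"inclusion criterion for patient {self.patient_id}"
                )


class CohortTable:
    """Annotated variants plus a variant x patient allele-count matrix.

    Genotypes are alternative-allele counts in {0, 1, 2}; in this study
    every carried copy is heterozygous (1).  Every variant must have at
    least one carrier, and variant identity keys are unique.
    """

    def __init__(
        self,
        variants: Sequence[AnnotatedVariant],
        patients: Sequence[PatientRecord],
        genotypes: np.ndarray,
    ) -> None:
        self.variants = list(variants)
        self.patients = list(patients)
        g = np.asarray(genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape != (len(self.variants), len(self.patients)):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.variants)} variants x {len(self.patients)} patients"
            )
        if g.size and not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotype entries must be allele counts in {0, 1, 2}")
        if g.size and (g.sum(axis=1) < 1).any():
            bad = int(np.flatnonzero(g.sum(axis=1) < 1)[0])
            raise ValueError(f"variant {self.variants[bad].key} has no carrier")
        self.genotypes = g
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            seen: set[VariantKey] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate variant identity key {k}")
                seen.add(k)
        self._key_index = {k: i for i, k in enumerate(keys)}
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids are not unique")

    # -- basic introspection -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def index_of(self, key: VariantKey) -> int:
        return self._key_index[key]

    def variant(self, key: VariantKey) -> AnnotatedVariant:
        return self.variants[self._key_index[key]]

    def carriers(self, key: VariantKey) -> list[str]:
        """Patient ids carrying at least one alternative allele of ``key``."""
        row = self.genotypes[self._key_index[key]]
        return [p.patient_id for p, g in zip(self.patients, row) if g > 0]

    def carrier_count(self, key: VariantKey) -> int:
        return int((self.genotypes[self._key_index[key]] > 0).sum())

    def total_allele_count(self) -> int:
        return int(self.genotypes.sum())

    # -- derivation ----------------------------------------------------------
    def subset(self, indices: Sequence[int]) -> "CohortTable":
        """Row-subset preserving variant order and all patients."""
        idx = list(indices)
        return CohortTable(
            [self.variants[i] for i in idx],
            self.patients,
            self.genotypes[idx] if idx else np.zeros((0, self.n_patients), dtype=np.int8),
        )

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.variants == other.variants
            and self.patients == other.patients
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return f"CohortTable({self.n_variants} variants, {self.n_patients} patients)"


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols (e.g. the curated AIS literature panel)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValueError("gene list contains an empty symbol")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over an explicit background universe.

    Every set is restricted to the background; empty-after-restriction sets
    are rejected.
    """

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if not members <= self.background:
                raise ValueError(f"gene set {name!r} is not a subset of the background")

    @staticmethod
    def from_sets(
        sets: dict[str, frozenset[str]],
        background: Optional[frozenset[str]] = None,
    ) -> "GeneSetCollection":
        """Build a collection, restricting sets to ``background`` when given.

        Without an explicit background the universe defaults to the union
        of all member genes.
        """
        if background is None:
            universe: frozenset[str] = frozenset().union(*sets.values()) if sets else frozenset()
            return GeneSetCollection(dict(sets), universe)
        restricted = {
            name: frozenset(members & background)
            for name, members in sets.items()
            if members & background
        }
        return GeneSetCollection(restricted, frozenset(background))

    def __len__(self) -> int:
        return len(self.sets)
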