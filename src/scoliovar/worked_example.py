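"""The published severe-AIS cohort summary tables as a reusable fixture.

The source study printed three desk-scale tables: the 11-patient clinical
roster, the 11 rare variants falling in literature AIS genes (two of them
in TBX1, one FBN2 variant score-predicted pathogenic), and the 7
dual-evidence variants passing both the ClinVar and CADD/REVEL tracks
(in SGCD, CLCN1, DPYS x2, MYBPC3, MYO7A and NDUFAF5).  This module
encodes those rows as one 18-variant, 11-patient :class:`CohortTable` on
GRCh38 coordinates.

SYNTHETIC FILL: the AIS-gene table prints only coordinates, gene,
consequence and genotypes.  Its population-frequency and score cells
here are synthetic fill values chosen to pass the rarity filter and fail
both pathogenicity tracks — except the FBN2 c.809G>T row, which the
study reports as predicted pathogenic by CADD and REVEL and therefore
receives score-track-passing fill.  The dual-evidence table's
frequencies, labels and scores are the printed values.
"""

from __future__ import annotations

import numpy as np

from .models import (
    AnnotatedVariant,
    CohortTable,
    PathoAnnotations,
    PatientRecord,
    PopulationFrequencies,
)

N_PATIENTS = 11

#: clinical roster: (id, sex, age, ((curve location, Cobb angle), ...))
PATIENT_ROWS = (
    ("Pt1", "M", 18, (("T5-T10", 50.0),)),
    ("Pt2", "F", 17, (("T10-L3", 47.0),)),
    ("Pt3", "F", 16, (("T2-T12", 45.0),)),
    ("Pt4", "F", 22, (("T7-L2", 61.0),)),
    ("Pt5", "M", 25, (("T9-L2", 82.0),)),
    ("Pt6", "M", 17, (("T6-T12", 72.0),)),
    ("Pt7", "F", 19, (("T12-L4", 44.0), ("T11-T6", 45.0))),
    ("Pt8", "F", 24, (("T12-L4", 45.0),)),
    ("Pt9", "F", 14, (("T4-T10", 69.0), ("T11-L4", 66.0))),
    ("Pt10", "F", 16, (("T1-T4", 49.0), ("T4-T12", 86.0), ("L1-L4", 56.0))),
    ("Pt11", "F", 21, (("T5-T12", 50.0),)),
)

# AIS-literature-gene rare variants.  Columns: chrom, pos, ref, alt, gene,
# hgvs, carrier patient, then SYNTHETIC FILL (twb, kgp, gnomad, exac,
# clinvar label, cadd, revel).
_F = None  # absent annotation
AIS_GENE_ROWS = (
    ("1", 228097412, "G", "T", "ARF1", _F, "Pt3",
     0.0005, _F, 0.0008, _F, "Uncertain_significance", 9.1, 0.12),
    ("3", 65478781, "G", "A", "MAGI1", _F, "Pt4",
     _F, 0.002, 0.0015, 0.001, _F, 14.2, 0.31),
    ("3", 171093913, "G", "A", "TNIK", _F, "Pt11",
     0.003, _F, 0.004, 0.0041, _F, 11.8, 0.22),
    ("4", 71765499, "A", "T", "GC", _F, "Pt10",
     0.008, 0.004, 0.006, 0.0052, "Benign", 6.3, 0.08),
    ("5", 128464741, "C", "A", "FBN2", "NM_001999:c.809G>T(p.Arg270Leu)", "Pt1",
     _F, 0.0008, _F, 0.0009, _F, 26.4, 0.812),   # score-track pathogenic
    ("6", 116117932, "G", "A", "NT5DC1", _F, "Pt6",
     0.001, _F, _F, 0.0012, _F, 17.5, 0.44),
    ("7", 22727278, "A", "G", "IL6", _F, "Pt1",
     _F, _F, 0.0003, _F, _F, 8.9, 0.05),
    ("8", 3142671, "G", "A", "CSMD1", _F, "Pt4",
     0.006, 0.0045, 0.005, 0.006, _F, 15.0, 0.38),
    ("20", 21709343, "C", "A", "PAX1", _F, "Pt8",
     _F, 0.001, 0.0008, 0.002, _F, 18.9, 0.51),
    ("22", 19761061, "C", "A", "TBX1", _F, "Pt5",
     0.002, _F, 0.0019, 0.0021, _F, 12.4, 0.27),
    ("22", 19761069, "C", "T", "TBX1", _F, "Pt2",
     _F, 0.003, 0.0028, 0.003, "Uncertain_significance", 16.7, 0.49),
)

# Dual-evidence variants, printed values throughout.  Columns: chrom, pos,
# ref, alt, gene, hgvs, carrier, kgp, gnomad, exac, twb, clinvar, cadd, revel.
DUAL_EVIDENCE_ROWS = (
    ("5", 156759365, "A", "G", "SGCD", _F, "Pt5",
     _F, 0.008, 0.0064, 0.01,
     "Conflicting_interpretations_of_pathogenicity", 20.3, 0.865),
    ("7", 143330810, "G", "A", "CLCN1", "NM_000083:c.892G>A(p.Ala298Thr)", "Pt11",
     _F, _F, 0.0002, _F,
     "Pathogenic/Likely_pathogenic", 29.5, 0.9),
    ("8", 104428071, "T", "C", "DPYS", _F, "Pt8",
     0.003, 0.001, 0.0013, 0.001,
     "Pathogenic", 28.1, 0.946),
    ("8", 104429590, "C", "T", "DPYS", _F, "Pt9",
     _F, _F, 0.0001, _F,
     "Likely_pathogenic", 35.0, 0.894),
    ("11", 47346297, "C", "T", "MYBPC3", _F, "Pt9",
     0.004, 0.0026, 0.0045, 0.001,
     "Conflicting_interpretations_of_pathogenicity", 24.9, 0.757),
    ("11", 77189442, "G", "C", "MYO7A", _F, "Pt9",
     0.004, 0.0057, 0.0042, 0.0085,
     "Conflicting_interpretations_of_pathogenicity", 28.5, 0.853),
    ("20", 13816520, "T", "G", "NDUFAF5", _F, "Pt3",
     _F, 0.001, 0.0006, 0.0015,
     "Conflicting_interpretations_of_pathogenicity", 27.7, 0.887),
)

DUAL_EVIDENCE_GENES = ("SGCD", "CLCN1", "DPYS", "DPYS", "MYBPC3", "MYO7A", "NDUFAF5")


def patients() -> list[PatientRecord]:
    return [
        PatientRecord(patient_id=pid, sex=sex, age=age, curves=curves)
        for pid, sex, age, curves in PATIENT_ROWS
    ]


def _build(rows, freq_order: tuple[str, str, str, str]) -> tuple[list[AnnotatedVariant], list[str]]:
    variants, carriers = [], []
    for chrom, pos, ref, alt, gene, hgvs, carrier, f1, f2, f3, f4, label, cadd, revel in rows:
        freqs = dict(zip(freq_order, (f1, f2, f3, f4)))
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                transcript_hgvs=hgvs, consequence=("missense",),
                freqs=PopulationFrequencies(**freqs),
                patho=PathoAnnotations(clinvar_label=label, cadd_phred=cadd, revel=revel),
            )
        )
        carriers.append(carrier)
    return variants, carriers


def _as_table(variants: list[AnnotatedVariant], carriers: list[str]) -> CohortTable:
    pts = patients()
    col = {p.patient_id: j for j, p in enumerate(pts)}
    genotypes = np.zeros((len(variants), len(pts)), dtype=np.int8)
    for i, carrier in enumerate(carriers):
        genotypes[i, col[carrier]] = 1  # every carried copy is heterozygous
    return CohortTable(variants, pts, genotypes)


def ais_gene_table() -> CohortTable:
    """The 11 rare variants in literature AIS genes (synthetic-fill cells)."""
    return _as_table(*_build(AIS_GENE_ROWS, ("twb", "kgp_eas", "gnomad_eas", "exac_eas")))


def dual_evidence_table() -> CohortTable:
    """The 7 dual-evidence variants with their printed annotations."""
    return _as_table(*_build(DUAL_EVIDENCE_ROWS, ("kgp_eas", "gnomad_eas", "exac_eas", "twb")))


def cohort() -> CohortTable:
    """Both tables merged into one 18-variant worked-example cohort."""
    a, ca = _build(AIS_GENE_ROWS, ("twb", "kgp_eas", "gnomad_eas", "exac_eas"))
    d, cd = _build(DUAL_EVIDENCE_ROWS, ("kgp_eas", "gnomad_eas", "exac_eas", "twb"))
    return _as_table(a + d, ca + cd)


# Four printed p/q pairs from the cohort's KEGG enrichment table; inputs to
# the BH test-count reconstruction (q = BH-adjusted p at the recovered m).
KEGG_TABLE_ROWS = (
    ("Hypertrophic cardiomyopathy", 83, 9, 3.61e-6, 1.18e-3),
    ("Arrhythmogenic right ventricular cardiomyopathy", 72, 8, 1.07e-5, 1.75e-3),
    ("Dilated cardiomyopathy", 90, 8, 5.55e-5, 6.03e-3),
    ("Lysosome", 123, 8, 4.90e-4, 3.99e-2),
)
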