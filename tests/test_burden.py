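"""Gene burden, sharing, literature-list intersection, patient profiles
and candidate-gene assembly."""

import numpy as np
import pytest

import scoliovar as sv
from scoliovar.burden import rare_then_intersect_commutes
from scoliovar.models import PathoAnnotations, PopulationFrequencies


def _variant(pos, gene, label=None, cadd=None, revel=None):
    return sv.AnnotatedVariant(
        chrom="1", pos=pos, ref="A", alt="C", gene=gene,
        patho=PathoAnnotations(clinvar_label=label, cadd_phred=cadd, revel=revel),
    )


def _single_patient_cohort(variants):
    return sv.CohortTable(
        variants, [sv.PatientRecord("P1")], np.ones((len(variants), 1), dtype=np.int8)
    )


class TestGeneBurden:
    def test_planted_burdens_top_ranking(self, sim_rare, sim_calls):
        """The gene planted with 8 ClinVar-track variants tops the ClinVar
        ranking and the 3-variant score-track gene tops that track."""
        burdens = sv.gene_burden_counts(sim_rare, sim_calls)
        assert burdens[0].gene == "GENE_A"
        assert (burdens[0].n_clinvar_track, burdens[0].n_any) == (8, 8)
        by_score = max(burdens, key=lambda b: b.n_score_track)
        assert by_score.gene == "GENE_B" and by_score.n_score_track == 3

    def test_conservation_of_any_track_count(self, sim_rare, sim_calls):
        burdens = sv.gene_burden_counts(sim_rare, sim_calls)
        total_any = sum(1 for c in sim_calls.values() if c.any_track)
        assert sum(b.n_any for b in burdens) == total_any == 216

    def test_empty_pathogenic_set(self):
        table = _single_patient_cohort([_variant(1, "G1")])
        assert sv.gene_burden_counts(table, sv.classify_cohort(table)) == []

    def test_missing_gene_goes_to_sentinel(self, caplog):
        table = _single_patient_cohort([_variant(1, None, label="Pathogenic")])
        with caplog.at_level("WARNING"):
            burdens = sv.gene_burden_counts(table, sv.classify_cohort(table))
        assert burdens[0].gene == "UNANNOTATED"

    def test_deterministic_tie_break_by_symbol(self):
        table = _single_patient_cohort(
            [_variant(1, "ZZZ", label="Pathogenic"), _variant(2, "AAA", label="Pathogenic")]
        )
        burdens = sv.gene_burden_counts(table, sv.classify_cohort(table))
        assert [b.gene for b in burdens] == ["AAA", "ZZZ"]


class TestSharing:
    def test_planted_shared_variant_tops_matrix(self, sim_rare, sim_calls):
        records = sv.sharing_matrix(sim_rare, sim_calls)
        assert records[0].n_carriers == 4
        assert records[0].gene == "GENE_S1"
        assert sv.sharing_histogram(records) == {1: 213, 2: 2, 4: 1}

    def test_histogram_matches_bruteforce_recount(self, sim_rare, sim_calls):
        records = sv.sharing_matrix(sim_rare, sim_calls)
        brute = {}
        for v, row in zip(sim_rare.variants, sim_rare.genotypes):
            if sim_calls[v.key].any_track:
                n = int((np.asarray(row) > 0).sum())
                brute[n] = brute.get(n, 0) + 1
        assert sv.sharing_histogram(records) == dict(sorted(brute.items()))

    def test_carrier_sum_conservation(self, sim_rare, sim_calls):
        records = sv.sharing_matrix(sim_rare, sim_calls)
        genotype_sum = sum(
            sim_rare.carrier_count(v.key)
            for v in sim_rare.variants
            if sim_calls[v.key].any_track
        )
        assert sum(r.n_carriers for r in records) == genotype_sum

    def test_single_patient_cohort_all_singletons(self):
        table = _single_patient_cohort([_variant(i + 1, f"G{i}") for i in range(5)])
        records = sv.sharing_matrix(table)
        assert all(r.n_carriers == 1 for r in records)


class TestGeneListIntersection:
    def test_worked_example_eleven_hits_tbx1_twice(self, we_cohort, ais_list):
        hits = sv.intersect_gene_list(we_cohort, ais_list)
        assert hits.n_variants == 11
        genes = [v.gene for v in hits.variants]
        assert genes.count("TBX1") == 2
        assert len(set(genes)) == 10

    def test_disjoint_list_empty(self, we_cohort):
        other = sv.GeneList("other", frozenset({"NOSUCHGENE"}))
        assert sv.intersect_gene_list(we_cohort, other).n_variants == 0

    def test_duplicate_symbols_same_result(self, we_cohort, ais_list):
        # GeneList stores a set, so feeding an inflated list is identical
        doubled = sv.GeneList("dup", frozenset(list(ais_list.genes) * 2))
        a = sv.intersect_gene_list(we_cohort, ais_list)
        b = sv.intersect_gene_list(we_cohort, doubled)
        assert a.equals(b)

    def test_commutes_with_rarity_filter(self, sim_default, ais_list):
        table, _ = sim_default
        assert rare_then_intersect_commutes(table, ais_list)


class TestPatientProfile:
    def test_patient9_carries_three_dual_evidence_variants(self, we_rare, we_calls):
        profile = sv.patient_profile(we_rare, we_calls, "Pt9")
        genes = sorted(we_rare.variant(k).gene for k in profile.pathogenic)
        assert genes == ["DPYS", "MYBPC3", "MYO7A"]

    def test_patient_without_variants_has_empty_lists(self, we_rare, we_calls):
        profile = sv.patient_profile(we_rare, we_calls, "Pt7")
        assert profile.pathogenic == () and profile.rescue == ()

    def test_unknown_patient_errors(self, we_rare, we_calls):
        with pytest.raises(KeyError):
            sv.patient_profile(we_rare, we_calls, "Pt99")

    def test_rescue_counts_single_criterion_components(self):
        """The relaxed re-screen accepts any one criterion in isolation:
        a whitelisted label alone, CADD alone, or REVEL alone."""
        variants = [
            _variant(1, "G1", label="Pathogenic"),            # label only
            _variant(2, "G2", cadd=25.0),                     # CADD only
            _variant(3, "G3", revel=0.8),                     # REVEL only
            _variant(4, "G4", cadd=10.0, revel=0.2),          # nothing
            _variant(5, "G5", label="Benign", cadd=19.0),     # nothing
        ]
        table = _single_patient_cohort(variants)
        calls = sv.classify_cohort(table)
        profile = sv.patient_profile(table, calls, "P1")
        assert [k[1] for k in profile.rescue] == [1, 2, 3]
        # only the whitelisted label passes a full track (the ClinVar one);
        # lone scores fail the CADD+REVEL conjunction
        assert [k[1] for k in profile.pathogenic] == [1]

    def test_rescue_recovers_planted_count(self):
        """25 single-criterion variants planted on one patient are all
        proposed by the relaxed re-screen."""
        variants = []
        for i in range(25):
            kind = i % 3
            variants.append(
                _variant(
                    i + 1, f"R{i}",
                    label="Likely_pathogenic" if kind == 0 else None,
                    cadd=30.0 if kind == 1 else None,
                    revel=0.9 if kind == 2 else None,
                )
            )
        table = _single_patient_cohort(variants)
        profile = sv.patient_profile(table, sv.classify_cohort(table), "P1")
        assert len(profile.rescue) == 25


class TestCandidateGenes:
    def test_union_rule_small_oracle(self):
        """5 pathogenic genes plus 3 list-hit genes sharing 1 symbol
        yield 7 candidates (plain set union)."""
        variants = [
            _variant(i + 1, g, label="Pathogenic")
            for i, g in enumerate(["P1G", "P2G", "P3G", "P4G", "SHARED"])
        ] + [_variant(10 + i, g) for i, g in enumerate(["L1G", "L2G", "SHARED"])]
        table = _single_patient_cohort(variants)
        calls = sv.classify_cohort(table)
        gene_list = sv.GeneList("lit", frozenset({"L1G", "L2G", "SHARED"}))
        cand = sv.candidate_gene_set(table, calls, gene_list)
        assert len(cand) == 7
        brute = {"P1G", "P2G", "P3G", "P4G", "SHARED"} | {"L1G", "L2G"}
        assert cand.genes == frozenset(brute)

    def test_no_hits_no_candidates(self):
        table = _single_patient_cohort([_variant(1, "G1")])
        cand = sv.candidate_gene_set(
            table, sv.classify_cohort(table), sv.GeneList("x", frozenset({"Z"}))
        )
        assert len(cand) == 0

    def test_worked_example_candidates(self, we_rare, we_calls, ais_list):
        cand = sv.candidate_gene_set(we_rare, we_calls, ais_list)
        for gene in ("SGCD", "CLCN1", "DPYS", "MYBPC3", "MYO7A", "NDUFAF5",
                     "ARF1", "MAGI1", "TNIK", "GC", "FBN2", "NT5DC1", "IL6",
                     "CSMD1", "PAX1", "TBX1"):
            assert gene in cand
        assert len(cand) == 16

    def test_pathogenic_only_mode(self, we_rare, we_calls, ais_list):
        cand = sv.candidate_gene_set(we_rare, we_calls, ais_list, mode="pathogenic_only")
        assert "ARF1" not in cand and "SGCD" in cand and "FBN2" in cand
        assert len(cand) == 7  # 6 dual-evidence genes + FBN2
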