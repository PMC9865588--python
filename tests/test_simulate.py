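"""Synthetic cohort generator: determinism, planted structure, file
round-trips, truth recovery."""

import numpy as np
import pytest

import scoliovar as sv
from scoliovar.models import PathoAnnotations


def test_same_seed_byte_identical(tmp_path):
    cfg = sv.SimConfig(seed=42)
    t1, truth1 = sv.generate_cohort(cfg)
    t2, truth2 = sv.generate_cohort(cfg)
    assert t1.equals(t2) and truth1 == truth2
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = sv.write_cohort(t1, truth1, d1)
    p2 = sv.write_cohort(t2, truth2, d2)
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()


def test_different_seeds_differ():
    t1, _ = sv.generate_cohort(sv.SimConfig(seed=1))
    t2, _ = sv.generate_cohort(sv.SimConfig(seed=2))
    assert not t1.equals(t2)


def test_default_cohort_shape(sim_default):
    table, truth = sim_default
    assert table.n_patients == 11
    assert sum(p.sex == "F" for p in table.patients) == 8
    assert (table.genotypes <= 1).all()  # heterozygous only
    assert len(truth) == table.n_variants == 377


def test_default_track_totals(sim_rare, sim_calls):
    ts = sv.summarize_tracks(sim_rare, sim_calls)
    assert (ts.n_clinvar, ts.n_score, ts.n_both, ts.n_union) == (87, 136, 7, 216)
    assert (ts.n_genes_clinvar, ts.n_genes_score) == (76, 130)


def test_emitted_tables_parse_through_io(tmp_path):
    table, truth = sv.generate_cohort(sv.SimConfig(seed=3))
    paths = sv.write_cohort(table, truth, tmp_path)
    back = sv.read_annotated_table(paths["cohort"], patients=table.patients)
    assert table.equals(back)


def test_single_patient_no_shared_plants():
    cfg = sv.SimConfig(
        n_patients=1, n_female=1, planted_shared=(), planted_burden=(),
        planted_dual=0, n_background_clinvar=5, n_background_clinvar_genes=5,
        n_background_score=5, n_background_score_genes=5,
        n_list_rare=2, n_list_genes=2, n_list_pathogenic_overlap=0,
        n_benign_rare=3, n_common=3, n_synonymous=3, seed=4,
    )
    table, _ = sv.generate_cohort(cfg)
    assert all(table.carrier_count(v.key) == 1 for v in table.variants)


def test_unsatisfiable_shared_plant_errors_before_emission():
    with pytest.raises(ValueError, match="carriers"):
        sv.SimConfig(planted_shared=((12, "score"),))


def test_unsatisfiable_burden_track_errors():
    with pytest.raises(ValueError, match="track"):
        sv.SimConfig(planted_burden=(("G", 2, "bogus"),))


def test_truth_recovery_is_exact(sim_default, sim_rare, sim_calls):
    _, truth = sim_default
    report = sv.verify_recovery(truth, sim_rare, sim_calls)
    assert report.recovery_fraction == 1.0
    assert report.n_planted == {"clinvar": 80, "score": 129, "both": 7}
    assert report.shared_recovered
    assert sorted(report.shared_expected.values()) == [2, 2, 4]
    assert report.n_benign_clean == report.n_benign


def test_boundary_scores_reported_unrecovered():
    """A plant whose CADD sits exactly on the strict threshold fails the
    score track by design and must show up as unrecovered."""
    v = sv.AnnotatedVariant(
        chrom="1", pos=100, ref="A", alt="C", gene="GB",
        patho=PathoAnnotations(cadd_phred=20.0, revel=0.9),
    )
    table = sv.CohortTable([v], [sv.PatientRecord("P1")], np.ones((1, 1), dtype=np.int8))
    truth = [sv.TruthRecord(v.key, "GB", "score", ("P1",), "boundary")]
    report = sv.verify_recovery(truth, table, sv.classify_cohort(table))
    assert report.recovery_fraction == 0.0
    assert report.unrecovered == (v.key,)


def test_background_never_shared_by_three_across_seeds():
    """Non-planted variants are private draws, so across 100 seeds no
    background pathogenic variant is ever shared by >=3 patients."""
    for seed in range(100):
        _, truth = sv.generate_cohort(sv.SimConfig(seed=seed))
        for t in truth:
            if not t.role.startswith("shared:"):
                assert len(t.carriers) == 1


def test_collection_decoy_overlaps_hypergeometric(sim_candidates):
    """Decoy sets are uniform draws: their query overlaps should match the
    hypergeometric mean within Monte-Carlo error."""
    coll = sv.generate_collection(sim_candidates, seed=21)
    n, N = len(sim_candidates), len(coll.background)
    ks, expected = [], []
    for name, members in coll.sets.items():
        if name == "PLANTED":
            continue
        ks.append(len(members & sim_candidates.genes))
        expected.append(len(members) * n / N)
    # mean observed-minus-expected overlap ~ 0 under uniform sampling
    diffs = np.array(ks) - np.array(expected)
    assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))


def test_collection_zero_decoys():
    coll = sv.generate_collection(
        sv.GeneList("q", frozenset(f"G{i}" for i in range(30))),
        background_size=500, planted_size=40, planted_overlap=9,
        n_decoy_sets=0, seed=1,
    )
    assert len(coll) == 1 and "PLANTED" in coll.sets


def test_mapping_deterministic_and_capitalized(sim_candidates):
    m1, u1 = sv.generate_mapping(sim_candidates, seed=9)
    m2, u2 = sv.generate_mapping(sim_candidates, seed=9)
    assert m1 == m2 and u1 == u2
    assert all(v == k.capitalize() for k, v in m1.items())
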