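"""Hypergeometric ORA and BH FDR: exact oracles, published-table
arithmetic, planted-fixture behavior."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

import scoliovar as sv
from scoliovar.worked_example import KEGG_TABLE_ROWS


def exact_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Independent oracle: exact rational tail sum via binomial coefficients."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return float(acc)


class TestHypergeomUpper:
    def test_zero_overlap_is_certain(self):
        assert sv.hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_small_exact_value(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert sv.hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_enumeration_over_all_draws(self):
        """Literal enumeration of every C(20,6) draw from a 20-gene urn."""
        N, K, n = 20, 8, 6
        universe = range(N)
        inside = set(range(K))
        counts = np.zeros(n + 1)
        for draw in itertools.combinations(universe, n):
            counts[len(inside & set(draw))] += 1
        probs = counts / counts.sum()
        for k in range(n + 1):
            assert sv.hypergeom_upper(k, K, n, N) == pytest.approx(
                probs[k:].sum(), abs=1e-12
            )

    def test_matches_exact_oracle_on_grid(self):
        for N in (1, 7, 13, 25):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 2):
                    for k in range(0, min(K, n) + 1):
                        assert sv.hypergeom_upper(k, K, n, N) == pytest.approx(
                            exact_upper_tail(k, K, n, N), rel=1e-9, abs=1e-300
                        )

    @pytest.mark.parametrize("k,K,n,N", [(3, 2, 5, 10), (1, 11, 5, 10), (-1, 2, 2, 10)])
    def test_parameter_violations_error(self, k, K, n, N):
        with pytest.raises(ValueError):
            sv.hypergeom_upper(k, K, n, N)


def bh_oracle(pvalues, m):
    """Brute-force double-loop step-up: q_i = min_{j>=i} p_(j) * m / j."""
    order = sorted(range(len(pvalues)), key=lambda i: pvalues[i])
    ranked = [pvalues[i] for i in order]
    q_sorted = []
    for i in range(len(ranked)):
        q_sorted.append(min(min(ranked[j] * m / (j + 1) for j in range(i, len(ranked))), 1.0))
    out = [0.0] * len(ranked)
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


class TestBhAdjust:
    def test_single_p_with_m_one(self):
        assert sv.bh_adjust([0.03], 1) == pytest.approx([0.03])

    def test_against_bruteforce_oracle_many_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.random(n)
            m = n + int(rng.integers(0, 50))
            assert sv.bh_adjust(p, m) == pytest.approx(bh_oracle(list(p), m), rel=1e-12)

    def test_against_statsmodels_when_m_equals_n(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(25)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert sv.bh_adjust(p) == pytest.approx(q_ref, rel=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_in_rank(self, pvalues):
        p = np.asarray(pvalues)
        q = sv.bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_duplicate_pvalues_order_invariant(self):
        p1 = [0.02, 0.02, 0.5, 0.02]
        p2 = [0.02, 0.5, 0.02, 0.02]
        q1 = sorted(sv.bh_adjust(p1))
        q2 = sorted(sv.bh_adjust(p2))
        assert q1 == pytest.approx(q2)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            sv.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            sv.bh_adjust([0.1, 0.2], m=1)


class TestPublishedTableReconstruction:
    """The published pathway table prints four (p, q) pairs; the number of
    tests m behind its BH adjustment is recoverable by integer search."""

    P = [row[3] for row in KEGG_TABLE_ROWS]
    Q = [row[4] for row in KEGG_TABLE_ROWS]

    def test_unique_consistent_m_is_326(self):
        assert sv.find_consistent_m(self.P, self.Q) == [326]

    def test_recomputed_q_match_printed_precision(self):
        q = sv.bh_adjust(self.P, 326)
        for computed, printed in zip(q, self.Q):
            ulp = 10.0 ** (math.floor(math.log10(printed)) - 2)
            assert abs(computed - printed) <= ulp


class TestRunOra:
    def test_planted_set_first_and_significant(self, sim_candidates, sim_collection):
        report = sv.run_ora(sim_candidates, sim_collection)
        top = report.results[0]
        assert top.set_name == "PLANTED"
        assert (top.K, top.k) == (83, 9)
        assert top.significant and top.q < 0.05
        assert report.m == 326 and report.n_background == 12000

    def test_k_counts_match_bruteforce_intersections(self, sim_candidates, sim_collection):
        report = sv.run_ora(sim_candidates, sim_collection)
        restricted = sim_candidates.genes & sim_collection.background
        for r in report.results:
            assert r.k == len(sim_collection.sets[r.set_name] & restricted)
            assert r.K == len(sim_collection.sets[r.set_name])
            assert r.q >= r.p

    def test_disjoint_query_all_null(self):
        coll = sv.GeneSetCollection(
            {"s1": frozenset({"A", "B", "C", "D", "E"})},
            frozenset({"A", "B", "C", "D", "E", "Q1", "Q2"}),
        )
        report = sv.run_ora(
            sv.GeneList("q", frozenset({"Q1", "Q2"})),
            coll,
            sv.OraConfig(min_set_size=1),
        )
        assert all(r.k == 0 and r.p == 1.0 and not r.significant for r in report.results)

    def test_empty_query_after_restriction_errors(self, sim_collection):
        with pytest.raises(ValueError):
            sv.run_ora(sv.GeneList("q", frozenset({"NOT_IN_BG"})), sim_collection)

    def test_set_size_window_defines_m(self, sim_candidates, sim_collection):
        tight = sv.OraConfig(min_set_size=80, max_set_size=90)
        report = sv.run_ora(sim_candidates, sim_collection, tight)
        expected = sum(80 <= len(s) <= 90 for s in sim_collection.sets.values())
        assert report.m == expected


class TestMapToMouse:
    def test_study_scale_mapping(self, sim_candidates):
        mapping, truth_unmapped = sv.generate_mapping(sim_candidates, n_unmapped=6, seed=5)
        mouse, unmapped = sv.map_to_mouse(sim_candidates, mapping)
        assert len(sim_candidates) == 206
        assert len(mouse) == 200 and len(unmapped) == 6
        assert unmapped == truth_unmapped

    def test_empty_gene_list(self):
        mouse, unmapped = sv.map_to_mouse(sv.GeneList("q", frozenset()), {"A": "a"})
        assert len(mouse) == 0 and unmapped == []

    def test_many_to_one_collapses(self):
        mouse, unmapped = sv.map_to_mouse(
            sv.GeneList("q", frozenset({"H1", "H2"})), {"H1": "Shared", "H2": "Shared"}
        )
        assert mouse.genes == frozenset({"Shared"}) and unmapped == []


def test_null_fwer_controlled(sim_collection):
    """Global-null queries produce >=1 significant set in at most ~5% of
    replicates (quick check; the full 1000-replicate bound is exercised
    in the acceptance suite)."""
    rate = sv.null_false_positive_rate(sim_collection, n_query=200, n_replicates=200, seed=11)
    se = math.sqrt(0.05 * 0.95 / 200)
    assert rate <= 0.05 + 3 * se
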