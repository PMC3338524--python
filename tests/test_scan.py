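"""Site scoring, null calibration, empirical p-values and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladeshift.alignment import AMINO_ACIDS
from cladeshift.scan import (
    CalibrationError,
    NullDistribution,
    calibrate_null,
    calibrate_nulls,
    call_branch,
    fdr_correct,
    score_columns,
    score_site,
    site_pvalues,
)
from cladeshift.tree import GeneTree, NodePartition

PART_441 = NodePartition(
    0,
    frozenset({"a1", "a2", "a3", "a4"}),
    frozenset({"b1", "b2", "b3", "b4"}),
    frozenset({"o1"}),
)


def column(a, b, o):
    col = {}
    col.update({f"a{i+1}": c for i, c in enumerate(a)})
    col.update({f"b{i+1}": c for i, c in enumerate(b)})
    col.update({f"o{i+1}": c for i, c in enumerate(o)})
    return col


class TestScoreSite:
    def test_identical_clades_and_outgroup_score_zero(self, blosum62):
        s = score_site(column("AAAA", "AAAA", "A"), PART_441, blosum62)
        assert s.xbar_a == s.xbar_b == 4.0
        assert s.fd_score == 0.0

    def test_hand_computed_welch_contrast(self, blosum62):
        # clade A {W,W,W,F} vs outgroup {W}: scores 11,11,11,1
        # clade B {A,A,A,S} vs outgroup {W}: scores -3,-3,-3,-3
        s = score_site(column("WWWF", "AAAS", "W"), PART_441, blosum62)
        assert s.xbar_a == pytest.approx(8.5)
        assert s.var_a == pytest.approx(25.0)
        assert s.xbar_b == pytest.approx(-3.0)
        assert s.var_b == pytest.approx(0.0)
        assert s.n_a == s.n_b == 4
        # SE = sqrt(25/4 + 0/4) = 2.5; FD = |8.5 - (-3)| / 2.5
        assert s.fd_score == pytest.approx(4.6)

    def test_all_gap_outgroup_is_not_scorable(self, blosum62):
        assert score_site(column("WWWF", "AAAS", "-"), PART_441, blosum62) is None

    def test_all_gap_clade_is_not_scorable(self, blosum62):
        assert score_site(column("----", "AAAS", "W"), PART_441, blosum62) is None

    def test_clade_swap_leaves_score_unchanged(self, blosum62):
        s1 = score_site(column("WWWF", "AAAS", "WY"), PART_441, blosum62)
        swapped = NodePartition(0, PART_441.clade_b, PART_441.clade_a, PART_441.outgroup)
        s2 = score_site(column("WWWF", "AAAS", "WY"), swapped, blosum62)
        assert s1.fd_score == pytest.approx(s2.fd_score)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(AMINO_ACIDS), min_size=9, max_size=9))
    def test_order_within_groups_is_irrelevant(self, blosum62, residues):
        a, b, o = residues[:4], residues[4:8], residues[8:]
        s1 = score_site(column(a, b, o), PART_441, blosum62)
        s2 = score_site(column(a[::-1], b[::-1], o), PART_441, blosum62)
        assert s1.fd_score == pytest.approx(s2.fd_score)

    def test_zero_se_with_distinct_means_gets_floored_not_infinite(self, blosum62):
        s = score_site(column("AAAA", "WWWW", "W"), PART_441, blosum62)
        assert np.isfinite(s.fd_score)
        # |(-3) - 11| / 1e-6
        assert s.fd_score == pytest.approx(14e6)


class TestScoreColumns:
    def test_matches_single_site_scoring(self, blosum62, rng):
        n, L = 9, 40
        mat = rng.integers(0, 20, size=(n, L)).astype(np.int8)
        mat[rng.random(size=mat.shape) < 0.15] = -1  # sprinkle gaps
        ids = [f"a{i+1}" for i in range(4)] + [f"b{i+1}" for i in range(4)] + ["o1"]
        fd, parts = score_columns(
            mat, np.arange(4), np.arange(4, 8), np.array([8]), blosum62
        )
        for col in range(L):
            residues = {
                ids[i]: (AMINO_ACIDS[mat[i, col]] if mat[i, col] >= 0 else "-")
                for i in range(n)
            }
            site = score_site(residues, PART_441, blosum62)
            if site is None:
                assert np.isnan(fd[col])
            else:
                assert fd[col] == pytest.approx(site.fd_score, rel=1e-12)


class TestCalibration:
    @pytest.fixture(scope="class")
    def ten_taxon_tree(self):
        return GeneTree.from_newick(
            "((((a1:.1,a2:.1):.1,(a3:.1,a4:.1):.1):.3,"
            "((b1:.1,b2:.1):.1,(b3:.1,b4:.1):.1):.3):.5,(o1:.1,o2:.1):.5);"
        )

    def test_deterministic_given_seed(self, ten_taxon_tree, jtt, blosum62):
        part = ten_taxon_tree.testable_partitions()[0]
        kw = dict(floor=50, batch=10, cap=60)
        n1 = calibrate_null(ten_taxon_tree, part, 30, jtt, blosum62, seed=9, **kw)
        n2 = calibrate_null(ten_taxon_tree, part, 30, jtt, blosum62, seed=9, **kw)
        assert np.array_equal(n1.scores, n2.scores)
        assert n1.n_replicates == n2.n_replicates

    def test_star_like_tree_concentrates_null_near_zero(self, jtt, blosum62):
        # vanishing internal branches: clades are interchangeable, so the
        # two clade means coincide at almost every simulated column
        tree = GeneTree.from_newick(
            "((((a1:.2,a2:.2):1e-9,(a3:.2,a4:.2):1e-9):1e-9,"
            "((b1:.2,b2:.2):1e-9,(b3:.2,b4:.2):1e-9):1e-9):1e-9,o1:.2);"
        )
        part = tree.testable_partitions()[0]
        null = calibrate_null(
            tree, part, 100, jtt, blosum62, seed=3, floor=100, batch=50, cap=150
        )
        assert np.median(null.scores) < 1.0

    def test_degenerate_simulated_length_raises(self, ten_taxon_tree, jtt, blosum62):
        part = ten_taxon_tree.testable_partitions()[0]
        with pytest.raises(ValueError):
            calibrate_null(ten_taxon_tree, part, 0, jtt, blosum62, seed=1)

    def test_convergence_bookkeeping(self, ten_taxon_tree, jtt, blosum62):
        part = ten_taxon_tree.testable_partitions()[0]
        # a loose tolerance converges before the cap ... (the tolerance is
        # huge because the SE-floored score pool is heavy-tailed, so batch
        # deltas of the running mean are of order 1e4)
        loose = calibrate_null(
            ten_taxon_tree, part, 50, jtt, blosum62, seed=2,
            floor=100, batch=50, cap=1000, tol=1e12,
        )
        assert loose.converged
        assert loose.n_replicates < 1000
        # ... the tight default tolerance does not, and the cap bounds work
        with pytest.warns(UserWarning, match="cap"):
            tight = calibrate_null(
                ten_taxon_tree, part, 50, jtt, blosum62, seed=2,
                floor=100, batch=50, cap=300, tol=1e-6,
            )
        assert not tight.converged
        assert tight.n_replicates == 300

    def test_shared_simulations_give_one_null_per_node(self, jtt, blosum62):
        tree = GeneTree.from_newick(
            "(((((a1:.1,a2:.1):.1,(a3:.1,a4:.1):.1):.2,"
            "((b1:.1,b2:.1):.1,(b3:.1,b4:.1):.1):.2):.2,"
            "((c1:.1,c2:.1):.1,(c3:.1,c4:.1):.1):.3):.4,o1:.6);"
        )
        parts = tree.testable_partitions()
        assert len(parts) >= 2
        nulls = calibrate_nulls(
            tree, parts, 40, jtt, blosum62, seed=4, floor=50, batch=25, cap=75
        )
        assert set(nulls) == {p.node_id for p in parts}
        sizes = {n.scores.size for n in nulls.values()}
        assert len(sizes) == 1  # same replicate stream scored at every node


class TestSitePvalues:
    def test_add_one_upper_tail_formula(self):
        null = NullDistribution(0, np.arange(999, dtype=float), 999, True)
        p = site_pvalues(np.array([2000.0]), null)
        assert p[0] == pytest.approx(1 / 1000)

    def test_minimum_score_has_pvalue_one(self):
        null = NullDistribution(0, np.abs(np.random.default_rng(0).normal(size=500)), 500, True)
        p = site_pvalues(np.array([0.0]), null)
        assert p[0] == pytest.approx(1.0)

    def test_monotone_in_observed_score(self):
        null = NullDistribution(0, np.linspace(0, 10, 1000), 1000, True)
        obs = np.array([0.5, 1.5, 3.0, 9.0, 12.0])
        p = site_pvalues(obs, null)
        assert (np.diff(p) <= 0).all()

    def test_empty_null_is_a_calibration_error(self):
        null = NullDistribution(0, np.array([]), 0, False)
        with pytest.raises(CalibrationError):
            site_pvalues(np.array([1.0]), null)

    def test_nan_observations_propagate(self):
        null = NullDistribution(0, np.linspace(0, 1, 100), 100, True)
        p = site_pvalues(np.array([np.nan, 0.5]), null)
        assert np.isnan(p[0]) and not np.isnan(p[1])


def bh_stepup_oracle(pvals, alpha):
    """Independent Benjamini-Hochberg: literal step-up over sorted p."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] / (rank / m))
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # largest k with p_(k) <= k/m * alpha; reject p_(1..k)
    thresh = np.nonzero(p[order] <= (np.arange(1, m + 1) / m) * alpha)[0]
    sig = np.zeros(m, dtype=bool)
    if thresh.size:
        sig[order[: thresh.max() + 1]] = True
    return q, sig


class TestFdrCorrect:
    def test_worked_example(self):
        q, sig = fdr_correct(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])
        assert sig.tolist() == [True, True, True, False]

    def test_all_ones_rejects_nothing(self):
        q, sig = fdr_correct(np.ones(10))
        assert not sig.any()
        assert q == pytest.approx(np.ones(10))

    def test_matches_independent_stepup_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m)
            if rng.random() < 0.3:
                p = np.round(p, 2)  # exercise ties
            q, sig = fdr_correct(p, alpha=0.05)
            q_ref, sig_ref = bh_stepup_oracle(p, alpha=0.05)
            assert np.allclose(q, q_ref, rtol=0, atol=0)
            assert np.array_equal(sig, sig_ref)

    def test_qvalues_nondecreasing_in_sorted_pvalues(self, rng):
        p = rng.random(50)
        q, _ = fdr_correct(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nans_excluded_from_correction(self):
        q, sig = fdr_correct(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(q[1]) and not sig[1]
        q2, _ = fdr_correct(np.array([0.01, 0.02]))
        assert q[[0, 2]] == pytest.approx(q2)


class TestCallBranch:
    def _branch(self, pvals, blosum62):
        fd = np.full(len(pvals), 5.0)
        null = NullDistribution(0, np.linspace(0, 10, 1000), 1000, True)
        # build p-values by inverting the add-one formula against this null
        obs = np.quantile(np.linspace(0, 10, 1000), 1 - np.asarray(pvals))
        parts = {
            k: np.zeros(len(pvals))
            for k in ("xbar_a", "xbar_b", "var_a", "var_b", "n_a", "n_b")
        }
        parts["n_a"] += 4
        parts["n_b"] += 4
        return call_branch("g", PART_441, obs, parts, null, alpha=0.05)

    def test_no_significant_sites_means_no_call(self, blosum62):
        br = self._branch([0.9, 0.8, 0.7], blosum62)
        assert not br.is_fd
        assert br.significant_sites == []

    def test_single_significant_site_calls_the_branch(self, blosum62):
        br = self._branch([0.0001] + [0.9] * 10, blosum62)
        assert br.is_fd
        assert br.significant_sites == [0]

    def test_all_significant_sites_are_reported(self, blosum62):
        br = self._branch([0.0001] * 14, blosum62)
        assert br.is_fd
        assert br.significant_sites == list(range(14))
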