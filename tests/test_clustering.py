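"""The hard-assignment EM loop over collapsed column models: joint
likelihood, leave-one-out scores, convergence, warm starts and cluster
number selection."""

import numpy as np
import pytest

from madmix import evaluation
from madmix.clustering_engine import (
    ClusterState,
    fit,
    fit_incremental,
    fit_k,
    joint_log_likelihood,
    score_matrix,
    score_row,
    warm_start_split,
)
from madmix.column_models import CategoricalModel, ColumnSchema, ColumnSpec, GaussianModel, Hyperparameters
from madmix.io_cli import Table
from madmix import simulate as sim

from conftest import build_table


def scalar_joint_ll(table, assignment, hyper=None):
    """Independent oracle: rebuild every cluster from scratch with the
    scalar column models and sum their marginals."""
    hyper = hyper or Hyperparameters()
    total = 0.0
    for j in np.unique(assignment):
        idx = np.nonzero(assignment == j)[0]
        for l, spec in enumerate(table.cat_specs):
            m = CategoricalModel(len(spec.levels), hyper.pseudo_count)
            for i in idx:
                m.add_row(table.cat[i, l])
            total += m.log_marginal()
        for l in range(table.num.shape[1]):
            m = GaussianModel(*hyper.resolve(table.num[:, l]))
            for i in idx:
                m.add_row(table.num[i, l])
            total += m.log_marginal()
    return total


class TestJointLogLikelihood:
    def test_k1_is_sum_of_whole_column_marginals(self, random_mixed_table):
        t = random_mixed_table
        a = np.ones(t.n_rows, dtype=int)
        assert joint_log_likelihood(t, a) == pytest.approx(
            scalar_joint_ll(t, a), abs=1e-8)

    def test_matches_scalar_oracle_random_partitions(self, random_mixed_table, rng):
        t = random_mixed_table
        for _ in range(5):
            a = rng.integers(1, 4, t.n_rows)
            assert joint_log_likelihood(t, a) == pytest.approx(
                scalar_joint_ll(t, a), abs=1e-8)

    def test_empty_cluster_contributes_zero(self, random_mixed_table):
        t = random_mixed_table
        a = np.ones(t.n_rows, dtype=np.int64)
        with_empty = ClusterState(t, a - 1, 3)  # clusters 1 and 2 empty
        assert with_empty.joint_log_likelihood() == pytest.approx(
            joint_log_likelihood(t, a), abs=1e-10)

    def test_row_permutation_invariance(self, random_mixed_table, rng):
        t = random_mixed_table
        a = rng.integers(1, 3, t.n_rows)
        perm = rng.permutation(t.n_rows)
        assert joint_log_likelihood(t.take(perm), a[perm]) == pytest.approx(
            joint_log_likelihood(t, a), abs=1e-8)


class TestScoring:
    def test_collapsed_score_identity(self, random_mixed_table, rng):
        """score_row equals the joint-likelihood change of inserting the
        row into each cluster after removal.  Hyperparameters are fixed
        explicitly so the prior does not change with the row subset."""
        t = random_mixed_table
        hyper = Hyperparameters(mu0=0.0, b0=1.5)
        a = rng.integers(1, 4, t.n_rows)
        state = ClusterState(t, a - 1, 3, hyper)
        for i in (0, 7, 29):
            scores = score_row(state, i)
            rest = np.delete(np.arange(t.n_rows), i)
            base = scalar_joint_ll(t.take(rest), a[rest], hyper)
            for j in range(3):
                a_j = a.copy()
                a_j[i] = j + 1
                expected = scalar_joint_ll(t, a_j, hyper) - base
                assert scores[j] == pytest.approx(expected, abs=1e-8)

    def test_identical_clusters_score_identically(self):
        # two clusters with identical contents
        num = np.array([0.0, 1.0, 0.0, 1.0, 5.0])
        cat = np.array([0, 1, 0, 1, 1])
        t = build_table(cat_codes=cat, num=num, cat_levels=[2], n_rows=5)
        a = np.array([0, 0, 1, 1, 0])
        state = ClusterState(t, a, 2)
        scores = score_row(state, 4)
        assert scores[0] == pytest.approx(scores[1], abs=1e-10)

    def test_score_matrix_matches_score_row(self, random_mixed_table, rng):
        t = random_mixed_table
        a = rng.integers(1, 4, t.n_rows)
        state = ClusterState(t, a - 1, 3)
        mat = state.score_matrix()
        for i in range(0, t.n_rows, 5):
            np.testing.assert_allclose(mat[i], score_row(state, i),
                                       atol=1e-9)

    def test_centroid_row_scores_highest_for_own_cluster(self):
        table, labels = sim.make_mixed(
            sim.SynthSpec(n_rows=90, n_binary=0, n_clusters=3, delta=4.5,
                          seed=2))
        state = ClusterState(table, labels - 1, 3)
        mat = state.score_matrix()
        own = mat[np.arange(table.n_rows), labels - 1]
        frac_best = np.mean(own >= mat.max(axis=1) - 1e-12)
        assert frac_best > 0.9


class TestFitK:
    def test_k1_trivial(self, random_mixed_table):
        res = fit_k(random_mixed_table, 1)
        assert res.k == 1 and res.iterations == 1 and res.converged
        np.testing.assert_array_equal(res.assignment, 1)

    def test_k_exceeding_rows_rejected(self, random_mixed_table):
        with pytest.raises(ValueError):
            fit_k(random_mixed_table, 31)

    def test_two_well_separated_numeric_clusters(self, rng):
        n = 200
        x = np.concatenate([rng.normal(0, 1, n // 2),
                            rng.normal(10, 1, n // 2)])
        truth = np.repeat([1, 2], n // 2)
        t = build_table(num=x[:, None])
        res = fit_k(t, 2, seed=0)
        assert evaluation.adjusted_rand_index(res.assignment, truth) == 1.0

    def test_sequential_mode_monotone_objective(self, rng):
        for trial in range(20):
            cat = rng.integers(0, 3, (25, 2))
            num = rng.normal(0, 1, (25, 1))
            t = build_table(cat_codes=cat, num=num, cat_levels=[3, 3])
            res = fit_k(t, 3, mode="sequential", seed=trial)
            diffs = np.diff(res.trace)
            assert (diffs >= -1e-8).all()

    def test_batch_reports_best_seen_assignment(self, rng):
        cat = rng.integers(0, 3, (40, 3))
        t = build_table(cat_codes=cat, cat_levels=[3, 3, 3])
        res = fit_k(t, 4, seed=1, max_iters=30)
        assert res.log_likelihood == pytest.approx(max(res.trace))
        assert res.iterations <= 30

    def test_deterministic_given_seed(self, random_mixed_table):
        a = fit_k(random_mixed_table, 3, seed=7)
        b = fit_k(random_mixed_table, 3, seed=7)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.log_likelihood == b.log_likelihood


class TestWarmStart:
    def test_selects_exactly_bottom_rows_by_score(self, random_mixed_table):
        t = random_mixed_table
        res = fit_k(t, 2, seed=0)
        a = res.assignment
        scores = score_matrix(t, a)
        own = scores[np.arange(t.n_rows), a - 1]
        n_move = t.n_rows // (res.k + 1)
        expected = set(np.argsort(own, kind="stable")[:n_move])
        new = warm_start_split(t, res)
        moved = set(np.nonzero(new == res.k + 1)[0])
        assert moved == expected

    def test_split_produces_k_plus_1_nonempty_clusters(self, random_mixed_table):
        t = random_mixed_table
        res = fit_k(t, 2, seed=0)
        new = warm_start_split(t, res)
        sizes = np.bincount(new - 1, minlength=res.k + 1)
        assert (sizes > 0).all()

    def test_tied_rows_split_deterministically(self):
        # all rows identical: stable sort picks the lowest indices
        t = build_table(num=np.ones((12, 1)))
        res = fit_k(t, 1)
        new = warm_start_split(t, res)
        moved = np.nonzero(new == 2)[0]
        np.testing.assert_array_equal(moved, np.arange(12 // 2))


class TestSelection:
    def test_pure_noise_selects_one_cluster(self):
        rng = np.random.default_rng(5)
        t = build_table(num=rng.normal(0, 1, (150, 4)))
        sel = fit(t, k_max=3, selection="hmbeta", seed=0, m=150)
        assert sel.best_k == 1
        assert set(sel.evidences) == {1, 2, 3}

    def test_planted_three_clusters_recovered(self):
        table, _ = sim.make_mixed(
            sim.SynthSpec(n_rows=120, n_binary=0, n_clusters=3, delta=4.5,
                          seed=9))
        sel = fit(table, k_max=4, selection="hmbeta", seed=0, m=100)
        assert sel.best_k == 3

    def test_ladder_recovery_beats_random_init(self):
        table, labels = sim.make_mixed(
            sim.SynthSpec(n_rows=500, n_binary=0, delta=4.5, seed=0))
        fits = fit_incremental(table, 5, seed=0)
        ari = evaluation.adjusted_rand_index(fits[5].assignment, labels)
        assert ari > 0.9
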