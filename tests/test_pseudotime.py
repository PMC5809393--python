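"""Ordering LP construction and solution, embedding, trajectory smoothing."""

import numpy as np
import pytest

import cytocycle as cc
from cytocycle.data import DataError, PHASES, Stage
from cytocycle.phases import PhaseAssignment
from cytocycle.pseudotime import (
    EmbeddingWeights,
    build_ordering_lp,
    default_window,
    embed,
    mean_trajectory,
    ordering_objective,
    solve_lp,
    solve_ordering_lp,
    validate_trajectories,
)

from oracles import grid_oracle, vertex_oracle


def _labels(counts):
    out = []
    for phase, k in zip(PHASES, counts):
        out += [phase] * k
    return PhaseAssignment.from_labels(np.asarray(out, dtype=object))


class TestBuildLP:
    def test_pair_counting_two_cells_per_phase(self, rng):
        X = rng.normal(size=(8, 4))
        inst = build_ordering_lp(X, _labels((2, 2, 2, 2)))
        assert inst.n_constraints == 12  # 3 adjacent class pairs x 2x2 cell pairs
        assert inst.pairs_per_class == {p: 4 for p in inst.pairs_per_class}

    def test_balanced_weights_sum_to_one_per_class_pair(self, rng):
        X = rng.normal(size=(10, 4))
        inst = build_ordering_lp(X, _labels((4, 3, 2, 1)))
        assert inst.pair_weights.sum() == pytest.approx(3.0)  # one per class pair

    def test_single_phase_is_error(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(DataError, match="two phases"):
            build_ordering_lp(X, _labels((5, 0, 0, 0)))

    def test_perfectly_ordered_marker_gives_zero_slack(self, rng):
        X = np.zeros((12, 4))
        X[:, 0] = np.arange(12)  # first marker alone orders the phases
        X[:, 1:] = rng.normal(0, 0.01, size=(12, 3))
        inst = build_ordering_lp(X, _labels((3, 3, 3, 3)), margin=0.01)
        alpha, slack = solve_lp(inst)
        assert slack == pytest.approx(0.0, abs=1e-9)
        assert ordering_objective(inst, alpha) == pytest.approx(0.0, abs=1e-9)


class TestSolve:
    def test_matches_exact_enumeration_oracle_on_small_instances(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 4, size=4)
            X = np.vstack(
                [
                    rng.normal(0.8 * k, 1.0, size=(counts[k], 4))
                    for k in range(4)
                ]
            )
            inst = build_ordering_lp(X, _labels(counts))
            _, slack = solve_lp(inst)
            exact = vertex_oracle(inst.diffs, inst.pair_weights, inst.margin)
            assert slack == pytest.approx(exact, abs=1e-6)
            # the lattice scan can only do as well as the continuous optimum
            assert grid_oracle(inst.diffs, inst.pair_weights, inst.margin) >= slack - 1e-9

    def test_no_subsampling_equals_full_lp(self, processed):
        X, a = processed["X"][:300], processed["assignment"].subset(slice(300))
        w_full = solve_ordering_lp(X, a, subsample_fraction=1.0)
        inst = build_ordering_lp(X, a)
        alpha, slack = solve_lp(inst)
        np.testing.assert_allclose(w_full.alpha, alpha / alpha.sum(), atol=1e-9)
        assert w_full.total_slack == pytest.approx(slack, abs=1e-12)

    def test_deterministic_given_seed(self, processed):
        X, a = processed["X"], processed["assignment"]
        w1 = solve_ordering_lp(X, a, subsample_fraction=0.05, seed=5)
        w2 = solve_ordering_lp(X, a, subsample_fraction=0.05, seed=5)
        np.testing.assert_array_equal(w1.alpha, w2.alpha)
        assert w1.total_slack == w2.total_slack


class TestEmbed:
    def test_single_marker_alpha_is_rescaled_marker(self, rng):
        X = rng.normal(size=(50, 4))
        w = EmbeddingWeights(np.array([1.0, 0, 0, 0]), 0.01, 0.0, 0)
        traj = embed(w, X)
        expected = (X[:, 0] - X[:, 0].min()) / (X[:, 0].max() - X[:, 0].min())
        np.testing.assert_allclose(traj.pseudotime, expected)
        assert traj.pseudotime.min() == 0.0 and traj.pseudotime.max() == 1.0

    def test_identical_cells_degenerate_to_zero(self):
        X = np.ones((5, 4))
        w = EmbeddingWeights(np.full(4, 0.25), 0.01, 0.0, 0)
        traj = embed(w, X)
        np.testing.assert_array_equal(traj.pseudotime, 0.0)

    def test_ties_break_by_ascending_cell_id(self):
        X = np.zeros((4, 4))
        X[:, 0] = [1.0, 0.0, 1.0, 0.0]
        w = EmbeddingWeights(np.array([1.0, 0, 0, 0]), 0.01, 0.0, 0)
        traj = embed(w, X, cell_ids=np.array([9, 3, 2, 7]))
        assert traj.cell_ids[traj.order].tolist() == [3, 7, 2, 9]

    def test_zero_slack_implies_strict_phase_separation_in_order(self, rng):
        X = rng.normal(0, 0.001, size=(20, 4))
        X[:, 2] = np.linspace(0.0, 6.0, 20)  # gaps far exceed the margin
        labels = _labels((8, 6, 4, 2))
        w = solve_ordering_lp(X, labels, subsample_fraction=1.0)
        assert w.total_slack == pytest.approx(0.0, abs=1e-9)
        traj = embed(w, X)
        codes = labels.codes[traj.order]
        assert np.all(np.diff(codes) >= 0)  # every adjacent pair correctly placed


class TestMeanTrajectory:
    def _traj(self, n, rng=None):
        t = np.linspace(0, 1, n) if rng is None else np.sort(rng.uniform(size=n))
        return cc.Trajectory(t, np.argsort(t), np.arange(n))

    def test_window_one_is_identity(self, rng):
        m = cc.ExpressionMatrix(rng.normal(size=(30, 1)) + 10, ("a",), Stage.TRANSFORMED)
        traj = self._traj(30)
        out = mean_trajectory(traj, m, window=1)
        np.testing.assert_array_equal(out["a"].to_numpy(), m.values[traj.order, 0])

    def test_constant_marker_stays_constant(self):
        m = cc.ExpressionMatrix(np.full((40, 1), 7.0), ("a",), Stage.TRANSFORMED)
        out = mean_trajectory(self._traj(40), m, window=9)
        np.testing.assert_allclose(out["a"], 7.0)

    def test_window_larger_than_n_is_error(self):
        m = cc.ExpressionMatrix(np.ones((5, 1)), ("a",), Stage.TRANSFORMED)
        with pytest.raises(DataError, match="window"):
            mean_trajectory(self._traj(5), m, window=6)

    def test_smoothing_recovers_sinusoid_below_noise_third(self, rng):
        n = 5000
        t = np.sort(rng.uniform(size=n))
        signal = np.sin(2 * np.pi * t)
        noise_sd = 0.5
        values = (signal + rng.normal(0, noise_sd, size=n))[:, None]
        m = cc.ExpressionMatrix(values, ("a",), Stage.TRANSFORMED)
        traj = cc.Trajectory(t, np.arange(n), np.arange(n))
        out = mean_trajectory(traj, m, window=n // 50)
        rmse = np.sqrt(np.mean((out["a"].to_numpy() - signal) ** 2))
        assert rmse < noise_sd / 3

    def test_invariant_to_input_row_order(self, rng):
        n = 200
        t = rng.uniform(size=n)
        values = rng.normal(size=(n, 2))
        m = cc.ExpressionMatrix(values, ("a", "b"), Stage.TRANSFORMED)
        traj = cc.Trajectory(t, np.lexsort((np.arange(n), t)), np.arange(n))
        perm = rng.permutation(n)
        m2 = cc.ExpressionMatrix(values[perm], ("a", "b"), Stage.TRANSFORMED,
                                 cell_ids=perm)
        traj2 = cc.Trajectory(t[perm], np.lexsort((perm, t[perm])), perm)
        out1 = mean_trajectory(traj, m, window=11)
        out2 = mean_trajectory(traj2, m2, window=11)
        np.testing.assert_allclose(out1["a"], out2["a"])
        np.testing.assert_array_equal(out1["cell_id"], out2["cell_id"])

    def test_default_window_is_odd_and_at_least_51(self):
        assert default_window(10_000) == 99 or default_window(10_000) == 101
        assert default_window(1000) == 51
        assert default_window(30) == 29


def test_flat_holdout_marker_shows_no_trend(rng):
    n = 2000
    X = np.zeros((n, 2))
    X[:, 0] = np.sort(rng.normal(size=n))
    X[:, 1] = rng.normal(10, 1, size=n)  # flat marker
    m = cc.ExpressionMatrix(X, ("driver", "flat"), Stage.TRANSFORMED)
    t = (X[:, 0] - X[:, 0].min()) / np.ptp(X[:, 0])
    traj = cc.Trajectory(t, np.arange(n), np.arange(n))
    labels = _labels((1000, 500, 300, 200))
    report = validate_trajectories(traj, m, ["flat"], labels)
    assert all(report.loc["flat", f"trend_{p}"] == 0 for p in PHASES)
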