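"""Standardization, tree training, GMM initialization, EM, assignment."""

import numpy as np
import pytest

import cytocycle as cc
from cytocycle.data import DataError, DegenerateChannelError, PHASES, Stage
from cytocycle.phases import (
    PhaseAssignment,
    PhaseModel,
    assign_phases,
    fit_phase_model,
    init_gmm_from_tree,
    loglikelihood,
    refine_em,
    score_vs_reference,
    standardize,
    train_tree,
)

CC_ROLES = {"IdU": "IdU", "cyclinB1": "CycB", "pHH3": "HH3", "pRB": "RB"}


def _cc_matrix(X, stage=Stage.TRANSFORMED):
    return cc.ExpressionMatrix(X, tuple(CC_ROLES.values()), stage)


def _cmap():
    return cc.ChannelMap((), CC_ROLES)


def _separated_clusters(rng, n_per=(300, 200, 150, 50), spread=0.25):
    """Four spherical clusters with >= 4 sd separation between means."""
    centers = np.array(
        [[0, 0, 0, 0], [4, 0, 0, 1.5], [0, 4, 0, 3], [0, 4, 4, 4]], dtype=float
    )
    X, labels = [], []
    for k, phase in enumerate(PHASES):
        X.append(rng.normal(centers[k], spread, size=(n_per[k], 4)))
        labels += [phase] * n_per[k]
    return np.vstack(X), np.asarray(labels, dtype=object)


class TestStandardize:
    def test_zero_mean_unit_sample_sd(self, rng):
        m = _cc_matrix(rng.gamma(2, 3, size=(100, 4)))
        out, stats = standardize(m, _cmap())
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-9)
        assert out.stage is Stage.STANDARDIZED

    def test_stored_stats_reproduce_training_scaling_on_new_batch(self, rng):
        values = rng.gamma(2, 3, size=(200, 4))
        full = _cc_matrix(values)
        _, stats = standardize(full, _cmap())
        half = _cc_matrix(values[:100])
        out, _ = standardize(half, _cmap(), stats=stats)
        expected = (values[:100] - stats.means) / stats.sds
        np.testing.assert_array_equal(out.values, expected)

    def test_zero_variance_channel_is_degenerate(self):
        X = np.ones((10, 4))
        with pytest.raises(DegenerateChannelError):
            standardize(_cc_matrix(X), _cmap())


class TestTree:
    def test_well_separated_training_accuracy(self, rng):
        X, labels = _separated_clusters(rng)
        tree, acc = train_tree(X, labels, seed=0)
        assert acc >= 0.999

    def test_single_phase_training_set_is_error(self, rng):
        X = rng.normal(size=(20, 4))
        labels = np.asarray(["S"] * 20, dtype=object)
        with pytest.raises(DataError, match="G0/G1"):
            train_tree(X, labels)

    def test_first_split_on_idu_for_default_generator(self, processed):
        # IdU's S-phase bimodality is the dominant gate, mirroring the order
        # of splits in manual gating
        tree = processed["model"].tree
        assert tree.tree_.feature[0] == 0  # column 0 = IdU


class TestGMMInit:
    def test_moment_matching_on_separated_clusters(self, rng):
        X, labels = _separated_clusters(rng)
        model = init_gmm_from_tree(X, labels)
        for k, phase in enumerate(PHASES):
            np.testing.assert_allclose(model.means[k], X[labels == phase].mean(axis=0))
        np.testing.assert_allclose(
            model.weights, [300 / 700, 200 / 700, 150 / 700, 50 / 700]
        )

    def test_tiny_component_raises(self, rng):
        X, labels = _separated_clusters(rng, n_per=(50, 50, 50, 3))
        with pytest.raises(DataError, match="M"):
            init_gmm_from_tree(X, labels)

    def test_initial_loglik_not_above_converged(self, rng):
        X, labels = _separated_clusters(rng, spread=0.8)
        init = init_gmm_from_tree(X, labels)
        refined = refine_em(init, X)
        assert loglikelihood(init, X) <= loglikelihood(refined, X) + 1e-9


class TestEM:
    def test_loglik_trace_monotone_nondecreasing(self, rng):
        X, labels = _separated_clusters(rng, spread=1.2)
        refined = refine_em(init_gmm_from_tree(X, labels), X)
        trace = np.asarray(refined.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_converged_means_last_step_below_tol(self, rng):
        X, labels = _separated_clusters(rng, spread=0.8)
        tol = 1e-6
        refined = refine_em(init_gmm_from_tree(X, labels), X, tol=tol)
        assert refined.converged
        trace = refined.loglik_trace
        assert abs(trace[-1] - trace[-2]) < tol * abs(trace[-2])

    def test_em_barely_moves_on_data_from_init_model(self, rng):
        X, labels = _separated_clusters(rng, n_per=(4000, 3000, 2000, 1000))
        init = init_gmm_from_tree(X, labels)
        # sample fresh data exactly from the initialized mixture
        comps = rng.choice(4, p=init.weights, size=10_000)
        Y = np.vstack(
            [
                rng.multivariate_normal(init.means[k], init.covariances[k])
                for k in comps
            ]
        )
        refined = refine_em(init, Y)
        sds = np.sqrt(np.einsum("kii->ki", init.covariances))
        assert np.all(np.abs(refined.means - init.means) < 0.1 * sds)


class TestAssignment:
    def test_posterior_rows_sum_to_one_and_argmax_matches_label(self, processed):
        a = processed["assignment"]
        np.testing.assert_allclose(a.posteriors.sum(axis=1), 1, atol=1e-9)
        np.testing.assert_array_equal(
            a.labels, np.asarray(PHASES, dtype=object)[a.posteriors.argmax(axis=1)]
        )

    def test_cell_at_component_mean_has_confident_posterior(self, rng):
        X, labels = _separated_clusters(rng)
        model = refine_em(init_gmm_from_tree(X, labels), X)
        at_means = assign_phases(model, model.means)
        assert np.all(at_means.posteriors.max(axis=1) > 0.99)
        np.testing.assert_array_equal(at_means.labels, np.asarray(PHASES, dtype=object))

    def test_refinement_moves_boundary_cells_not_core_cells(self, processed):
        # cells whose label EM changed should come from less pure tree
        # leaves than cells it left alone
        model, X = processed["model"], processed["X"]
        tree_labels = model.tree.predict(X).astype(object)
        gmm_labels = processed["assignment"].labels
        changed = tree_labels != gmm_labels
        assert 0 < changed.sum() < 0.1 * X.shape[0]
        leaf = model.tree.apply(X)
        proba = model.tree.predict_proba(X).max(axis=1)  # leaf purity per cell
        assert proba[changed].mean() < proba[~changed].mean()

    def test_determinism_same_seed_same_model_and_labels(self, rng):
        X, labels = _separated_clusters(rng, spread=1.0)
        m1 = fit_phase_model(X, labels, seed=7)
        m2 = fit_phase_model(X, labels, seed=7)
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(
            assign_phases(m1, X).labels, assign_phases(m2, X).labels
        )


class TestScoring:
    def test_identity_gives_unit_accuracy_diagonal_confusion(self):
        a = PhaseAssignment.from_labels(np.array(["S", "M", "G2", "S"], dtype=object))
        acc, table = score_vs_reference(a, a)
        assert acc == 1.0
        assert table.values.sum() == np.trace(table.values) == 4

    def test_shifted_labels_give_zero_accuracy(self):
        ref = PhaseAssignment.from_labels(np.array(["G0/G1", "S", "G2"], dtype=object))
        shifted = PhaseAssignment.from_labels(np.array(["S", "G2", "M"], dtype=object))
        acc, _ = score_vs_reference(shifted, ref)
        assert acc == 0.0

    def test_random_labels_accuracy_near_quarter(self, rng):
        n = 20_000
        ref = PhaseAssignment.from_labels(
            rng.choice(np.asarray(PHASES, dtype=object), size=n)
        )
        pred = PhaseAssignment.from_labels(
            rng.choice(np.asarray(PHASES, dtype=object), size=n)
        )
        acc, _ = score_vs_reference(pred, ref)
        assert acc == pytest.approx(0.25, abs=0.02)

    def test_cell_id_mismatch_is_error(self):
        a = PhaseAssignment.from_labels(np.array(["S"], dtype=object), cell_ids=[1])
        b = PhaseAssignment.from_labels(np.array(["S"], dtype=object), cell_ids=[2])
        with pytest.raises(DataError, match="cell id"):
            score_vs_reference(a, b)


def test_model_json_round_trip_preserves_assignments(processed):
    model, X = processed["model"], processed["X"]
    restored = PhaseModel.from_json(model.to_json())
    np.testing.assert_allclose(restored.means, model.means)
    np.testing.assert_array_equal(
        assign_phases(restored, X).labels, processed["assignment"].labels
    )
    assert "IdU" in model.tree_rules()
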