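"""Diversity scoring, accuracy scoring, top-S pruning and aggregation."""

from types import SimpleNamespace

import numpy as np
import pytest

from hetsurv import (
    ModelLibrary,
    PruningConfig,
    ValidationError,
    accuracy_scores,
    diversity_scores,
    ensemble_predict,
    prediction_matrix,
    prune_top_s,
)
from hetsurv.selection import FoldRecord


def fake_library(predict_fns, perfs, orientation="higher_better"):
    members = []
    for i, fn in enumerate(predict_fns):
        members.append(
            SimpleNamespace(
                predict=fn,
                spec=SimpleNamespace(label=lambda i=i: f"member{i}"),
            )
        )
    return ModelLibrary(
        members=members,
        metric="cindex" if orientation == "higher_better" else "rmse",
        orientation=orientation,
        performances=np.asarray(perfs, dtype=float),
    )


def const_members(cols, perfs, **kw):
    fns = [lambda X, c=np.asarray(c, float): c for c in cols]
    return fake_library(fns, perfs, **kw)


def _orthonormal_mean_zero(n, k, seed=0):
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, k + 1))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q[:, :k]


class TestPredictionMatrix:
    def test_single_member_column(self):
        lib = const_members([[1.0, 2.0, 3.0]], [0.7])
        M = prediction_matrix(lib, np.zeros((3, 1)))
        np.testing.assert_allclose(M, [[1.0], [2.0], [3.0]])

    def test_member_order_permutes_columns(self):
        cols = [[1.0, 2.0], [5.0, 6.0], [9.0, 8.0]]
        lib = const_members(cols, [0.7, 0.8, 0.9])
        perm = const_members([cols[2], cols[0], cols[1]], [0.9, 0.7, 0.8])
        M = prediction_matrix(lib, np.zeros((2, 1)))
        P = prediction_matrix(perm, np.zeros((2, 1)))
        np.testing.assert_allclose(P, M[:, [2, 0, 1]])

    def test_member_failure_named(self):
        def boom(X):
            raise RuntimeError("nope")

        lib = fake_library([boom], [0.7])
        with pytest.raises(ValidationError, match="member0"):
            prediction_matrix(lib, np.zeros((2, 1)))

    def test_empty_input_rejected(self):
        lib = const_members([[1.0]], [0.7])
        with pytest.raises(ValidationError):
            prediction_matrix(lib, np.zeros((0, 1)))


class TestDiversityScores:
    def test_uncorrelated_member_diversity_one(self):
        q = _orthonormal_mean_zero(12, 4)
        # column 0 is orthogonal (Pearson 0) to the three others
        M = np.column_stack([q[:, 0], q[:, 1], q[:, 1] * 2, q[:, 1] * 3 + q[:, 2] * 0.1])
        d = diversity_scores(M, tau_corr=0.6)
        assert d[0] == 1.0

    def test_count_formula_direct_application(self):
        q = _orthonormal_mean_zero(20, 4)
        rhos = [0.7, 0.5, 0.9]
        cols = [q[:, 0]]
        for j, rho in enumerate(rhos, start=1):
            cols.append(rho * q[:, 0] + np.sqrt(1 - rho**2) * q[:, j])
        M = np.column_stack(cols)
        d = diversity_scores(M, tau_corr=0.6)
        # column 0 correlates >= 0.6 with exactly two others -> (4 - 2) / 4
        assert d[0] == pytest.approx(0.5)

    def test_identical_columns_floor_one_over_L(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        M = np.column_stack([col, col, col])
        np.testing.assert_allclose(diversity_scores(M, tau_corr=0.6), [1 / 3] * 3)

    def test_bounds_and_monotonicity_in_threshold(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(30, 6))
        L = M.shape[1]
        d_loose = diversity_scores(M, tau_corr=0.9)
        d_tight = diversity_scores(M, tau_corr=-0.5)
        for d in (d_loose, d_tight):
            assert (d >= 1 / L - 1e-12).all() and (d <= 1.0).all()
        # lowering the threshold can only count more members as correlated
        assert (d_tight <= d_loose + 1e-12).all()

    def test_constant_column_counts_as_uncorrelated(self):
        M = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0) * 2])
        d = diversity_scores(M, tau_corr=0.6)
        assert d[0] == 1.0  # sentinel never reaches the threshold

    def test_kendall_method_supported(self):
        M = np.column_stack([np.arange(6.0), np.arange(6.0) ** 3, -np.arange(6.0)])
        d = diversity_scores(M, tau_corr=0.9, method="kendall")
        np.testing.assert_allclose(d[:2], [2 / 3, 2 / 3])
        assert d[2] == 1.0

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            diversity_scores(np.ones((1, 3)), 0.5)


class TestAccuracyScores:
    def test_best_member_scores_one_both_orientations(self):
        assert accuracy_scores([0.6, 0.7], "higher_better")[1] == 1.0
        assert accuracy_scores([200.0, 100.0], "lower_better")[1] == 1.0

    def test_higher_better_ratio(self):
        np.testing.assert_allclose(
            accuracy_scores([0.6, 0.7], "higher_better"), [0.6 / 0.7, 1.0]
        )

    def test_lower_better_min_over_value(self):
        np.testing.assert_allclose(
            accuracy_scores([200.0, 100.0], "lower_better"), [0.5, 1.0]
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            accuracy_scores([0.5, 0.0], "higher_better")


class TestPruneTopS:
    def test_sort_and_take(self):
        lib = const_members([[1.0, 2.0]] * 3, [0.7, 0.6, 0.65])
        ens = prune_top_s(lib, [0.9, 0.6, 0.75], [0.9, 0.6, 0.75], size=2)
        assert set(ens.member_indices.tolist()) == {0, 2}
        assert ens.pruned

    def test_small_library_bypass(self):
        lib = const_members([[1.0, 2.0]] * 3, [0.7, 0.6, 0.65])
        ens = prune_top_s(lib, [1.0, 0.9, 0.8], [1.0, 1.0, 1.0], size=10)
        assert ens.member_indices.tolist() == [0, 1, 2]
        assert not ens.pruned

    @pytest.mark.parametrize("library_size,expected", [(1842, 92), (1801, 90)])
    def test_top_five_percent_arithmetic(self, library_size, expected):
        assert PruningConfig(top_fraction=0.05).resolve_size(library_size) == expected

    def test_boundary_tie_broken_by_accuracy(self):
        lib = const_members([[1.0, 2.0]] * 3, [0.7, 0.7, 0.7])
        # members 1 and 2 tie on combined; member 2 has higher accuracy
        ens = prune_top_s(lib, [1.0, 0.4, 0.6], [0.5, 1.1, 0.9], size=2)
        assert ens.member_indices.tolist() == [2, 0] or set(
            ens.member_indices.tolist()
        ) == {0, 2}

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            PruningConfig(size=5, top_fraction=0.05)
        with pytest.raises(ValidationError):
            PruningConfig(top_fraction=1.5)
        with pytest.raises(ValidationError):
            PruningConfig(size=5, tau_corr=2.0)


class TestEnsemblePredict:
    def test_single_member_identity_under_mean(self):
        lib = const_members([[3.0, 1.0, 2.0]], [0.7])
        out = ensemble_predict(lib, np.zeros((3, 1)), PruningConfig(size=1))
        np.testing.assert_allclose(out, [3.0, 1.0, 2.0])

    def test_rank_mean_scale_free(self):
        lib = const_members(
            [[1000.0, 2000.0, 3000.0], [0.1, 0.2, 0.3]], [0.7, 0.7]
        )
        out = ensemble_predict(
            lib, np.zeros((3, 1)), PruningConfig(size=2, aggregation="rank_mean")
        )
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_rank_mean_invariant_mean_is_not(self):
        cols = [np.array([1.0, 3.0, 2.0]), np.array([2.0, 1.0, 3.0])]
        transformed = [np.exp(5 * cols[0]), cols[1]]  # strictly increasing map
        cfgR = PruningConfig(size=2, aggregation="rank_mean")
        cfgM = PruningConfig(size=2, aggregation="mean")
        X = np.zeros((3, 1))
        rank_before = ensemble_predict(const_members(cols, [0.7, 0.7]), X, cfgR)
        rank_after = ensemble_predict(const_members(transformed, [0.7, 0.7]), X, cfgR)
        np.testing.assert_allclose(rank_before, rank_after)
        mean_before = ensemble_predict(const_members(cols, [0.7, 0.7]), X, cfgM)
        mean_after = ensemble_predict(const_members(transformed, [0.7, 0.7]), X, cfgM)
        assert not np.allclose(
            np.argsort(mean_before), np.argsort(mean_after)
        ) or not np.allclose(mean_before, mean_after)

    def test_three_members_mean_matches_arithmetic(self):
        rng = np.random.default_rng(2)
        cols = [rng.normal(size=5) for _ in range(3)]
        lib = const_members(cols, [0.7, 0.8, 0.9])
        out = ensemble_predict(lib, np.zeros((5, 1)), PruningConfig(size=3))
        np.testing.assert_allclose(out, np.column_stack(cols).mean(axis=1))

    def test_single_sample_rank_mean_undefined(self):
        lib = const_members([[1.0]], [0.7])
        with pytest.raises(ValidationError, match="single"):
            ensemble_predict(
                lib, np.zeros((1, 1)), PruningConfig(size=1, aggregation="rank_mean")
            )

    def test_best_uncorrelated_member_combined_score_two(self):
        q = _orthonormal_mean_zero(15, 3)
        cols = [q[:, 0], q[:, 1], q[:, 1] * 3.0]
        lib = const_members(cols, [0.8, 0.7, 0.6])
        _, trace = ensemble_predict(
            lib, np.zeros((15, 1)), PruningConfig(size=2), return_trace=True
        )
        assert trace.combined[0] == pytest.approx(2.0)
        np.testing.assert_allclose(
            trace.combined, trace.accuracy + trace.diversity
        )

    def test_dynamic_pruning_changes_with_test_data(self):
        """The same library can select different members on different test
        sets, because diversity is computed on the test features."""
        fns = [
            lambda X: X[:, 0],
            lambda X: X[:, 1],
            lambda X: X[:, 2],
        ]
        lib = fake_library(fns, [0.70, 0.69, 0.68])
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        X_corr = np.column_stack([base, base + 1e-3 * rng.normal(size=20),
                                  rng.normal(size=20)])
        X_anti = np.column_stack([base, rng.permutation(base), rng.normal(size=20)])
        cfg = PruningConfig(size=2)
        _, tr_corr = ensemble_predict(lib, X_corr, cfg, return_trace=True)
        _, tr_anti = ensemble_predict(lib, X_anti, cfg, return_trace=True)
        assert set(tr_corr.member_indices.tolist()) != set(
            tr_anti.member_indices.tolist()
        )

    def test_residual_basis_uses_training_store(self):
        times = np.array([10.0, 20.0, 30.0])
        events = np.array([True, True, False])

        def member(preds, perf):
            m = SimpleNamespace(
                predict=lambda X, p=np.asarray(preds, float): p[: len(X)],
                spec=SimpleNamespace(label=lambda: "m"),
                oof_store_=[
                    FoldRecord(
                        test_index=np.arange(3),
                        predictions=np.asarray(preds, float),
                        times=times,
                        events=events,
                    )
                ],
            )
            return m

        lib = ModelLibrary(
            members=[member([12.0, 18.0, 25.0], 5.0), member([8.0, 22.0, 40.0], 4.0)],
            metric="rmse",
            orientation="lower_better",
            performances=np.array([5.0, 4.0]),
        )
        cfg = PruningConfig(size=1, diversity_basis="residuals_on_training")
        out, trace = ensemble_predict(
            lib, np.zeros((3, 1)), cfg, return_trace=True
        )
        # residual correlation over events only; accuracy favors member 1
        assert trace.accuracy[1] == 1.0
        assert len(out) == 3
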