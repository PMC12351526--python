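"""Teacher and learner model contracts: stochasticity, support, fixed point."""

import numpy as np
import pytest

from motifteach import models
from motifteach.models import FixedPointConfig, TeacherModelSpec


def assert_column_stochastic(P, tol=1e-9):
    assert np.allclose(P.sum(axis=0), 1.0, atol=tol)


def assert_row_stochastic_on_support(P, tol=1e-9):
    sums = P.sum(axis=1)
    nonzero = sums > 0
    assert np.allclose(sums[nonzero], 1.0, atol=tol)


def slow_reference_fixed_point(C, alpha, tol=1e-12, max_iter=10_000):
    """Independent reference: explicit per-entry loops, no shared code."""
    C = [[float(x) for x in row] for row in C]
    n_d, n_h = len(C), len(C[0])

    def colnorm(M):
        out = [[0.0] * n_h for _ in range(n_d)]
        for j in range(n_h):
            s = sum(M[i][j] for i in range(n_d))
            for i in range(n_d):
                out[i][j] = M[i][j] / s
        return out

    def rownorm(M):
        out = [[0.0] * n_h for _ in range(n_d)]
        for i in range(n_d):
            s = sum(M[i])
            if s > 0:
                for j in range(n_h):
                    out[i][j] = M[i][j] / s
        return out

    T = colnorm(C)
    L = rownorm(T)
    for _ in range(max_iter):
        W = [[L[i][j] ** alpha if C[i][j] > 0 else 0.0 for j in range(n_h)]
             for i in range(n_d)]
        T2 = colnorm(W)
        L2 = rownorm(T2)
        resid = max(
            max(abs(T2[i][j] - T[i][j]) for j in range(n_h)) for i in range(n_d)
        )
        resid = max(
            resid,
            max(max(abs(L2[i][j] - L[i][j]) for j in range(n_h)) for i in range(n_d)),
        )
        T, L = T2, L2
        if resid < tol:
            return np.array(T), np.array(L)
    raise RuntimeError("reference did not converge")


class TestStrongSampling:
    def test_uniform_over_consistent(self, full_space):
        P = models.strong_sampling(full_space.C)
        assert_column_stochastic(P)
        m = full_space.C[:, 0].sum()
        col = P[:, 0]
        assert np.allclose(col[full_space.C[:, 0] > 0], 1.0 / m)

    def test_inconsistent_cells_exactly_zero(self, full_space):
        P = models.strong_sampling(full_space.C)
        assert (P[full_space.C == 0] == 0).all()

    def test_zero_column_rejected(self):
        C = np.array([[1, 0], [0, 0]])
        with pytest.raises(ValueError):
            models.strong_sampling(C)


class TestBaselineLearner:
    def test_row_stochastic_and_zero_rows(self, full_space):
        P = models.baseline_learner(full_space.C)
        assert_row_stochastic_on_support(P)
        i = full_space.row("0000000000")
        assert (P[i] == 0).all()

    def test_single_hypothesis_row(self):
        C = np.array([[1, 0], [1, 1], [0, 1]])
        P = models.baseline_learner(C)
        assert P[0, 0] == 1.0 and P[2, 1] == 1.0

    def test_worked_example_support_size(self, full_space, worked_example):
        P = models.baseline_learner(full_space.C)
        # 8 alternatives + the true hypothesis under this matcher
        assert (P[full_space.row(worked_example["simple"])] > 0).sum() == 9


class TestPedagogicalFixedPoint:
    def test_alpha_zero_recovers_strong(self, full_space):
        res = models.pedagogical_fixed_point(full_space.C, 0.0)
        assert np.abs(res.teacher - models.strong_sampling(full_space.C)).max() < 1e-12

    def test_converges_on_full_space(self, full_space):
        res = models.pedagogical_fixed_point(full_space.C, 1.0)
        assert res.residual < 1e-12
        assert_column_stochastic(res.teacher)
        assert_row_stochastic_on_support(res.learner)
        assert (res.teacher[full_space.C == 0] == 0).all()

    def test_idempotent_at_fixed_point(self, full_space):
        res = models.pedagogical_fixed_point(full_space.C, 1.0)
        again = models.pedagogical_fixed_point(
            full_space.C, 1.0, init_teacher=res.teacher
        )
        assert again.n_iterations == 1
        assert np.abs(again.teacher - res.teacher).max() < 1e-12

    def test_favors_less_ambiguous_necklace(self, full_space, worked_example):
        res = models.pedagogical_fixed_point(full_space.C, 1.0)
        j = worked_example["col"]
        p_simple = res.teacher[full_space.row(worked_example["simple"]), j]
        p_clumpy = res.teacher[full_space.row(worked_example["clumpy"]), j]
        assert p_simple > p_clumpy

    def test_concentration_monotone_in_alpha(self, full_space, worked_example):
        j = worked_example["col"]
        i = full_space.row(worked_example["simple"])
        probs = [
            models.pedagogical_fixed_point(full_space.C, a).teacher[i, j]
            for a in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_matches_slow_reference_on_reduced_space(self, reduced_space):
        for alpha in (0.5, 1.0, 2.0):
            fast = models.pedagogical_fixed_point(reduced_space.C, alpha)
            T_ref, L_ref = slow_reference_fixed_point(reduced_space.C, alpha)
            assert np.abs(fast.teacher - T_ref).max() < 1e-9
            assert np.abs(fast.learner - L_ref).max() < 1e-9

    def test_underflow_guard_large_alpha(self, reduced_space):
        res = models.pedagogical_fixed_point(reduced_space.C, 50.0)
        assert_column_stochastic(res.teacher)
        assert np.isfinite(res.teacher).all()

    def test_convergence_error_reports_residual(self, full_space):
        with pytest.raises(models.ConvergenceError, match="residual"):
            models.pedagogical_fixed_point(
                full_space.C, 1.0, FixedPointConfig(max_iterations=3)
            )


class TestLRBias:
    def test_prefix_readout(self):
        assert models.lr_bias_indicator("0010010100", ("00", "100", "101")) == 1
        assert models.lr_bias_indicator("1000000101", ("00", "100", "101")) == 0

    def test_concatenation_padded(self):
        h = ("01", "000", "111")
        for perm in (("01", "000", "111"), ("111", "01", "000")):
            d = "".join(perm).ljust(10, "0")
            assert models.lr_bias_indicator(d, h) == 1

    def test_matrix_agrees_with_indicator(self, reduced_space):
        M = models.lr_bias_matrix(reduced_space.necklaces, reduced_space.hypotheses)
        for i in range(0, len(reduced_space.necklaces), 7):
            for j in range(len(reduced_space.hypotheses)):
                assert M[i, j] == models.lr_bias_indicator(
                    reduced_space.necklaces[i], reduced_space.hypotheses[j]
                )


class TestVariants:
    def test_simplicity_heuristic_lambda_zero_is_strong(self, full_space):
        K = np.ones(len(full_space.necklaces))
        spec = TeacherModelSpec("simplicity_heuristic", simplicity_penalty=0.0)
        T = models.variant_teacher(full_space.C, spec, complexity_scores=K)
        assert np.abs(T - models.strong_sampling(full_space.C)).max() < 1e-12

    def test_lr_heuristic_large_weight_concentrates(self, full_space):
        lr = models.lr_bias_matrix(full_space.necklaces, full_space.hypotheses)
        spec = TeacherModelSpec("lr_heuristic", lr_weight=1e12)
        T = models.variant_teacher(full_space.C, spec, lr_indicator=lr)
        # columns with LR-satisfying necklaces put ~all mass there, uniformly
        j = 0
        sat = (lr[:, j] > 0) & (full_space.C[:, j] > 0)
        assert sat.any()
        assert T[sat, j].sum() > 1 - 1e-9
        assert np.allclose(T[sat, j], 1.0 / sat.sum(), atol=1e-9)

    def test_pedagogical_lr_neutral_weight_matches_plain(self, reduced_space):
        lr = models.lr_bias_matrix(reduced_space.necklaces, reduced_space.hypotheses)
        spec = TeacherModelSpec("pedagogical_lr", alpha=1.0, lr_weight=1.0)
        T = models.variant_teacher(reduced_space.C, spec, lr_indicator=lr)
        plain = models.pedagogical_fixed_point(reduced_space.C, 1.0).teacher
        assert np.abs(T - plain).max() < 1e-9

    def test_missing_bias_parameter_raises(self, reduced_space):
        with pytest.raises(ValueError, match="lr_weight"):
            models.variant_teacher(
                reduced_space.C, TeacherModelSpec("pedagogical_lr", alpha=1.0)
            )

    def test_all_variants_stochastic_and_support_preserving(self, reduced_space):
        lr = models.lr_bias_matrix(reduced_space.necklaces, reduced_space.hypotheses)
        K = np.linspace(1.0, 3.0, len(reduced_space.necklaces))
        specs = [
            TeacherModelSpec("pedagogical_lr", alpha=1.0, lr_weight=5.0),
            TeacherModelSpec("pedagogical_simplicity", alpha=1.0, simplicity_penalty=0.5),
            TeacherModelSpec("lr_heuristic", lr_weight=5.0),
            TeacherModelSpec("simplicity_heuristic", simplicity_penalty=0.5),
        ]
        for spec in specs:
            T = models.variant_teacher(
                reduced_space.C, spec, lr_indicator=lr, complexity_scores=K
            )
            assert_column_stochastic(T)
            assert (T[reduced_space.C == 0] == 0).all()
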