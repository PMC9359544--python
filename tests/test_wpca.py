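"""Weighted PCA regression: gap groups, weight matrix, alpha solve, recovery."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg
import scipy.optimize

from mocapfill import (
    DeltaThreshold,
    GapSpec,
    KRule,
    MotionSample,
    WeightMatrix,
    apply_gaps,
    build_gap_groups,
    fit_wpca,
    mse,
    reconstruct,
    residual_weight_matrix,
    solve_alpha,
)
from mocapfill.subspace import demean
from mocapfill.wpca_regression import _zero_gap_blocks


class TestBuildGapGroups:
    def test_one_group_per_gap(self, world):
        gaps = [GapSpec(0, 0, 30), GapSpec(2, 40, 80), GapSpec(5, 10, 50)]
        _, groups, _ = build_gap_groups(world.training, gaps, KRule.fixed(world.rank + 3))
        assert len(groups) == 3
        assert all(g.mapping.shape == (world.rank + 3,) * 2 for g in groups)

    def test_gap_on_constant_marker_gives_identity_mapping(self, rng):
        """Masking a zero-variance marker changes nothing: U~ spans U, T = I."""
        vals = rng.normal(size=(30, 9))
        vals[:, 0:3] = 2.0  # marker 0 constant
        s = MotionSample(values=vals, marker_names=["a", "b", "c"])
        U, groups, _ = build_gap_groups([s], [GapSpec(0, 5, 25)], KRule.fixed(4))
        g = groups[0]
        np.testing.assert_allclose(
            g.basis_gapped.basis @ g.basis_gapped.basis.T, U.basis @ U.basis.T, atol=1e-8
        )
        np.testing.assert_allclose(g.mapping, np.eye(4), atol=1e-8)

    def test_duplicated_training_set_changes_nothing(self, world):
        """Stacking the same sample K times leaves bases and mappings unchanged."""
        gaps = [GapSpec(1, 20, 60)]
        one = [world.training[0]]
        four = [world.training[0]] * 4
        U1, g1, _ = build_gap_groups(one, gaps, KRule.fixed(3))
        U4, g4, _ = build_gap_groups(four, gaps, KRule.fixed(3))
        np.testing.assert_allclose(U1.basis, U4.basis, atol=1e-8)
        np.testing.assert_allclose(g1[0].mapping, g4[0].mapping, atol=1e-7)

    def test_shape_mismatch_raises(self, world, rng):
        bad = MotionSample(values=rng.normal(size=(10, 24)), marker_names=[f"M{j}" for j in range(8)])
        with pytest.raises(ValueError, match="shape"):
            build_gap_groups(world.training + [bad], [GapSpec(0, 0, 5)])


class TestWeightMatrix:
    def test_zero_residual_floors_all_eigenvalues(self, world):
        """Perfect reconstruction (B = 0) -> W = (1/threshold) * identity."""
        gaps = [GapSpec(2, 30, 70)]
        _, groups, _ = build_gap_groups(world.training, gaps, KRule.fixed(world.rank + 3))
        centered, _ = demean(world.training)
        w = residual_weight_matrix(centered, groups, DeltaThreshold(absolute=0.5))
        np.testing.assert_allclose(w.diagonal, 2.0)

    def test_threshold_rule_direct_evaluation(self):
        w = WeightMatrix.from_residual_eigenvalues(np.array([4.0, 0.01]), DeltaThreshold(absolute=0.1))
        np.testing.assert_allclose(w.diagonal, [0.25, 10.0])

    def test_matches_independent_eigensolver(self, make_world):
        """1/diagonal equals the (floored) eigenvalues of B^T B from scipy.eigh."""
        world = make_world(noise_sd=0.05, seed=3)
        gaps = [GapSpec(1, 10, 90), GapSpec(4, 40, 110)]
        _, groups, _ = build_gap_groups(world.training, gaps, KRule.fixed(3))
        centered, _ = demean(world.training)
        thr = DeltaThreshold(relative=1e-3)
        w = residual_weight_matrix(centered, groups, thr)
        B = np.zeros_like(centered[0])
        for grp in groups:
            for a in centered:
                B += a - _zero_gap_blocks(a, [grp.gap]) @ grp.projector
        delta = np.sort(scipy.linalg.eigh(B.T @ B, eigvals_only=True))[::-1]
        delta = np.maximum(delta, thr.floor(delta))
        np.testing.assert_allclose(w.diagonal, 1.0 / delta, rtol=1e-8, atol=1e-10)

    def test_positive_entries_required(self):
        with pytest.raises(ValueError):
            WeightMatrix(diagonal=np.array([1.0, 0.0]))


def wls_objective(alpha, A_list, G_list, projectors, w, taper=None):
    """Literal weighted objective sum_i tr(R_i W R_i^T), independent route."""
    total = 0.0
    for a, g in zip(A_list, G_list):
        r = a - g @ sum(al * p for al, p in zip(alpha, projectors))
        if taper is not None:
            r = r * taper
        total += float(np.trace(r @ np.diag(w) @ r.T))
    return total


class TestSolveAlpha:
    def _random_instance(self, seed, K=3, G=2, m=15, d=9, k=3):
        r = np.random.default_rng(seed)
        A = [r.normal(size=(m, d)) for _ in range(K)]
        Ag = [a * (r.uniform(size=(m, d)) > 0.15) for a in A]
        projectors = []
        for _ in range(G):
            q = np.linalg.qr(r.normal(size=(d, k)))[0]
            projectors.append(q @ r.normal(size=(k, k)) @ q.T)
        w = r.uniform(0.5, 2.0, size=d)
        return A, Ag, projectors, WeightMatrix(diagonal=w)

    def test_exact_fit_gives_alpha_one(self, rng):
        A = [rng.normal(size=(12, 6)) for _ in range(3)]
        eye = [np.eye(6)]
        alpha = solve_alpha(A, A, eye, WeightMatrix(diagonal=np.ones(6)))
        np.testing.assert_allclose(alpha, [1.0], atol=1e-10)

    def test_identity_weight_reduces_to_ols(self):
        """W = I, no taper: alpha equals the unweighted normal-equation solution."""
        A, Ag, projectors, _ = self._random_instance(7)
        w1 = WeightMatrix(diagonal=np.ones(9))
        alpha = solve_alpha(A, Ag, projectors, w1)
        C = [np.vstack([g @ p for g in Ag]).ravel() for p in projectors]
        y = np.vstack(A).ravel()
        Cm = np.column_stack(C)
        oracle = np.linalg.solve(Cm.T @ Cm, Cm.T @ y)
        np.testing.assert_allclose(alpha, oracle, atol=1e-8)

    def test_matches_derivative_free_minimizer(self):
        """Normal equations agree with Powell minimization of the literal objective."""
        A, Ag, projectors, w = self._random_instance(11)
        alpha = solve_alpha(A, Ag, projectors, w)
        res = scipy.optimize.minimize(
            wls_objective, np.zeros(len(projectors)),
            args=(A, Ag, projectors, w.diagonal), method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14},
        )
        np.testing.assert_allclose(alpha, res.x, atol=1e-5)

    def test_invariant_to_weight_rescaling(self):
        A, Ag, projectors, w = self._random_instance(13)
        a1 = solve_alpha(A, Ag, projectors, w)
        a2 = solve_alpha(A, Ag, projectors, WeightMatrix(diagonal=17.0 * w.diagonal))
        np.testing.assert_allclose(a1, a2, atol=1e-8)

    def test_minimizer_dominance(self):
        """The solution beats alpha = 0 and the uniform alpha = 1/G."""
        A, Ag, projectors, w = self._random_instance(17, G=3)
        alpha = solve_alpha(A, Ag, projectors, w)
        G = len(projectors)
        f = lambda a: wls_objective(a, A, Ag, projectors, w.diagonal)
        assert f(alpha) <= f(np.zeros(G)) + 1e-9
        assert f(alpha) <= f(np.full(G, 1 / G)) + 1e-9

    def test_degenerate_all_masked_raises(self):
        A = [np.zeros((5, 6))]
        with pytest.raises(ValueError, match="degenerate"):
            solve_alpha(A, A, [np.eye(6)], WeightMatrix(diagonal=np.ones(6)))


class TestReconstruct:
    def test_no_gaps_passes_through(self, world):
        fitted = fit_wpca(world.training, [GapSpec(0, 0, 40)], KRule.fixed(world.rank + 3))
        out = reconstruct(world.test, fitted)  # test has no missing entries
        np.testing.assert_array_equal(out.values, world.test.values)
        assert (out.mask == 1).all()

    def test_exact_low_rank_recovery_single_gap(self, world):
        """Noiseless rank-r test in the training row-span: gap MSE ~ 0 for k >= r+3."""
        gaps = [GapSpec(marker=2, start=30, end=70)]
        gapped = apply_gaps(world.test, gaps)
        fitted = fit_wpca(world.training, gaps, KRule.fixed(world.rank + 3))
        out = reconstruct(gapped, fitted)
        rel = mse(out, world.test, (gapped.mask == 0).astype(float)) / world.test.values.var()
        assert rel < 1e-6
        np.testing.assert_allclose(fitted.alpha, [1.0], atol=1e-6)

    def test_only_missing_entries_replaced(self, make_world):
        world = make_world(noise_sd=0.05, seed=5)
        gaps = [GapSpec(marker=1, start=10, end=50)]
        gapped = apply_gaps(world.test, gaps)
        fitted = fit_wpca(world.training, gaps)
        out = reconstruct(gapped, fitted)
        obs = gapped.mask == 1
        np.testing.assert_array_equal(out.values[obs], gapped.values[obs])
        assert (out.mask == 1).all()

    def test_gap_mse_improves_with_training_set_size(self, make_world):
        """Mean gap MSE over 20 seeds decreases as K grows 1 -> 8 (noisy data)."""
        means = []
        for K in (1, 2, 4, 8):
            errs = []
            for seed in range(20):
                w = make_world(seed=100 + seed, n_train=8, noise_sd=0.05)
                gaps = [GapSpec(marker=3, start=25, end=95)]
                gapped = apply_gaps(w.test, gaps)
                fitted = fit_wpca(w.training[:K], gaps, KRule.fixed(w.rank + 3))
                errs.append(mse(reconstruct(gapped, fitted), w.test, (gapped.mask == 0).astype(float)))
            means.append(np.mean(errs))
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:])), means
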