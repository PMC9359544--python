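"""Weighted PCA regression for missing-marker recovery.

Training pipeline, for a test sample with gaps g = 1..G and gap-free training
samples A_1..A_K (all centered by pooled column means):

1. ``U`` — eigenbasis of the ungapped stack.
2. Per gap g: apply ONLY gap g to every training sample, giving the gap-group
   stack ``A~^g``; its eigenbasis ``U~^g`` and the mapping ``T^g`` aligning
   projections, so that ``P^g = U~^g T^g U^T`` reconstructs gap-g data.
3. Residual matrix ``B = sum_g sum_i (A_i - A~_i^g P^g)``; the eigenvalues
   {delta_i} of ``B^T B`` give the diagonal weight ``W = diag(1/delta_i)``
   with small eigenvalues floored at a threshold — the weighted-least-squares
   remedy for non-constant residual variance.
4. Regression coefficients alpha solve the weighted least squares
   ``min_a sum_i tr(R_i W R_i^T)`` with ``R_i = A_i - A~_i sum_g a_g P^g``,
   where ``A~_i`` now carries ALL G gaps simultaneously.
5. A test sample M is reconstructed as ``M* = M (sum_g a_g P^g)`` (after
   centering, gaps zero-filled); only the missing entries of M are replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion_io import GapSpec, MotionSample
from .subspace import EigenBasis, KRule, center_with_means, demean, eigen_mapping, pca_subspace

__all__ = [
    "DeltaThreshold",
    "WeightMatrix",
    "GapGroupModel",
    "FittedRegressor",
    "build_gap_groups",
    "residual_weight_matrix",
    "solve_alpha",
    "fit_wpca",
    "reconstruct",
]


@dataclass
class DeltaThreshold:
    """Floor for the residual eigenvalues entering ``W = diag(1/delta)``.

    ``relative`` floors at ``relative * max(delta)``; an ``absolute`` value,
    if given, overrides the relative rule.  A tiny absolute floor (1e-12)
    always applies so that an exactly-zero residual cannot divide by zero.
    """

    relative: float = 1e-3
    absolute: float | None = None

    def floor(self, delta: np.ndarray) -> float:
        if self.absolute is not None:
            return max(float(self.absolute), 1e-12)
        return max(self.relative * float(delta.max(initial=0.0)), 1e-12)


@dataclass
class WeightMatrix:
    """Diagonal weight ``W``: entries ``1/max(delta_i, threshold)``, all > 0."""

    diagonal: np.ndarray

    def __post_init__(self) -> None:
        self.diagonal = np.asarray(self.diagonal, dtype=float)
        if self.diagonal.ndim != 1 or (self.diagonal <= 0).any():
            raise ValueError("weight diagonal must be 1-D and strictly positive")

    @classmethod
    def from_residual_eigenvalues(
        cls, delta: np.ndarray, threshold: DeltaThreshold = DeltaThreshold()
    ) -> "WeightMatrix":
        delta = np.asarray(delta, dtype=float)
        floor = threshold.floor(delta)
        return cls(diagonal=1.0 / np.maximum(delta, floor))

    @property
    def size(self) -> int:
        return len(self.diagonal)


@dataclass
class GapGroupModel:
    """Per-gap model pieces: eigenbasis of the gap-group stack and mapping T."""

    gap: GapSpec
    basis_gapped: EigenBasis  # U~^g
    mapping: np.ndarray  # T^g, k x k
    basis_full: EigenBasis  # U^g: shared U for WPCA, taper-masked for LWPCA

    @property
    def projector(self) -> np.ndarray:
        """``P^g = U~^g T^g (U^g)^T``, the 3n x 3n per-gap reconstruction map."""
        return self.basis_gapped.basis @ self.mapping @ self.basis_full.basis.T


@dataclass
class FittedRegressor:
    """Everything needed to fill a test sample: projectors, alpha, W, means."""

    projectors: list[np.ndarray]
    alpha: np.ndarray
    weight: WeightMatrix
    column_means: np.ndarray
    gaps: list[GapSpec] = field(default_factory=list)
    variant: str = "wpca"

    def __post_init__(self) -> None:
        if len(self.projectors) != len(self.alpha) or len(self.alpha) < 1:
            raise ValueError("need one projector per alpha coefficient, G >= 1")

    @property
    def combined_operator(self) -> np.ndarray:
        """``sum_g alpha_g P^g`` applied to a centered test sample."""
        return sum(a * p for a, p in zip(self.alpha, self.projectors))


def _zero_gap_blocks(centered: np.ndarray, gaps: list[GapSpec]) -> np.ndarray:
    """Apply gaps to an already-centered matrix (zero = mean imputation)."""
    out = centered.copy()
    for g in gaps:
        out[g.start : g.end, 3 * g.marker : 3 * g.marker + 3] = 0.0
    return out


def build_gap_groups(
    training: list[MotionSample] | list[np.ndarray],
    gaps: list[GapSpec],
    k_rule: KRule = KRule(),
) -> tuple[EigenBasis, list[GapGroupModel], np.ndarray]:
    """Shared basis U plus one (U~^g, T^g) pair per gap.

    ``training`` may be MotionSamples (centered internally by pooled means) or
    already-centered matrices (means then reported as zero).  Each gap-group
    stack applies exactly one gap to every training sample.  The retained
    dimension k is chosen from U's eigenvalues and imposed on every U~^g so
    that every mapping is k x k.
    """
    if not gaps:
        raise ValueError("need at least one gap")
    if isinstance(training[0], MotionSample):
        centered, means = demean(training)  # type: ignore[arg-type]
    else:
        centered = [np.asarray(a, dtype=float) for a in training]
        means = np.zeros(centered[0].shape[1])
    shape = centered[0].shape
    if any(a.shape != shape for a in centered):
        raise ValueError("training samples must share one shape")
    for g in gaps:
        if g.end > shape[0] or 3 * g.marker + 3 > shape[1]:
            raise IndexError(f"gap {g} outside sample shape {shape}")

    basis_full = pca_subspace(np.vstack(centered), k_rule)
    k = KRule.fixed(basis_full.k)
    groups = []
    for gap in gaps:
        gapped = [_zero_gap_blocks(a, [gap]) for a in centered]
        basis_gapped = pca_subspace(np.vstack(gapped), k)
        mapping = eigen_mapping(centered, basis_full, gapped, basis_gapped)
        groups.append(
            GapGroupModel(gap=gap, basis_gapped=basis_gapped, mapping=mapping, basis_full=basis_full)
        )
    return basis_full, groups, means


def residual_weight_matrix(
    training_centered: list[np.ndarray],
    groups: list[GapGroupModel],
    threshold: DeltaThreshold = DeltaThreshold(),
) -> WeightMatrix:
    """Weight matrix from the accumulated single-gap reconstruction residual.

    ``B = sum_g sum_i (A_i - A~_i^g P^g)`` is an m x 3n matrix; the
    eigenvalues {delta} of ``B^T B`` (squared singular values of B, padded
    with zeros up to 3n) give ``W = diag(1 / max(delta, threshold))``.
    """
    m, d = training_centered[0].shape
    B = np.zeros((m, d))
    for grp in groups:
        P = grp.projector
        for a in training_centered:
            B += a - _zero_gap_blocks(a, [grp.gap]) @ P
    s = np.linalg.svd(B, compute_uv=False)
    delta = np.zeros(d)
    delta[: len(s)] = s**2
    return WeightMatrix.from_residual_eigenvalues(delta, threshold)


def solve_alpha(
    training_centered: list[np.ndarray],
    multi_gapped: list[np.ndarray],
    projectors: list[np.ndarray],
    weight: WeightMatrix,
    taper: np.ndarray | None = None,
) -> np.ndarray:
    """Regression coefficients minimizing the weighted quadratic residual.

    Objective:  ``sum_i tr( R_i W R_i^T )`` with
    ``R_i = (A_i - A~_i sum_g alpha_g P^g) .* taper``  (elementwise taper
    optional; `A~_i` carries all G gaps).  Being quadratic in alpha, the
    minimizer solves the G x G normal equations
    ``M_{gh} = sum_i tr(C_i^g W C_i^h^T)``, ``b_g = sum_i tr(C_i^g W A_i'^T)``
    with ``C_i^g = (A~_i P^g) .* taper`` and ``A_i' = A_i .* taper``;
    a pseudo-inverse handles a singular M.
    """
    G = len(projectors)
    if G < 1:
        raise ValueError("need at least one projector")
    w = weight.diagonal
    M = np.zeros((G, G))
    b = np.zeros(G)
    any_signal = False
    for a_full, a_gapped in zip(training_centered, multi_gapped):
        target = a_full if taper is None else a_full * taper
        C = []
        for P in projectors:
            c = a_gapped @ P
            C.append(c if taper is None else c * taper)
        if any(np.any(c) for c in C):
            any_signal = True
        for g in range(G):
            cgw = C[g] * w  # column-wise scaling by the diagonal of W
            b[g] += float(np.sum(cgw * target))
            for h in range(g, G):
                M[g, h] += float(np.sum(cgw * C[h]))
    if not any_signal:
        raise ValueError("all projected training samples are zero; system is degenerate")
    M = M + np.triu(M, 1).T
    try:
        alpha = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        alpha = np.linalg.pinv(M) @ b
    if not np.isfinite(alpha).all() or np.linalg.cond(M) > 1e12:
        alpha = np.linalg.pinv(M, rcond=1e-12) @ b
    return alpha


def fit_wpca(
    training: list[MotionSample],
    gaps: list[GapSpec],
    k_rule: KRule = KRule(),
    threshold: DeltaThreshold = DeltaThreshold(),
) -> FittedRegressor:
    """Fit the weighted PCA regressor for a given test gap pattern."""
    basis_full, groups, means = build_gap_groups(training, gaps, k_rule)
    centered, _ = demean(training)
    weight = residual_weight_matrix(centered, groups, threshold)
    projectors = [grp.projector for grp in groups]
    multi = [_zero_gap_blocks(a, gaps) for a in centered]
    alpha = solve_alpha(centered, multi, projectors, weight)
    return FittedRegressor(
        projectors=projectors,
        alpha=alpha,
        weight=weight,
        column_means=means,
        gaps=list(gaps),
        variant="wpca",
    )


def reconstruct(test: MotionSample, fitted: FittedRegressor) -> MotionSample:
    """Fill the missing entries of a test sample.

    The test sample is centered with the stored *training* means (gaps
    zero-filled), pushed through ``sum_g alpha_g P^g``, and un-centered.
    Only entries with mask=0 are replaced; observed entries pass through
    unchanged.  The output mask is all-ones.
    """
    if test.values.shape[1] != fitted.column_means.shape[0]:
        raise ValueError("test sample width does not match the fitted model")
    centered = center_with_means(test, fitted.column_means)
    filled = centered @ fitted.combined_operator + fitted.column_means
    out = test.copy()
    out.values = np.where(test.mask == 1, test.values, filled)
    out.mask = np.ones_like(out.mask)
    return out
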