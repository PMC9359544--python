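"""Locally weighted PCA regression: Gaussian taper masks over the skeleton.

Plain weighted PCA regression underfits when a gap sits in a region of sharp,
localized motion: the global eigenspaces smooth right over it.  The locally
weighted variant multiplies the training data, per gap, by a Gaussian taper
mask that keeps full weight at the gap and decays with spatio-temporal
distance from it,

    Q^g[i, j] = exp( - dist^2((i, j), gap g) / sigma^2 ),

where the distance combines the temporal offset of frame ``i`` from the gap
interval with the shortest-path distance of marker ``j`` from the gap marker
on the skeleton graph.  Masking the data this way tapers the effective
covariance to a neighborhood of the gap (covariance tapering), so the per-gap
eigenspaces ``U^g`` and ``U~^g`` describe local structure; the regression
residual and the alpha-solve are tapered the same way.

With sigma -> infinity every mask tends to 1 and the fit coincides with the
plain weighted PCA regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion_io import GapSpec, MotionSample, SkeletonModel, skeleton_distance
from .subspace import KRule, demean, eigen_mapping, pca_subspace
from .wpca_regression import (
    DeltaThreshold,
    FittedRegressor,
    GapGroupModel,
    WeightMatrix,
    _zero_gap_blocks,
    reconstruct,
    solve_alpha,
)

__all__ = ["TaperConfig", "TaperMask", "taper_mask", "fit_lwpca", "reconstruct_lwpca"]


@dataclass
class TaperConfig:
    """Gaussian taper parameters.

    ``sigma`` is the window size of the Gaussian, in the dimensionless
    combined distance.  Frames and skeleton hops are incommensurate, so each
    is scaled to a dimensionless quantity first: ``temporal_scale`` frames
    and ``spatial_scale`` skeleton-distance units both map to one unit of
    distance.  Defaults (sigma=3, temporal_scale=10 frames, spatial_scale=1
    hop) make the mask decay over a few bones and a few tens of frames.
    """

    sigma: float = 3.0
    temporal_scale: float = 10.0
    spatial_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma, self.temporal_scale, self.spatial_scale) <= 0:
            raise ValueError("sigma and scales must be positive")


@dataclass
class TaperMask:
    """An m x n matrix of weights in (0, 1]; 1 on every cell inside its gap."""

    values: np.ndarray

    def expand(self) -> np.ndarray:
        """Replicate each marker column across its x, y, z coordinates."""
        return np.repeat(self.values, 3, axis=1)


def temporal_gap_distance(frames: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance in frames from each frame index to the interval [start, end):
    0 inside, otherwise distance to the nearest frame of the interval."""
    return np.maximum(0, np.maximum(start - frames, frames - (end - 1)))


def taper_mask(
    gap: GapSpec,
    shape: tuple[int, int],
    skeleton: SkeletonModel,
    config: TaperConfig = TaperConfig(),
) -> TaperMask:
    """Gaussian taper mask for one gap over an (m frames x n markers) grid.

    For cell (i, j):  ``d_t`` = frame distance of i to the gap interval over
    ``temporal_scale``;  ``d_s`` = skeleton shortest-path distance of marker j
    to the gap marker over ``spatial_scale``;
    ``Q[i, j] = exp(-(d_t^2 + d_s^2) / sigma^2)``.
    """
    m, n = shape
    if gap.end > m or gap.marker >= n:
        raise IndexError(f"gap {gap} outside shape {shape}")
    d_t = temporal_gap_distance(np.arange(m), gap.start, gap.end) / config.temporal_scale
    d_s = (
        np.array([skeleton_distance(skeleton, j, gap.marker) for j in range(n)])
        / config.spatial_scale
    )
    q = np.exp(-(d_t[:, None] ** 2 + d_s[None, :] ** 2) / config.sigma**2)
    return TaperMask(values=q)


def fit_lwpca(
    training: list[MotionSample],
    gaps: list[GapSpec],
    skeleton: SkeletonModel,
    config: TaperConfig = TaperConfig(),
    k_rule: KRule = KRule(),
    threshold: DeltaThreshold = DeltaThreshold(),
) -> FittedRegressor:
    """Fit the locally weighted PCA regressor.

    Per gap g the ungapped and the single-gap training stacks are multiplied
    elementwise by Q^g (expanded to the 3n coordinate columns) before the
    eigen-decompositions, yielding local bases U^g and U~^g and the mapping
    T^g between them.  The accumulated residual

        B = sum_g [ sum_i (A_i - A~_i^g U~^g T^g (U^g)^T) ] .* Q^g

    feeds the weight matrix, and alpha is solved under the normalized
    combined mask ``Qbar = (sum_g Q^g) / max`` (maximum entry exactly 1).

    The retained dimension k is chosen once from the unmasked stack and
    imposed on every local basis, so the sigma -> infinity limit reproduces
    the plain WPCA fit exactly.
    """
    if not gaps:
        raise ValueError("need at least one gap")
    centered, means = demean(training)
    m, d = centered[0].shape
    n = d // 3
    if skeleton.n_markers != n:
        raise ValueError(f"skeleton has {skeleton.n_markers} markers, samples have {n}")

    # shared k from the unmasked stack
    k = KRule.fixed(pca_subspace(np.vstack(centered), k_rule).k)

    groups: list[GapGroupModel] = []
    masks: list[TaperMask] = []
    B = np.zeros((m, d))
    for gap in gaps:
        q3 = taper_mask(gap, (m, n), skeleton, config)
        masks.append(q3)
        q = q3.expand()
        full_masked = [a * q for a in centered]
        gapped = [_zero_gap_blocks(a, [gap]) for a in centered]
        gapped_masked = [a * q for a in gapped]
        basis_full = pca_subspace(np.vstack(full_masked), k)
        basis_gapped = pca_subspace(np.vstack(gapped_masked), k)
        mapping = eigen_mapping(full_masked, basis_full, gapped_masked, basis_gapped)
        grp = GapGroupModel(gap=gap, basis_gapped=basis_gapped, mapping=mapping, basis_full=basis_full)
        groups.append(grp)
        P = grp.projector
        resid = np.zeros((m, d))
        for a, ag in zip(centered, gapped):
            resid += a - ag @ P
        B += resid * q

    s = np.linalg.svd(B, compute_uv=False)
    delta = np.zeros(d)
    delta[: len(s)] = s**2
    weight = WeightMatrix.from_residual_eigenvalues(delta, threshold)

    qbar = np.sum([tm.values for tm in masks], axis=0)
    qbar = qbar / qbar.max()
    qbar3 = np.repeat(qbar, 3, axis=1)

    projectors = [grp.projector for grp in groups]
    multi = [_zero_gap_blocks(a, gaps) for a in centered]
    alpha = solve_alpha(centered, multi, projectors, weight, taper=qbar3)
    return FittedRegressor(
        projectors=projectors,
        alpha=alpha,
        weight=weight,
        column_means=means,
        gaps=list(gaps),
        variant="lwpca",
    )


def reconstruct_lwpca(test: MotionSample, fitted: FittedRegressor) -> MotionSample:
    """Fill a test sample with a locally weighted fit.

    Identical contract to :func:`mocapfill.wpca_regression.reconstruct` (the
    two variants differ only in how their projectors were trained).
    """
    return reconstruct(test, fitted)
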