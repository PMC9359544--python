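"""Recovery of wholly missing frames via Gram-matrix (frame-space) eigenbases.

When entire frames are dropped (e.g. removed because of jitter), no marker
carries information at those times and the marker-space regression cannot
help.  Frame correlation can: the Gram matrix ``A A^T`` of the horizontally
concatenated training stack ``A = (A_1, ..., A_K)`` (m x 3nK, centered) has
eigenvectors spanning the frame-correlation space, and a sample whose columns
lie in that space can have missing rows reconstructed from observed ones.

Each missing frame is treated as its own gap g with a temporal-only Gaussian
taper ``q^g[i] = exp(-(d_t(i, g) / temporal_scale)^2 / sigma^2)`` multiplying
the ROWS of the training stack before the decomposition, which localizes the
frame basis ``V^g`` around that frame.  Splitting rows into observed (part 1)
and missing (part 2), the per-gap regressor predicts missing rows from
observed ones,

    D^g = V2^g H^g (V1^g)^T Lam1^g,     H^g = (V1^g^T V1^g)^+,

with ``Lam1^g`` the taper weights on observed rows, so that ``D^g M1`` is the
taper-weighted least-squares projection of the observed rows onto the local
frame subspace, evaluated at the missing rows.  (Written on the *tapered*
stack, this is exactly the tapered-basis regression; folding the taper into
the projection keeps the estimator consistent for samples whose observed rows
are not themselves tapered, and makes it exact on noiseless subspace data.)

The residual ``B = sum_g (A_2 - D^g A_1)`` over the training stack feeds a
diagonal weight matrix from the eigenvalues of ``B B^T`` — one weight per
missing frame — and the coefficients alpha solve the weighted least squares
``min_a tr(R^T W R)``, ``R = A_2 - sum_g a_g D^g A_1``.  Recovery:
``M2* = sum_g a_g D^g M1`` (means restored; observed rows untouched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lwpca_regression import TaperConfig, temporal_gap_distance
from .motion_io import FrameGapSpec, MotionSample
from .subspace import KRule, center_with_means, demean
from .wpca_regression import DeltaThreshold, WeightMatrix

__all__ = [
    "FrameRecoveryModel",
    "fit_frame_recovery",
    "recover_frames",
    "frame_gap_fraction",
]

log = logging.getLogger(__name__)


@dataclass
class FrameGroup:
    """Per-missing-frame pieces: partitioned local frame basis and H^g."""

    frame: int
    basis_observed: np.ndarray  # V1^g, (m - G) x k
    basis_missing: np.ndarray  # V2^g, G x k
    h: np.ndarray  # k x k, symmetric
    taper_observed: np.ndarray  # q^g restricted to observed rows

    @property
    def regressor(self) -> np.ndarray:
        """``D^g = V2 H V1^T Lam1``, (G x m-G): observed rows -> missing rows."""
        return self.basis_missing @ self.h @ (self.basis_observed * self.taper_observed[:, None]).T


@dataclass
class FrameRecoveryModel:
    """Fitted frame-space regressor for a fixed missing-frame pattern."""

    groups: list[FrameGroup]
    alpha: np.ndarray
    weight: WeightMatrix
    column_means: np.ndarray
    missing_frames: np.ndarray  # sorted frame indices, length G
    n_frames: int

    @property
    def observed_frames(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_frames), self.missing_frames)

    @property
    def combined_regressor(self) -> np.ndarray:
        return sum(a * grp.regressor for a, grp in zip(self.alpha, self.groups))


def frame_gap_fraction(frame_gaps: list[FrameGapSpec], m: int) -> float:
    """Percentage of frames missing: ``100 * (total missing frames) / m``."""
    frames: set[int] = set()
    for fg in frame_gaps:
        if fg.end > m:
            raise IndexError(f"frame gap [{fg.start}, {fg.end}) exceeds {m} frames")
        frames.update(fg.frames)
    return 100.0 * len(frames) / m


def _missing_frames(frame_gaps: list[FrameGapSpec], m: int) -> np.ndarray:
    frames: set[int] = set()
    for fg in frame_gaps:
        if fg.end > m:
            raise IndexError(f"frame gap [{fg.start}, {fg.end}) exceeds {m} frames")
        frames.update(fg.frames)
    return np.array(sorted(frames), dtype=int)


def fit_frame_recovery(
    training: list[MotionSample],
    frame_gaps: list[FrameGapSpec],
    config: TaperConfig = TaperConfig(),
    k_rule: KRule = KRule(),
    threshold: DeltaThreshold = DeltaThreshold(),
) -> FrameRecoveryModel:
    """Fit the frame-space regressor for a missing-frame pattern.

    Every individual missing frame counts as one gap, so a 3-frame run yields
    G = 3 taper masks and 3 alpha coefficients.  All training samples must
    share the frame count m; they are centered by pooled column means and
    concatenated horizontally (m x 3nK).
    """
    if not training:
        raise ValueError("need at least one training sample")
    m = training[0].n_frames
    if any(s.n_frames != m for s in training):
        raise ValueError("all training samples must share the frame count")
    miss = _missing_frames(frame_gaps, m)
    G = len(miss)
    if G < 1:
        raise ValueError("need at least one missing frame")
    if G >= m:
        raise ValueError(f"{G} missing frames of {m} leaves nothing observed")
    obs = np.setdiff1d(np.arange(m), miss)

    centered, means = demean(training)
    A = np.hstack(centered)  # m x 3nK

    # shared k from the unmasked stack; frame-space singular values
    s_full = np.linalg.svd(A, compute_uv=False)
    k = k_rule.choose_k(s_full**2)
    if k > len(obs):
        log.warning("k=%d exceeds %d observed frames; reduced", k, len(obs))
        k = len(obs)

    frames_idx = np.arange(m)
    groups: list[FrameGroup] = []
    B = np.zeros((G, A.shape[1]))
    A1, A2 = A[obs], A[miss]
    for f in miss:
        d_t = temporal_gap_distance(frames_idx, int(f), int(f) + 1) / config.temporal_scale
        q = np.exp(-(d_t**2) / config.sigma**2)
        masked = A * q[:, None]
        v, _, _ = np.linalg.svd(masked, full_matrices=False)
        v = v[:, :k]
        v1, v2 = v[obs], v[miss]
        h = np.linalg.pinv(v1.T @ v1, hermitian=True)
        h = (h + h.T) / 2
        grp = FrameGroup(
            frame=int(f),
            basis_observed=v1,
            basis_missing=v2,
            h=h,
            taper_observed=q[obs],
        )
        groups.append(grp)
        B += A2 - grp.regressor @ A1

    s = np.linalg.svd(B, compute_uv=False)
    delta = np.zeros(G)
    delta[: len(s)] = s**2
    weight = WeightMatrix.from_residual_eigenvalues(delta, threshold)

    # weighted least squares for alpha over the training stack
    w = weight.diagonal
    C = [grp.regressor @ A1 for grp in groups]
    M = np.zeros((G, G))
    b = np.zeros(G)
    for g in range(G):
        cgw = C[g] * w[:, None]  # row-wise scaling: W acts on missing-frame index
        b[g] = float(np.sum(cgw * A2))
        for hh in range(g, G):
            M[g, hh] = float(np.sum(cgw * C[hh]))
    M = M + np.triu(M, 1).T
    try:
        alpha = np.linalg.solve(M, b)
        if not np.isfinite(alpha).all() or np.linalg.cond(M) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        alpha = np.linalg.pinv(M, rcond=1e-10) @ b
    return FrameRecoveryModel(
        groups=groups,
        alpha=alpha,
        weight=weight,
        column_means=means,
        missing_frames=miss,
        n_frames=m,
    )


def recover_frames(test: MotionSample, model: FrameRecoveryModel) -> MotionSample:
    """Replace the missing frames of a test sample using the fitted model.

    The test sample must have exactly the missing-frame pattern the model was
    fitted with; observed rows pass through unchanged and the output mask is
    all-ones.
    """
    if test.n_frames != model.n_frames:
        raise ValueError("test frame count does not match the fitted model")
    missing_rows = np.flatnonzero((test.mask == 0).all(axis=1))
    if not np.array_equal(missing_rows, model.missing_frames):
        raise ValueError(
            f"test missing-frame pattern {missing_rows.tolist()} does not match "
            f"the fitted pattern {model.missing_frames.tolist()}"
        )
    width = test.values.shape[1]
    centered = center_with_means(test, model.column_means[:width])
    m1 = centered[model.observed_frames]
    m2 = model.combined_regressor @ m1
    out = test.copy()
    out.values[model.missing_frames] = m2 + model.column_means[:width]
    out.mask = np.ones_like(out.mask)
    return out
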