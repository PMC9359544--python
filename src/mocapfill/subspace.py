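"""De-meaning, truncated eigenbases, and the per-gap eigenspace mapping.

The regression family works in the principal-component space of the stacked
training matrix: with centered samples stacked as ``A = (A_1^T, ..., A_K^T)^T``,
the marker-space eigenbasis ``U`` holds the top-``k`` right singular vectors of
``A`` (equivalently, eigenvectors of ``A^T A``).  A gapped stack has its own
basis ``U~``, and a small ``k x k`` mapping ``T`` aligns projections onto the
gapped subspace with projections onto the full one:  ``A_i U  ~=  A~_i U~ T``.

Eigenvectors are computed via thin SVD of the data matrix rather than by
forming the covariance — mathematically the same right-singular-vector result,
numerically more stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motion_io import MotionSample

__all__ = ["EigenBasis", "KRule", "demean", "center_with_means", "pca_subspace", "eigen_mapping"]

log = logging.getLogger(__name__)


@dataclass
class EigenBasis:
    """Orthonormal basis of a principal subspace.

    ``basis`` is ``d x k`` with orthonormal columns; ``eigenvalues`` are the
    corresponding squared singular values of the data matrix, non-increasing.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.basis.shape[1]


@dataclass
class KRule:
    """Rule for choosing the retained dimension ``k``.

    ``mode='variance'`` keeps the smallest ``k`` whose cumulative eigenvalue
    fraction reaches ``value`` (default 0.95); ``mode='fixed'`` keeps exactly
    ``value`` components.  Either way ``k`` is capped at the number of singular
    vectors the matrix affords, ``min(rows, cols)``.
    """

    mode: str = "variance"
    value: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("variance", "fixed"):
            raise ValueError(f"unknown k rule mode {self.mode!r}")
        if self.mode == "variance" and not 0 < self.value <= 1:
            raise ValueError("variance fraction must lie in (0, 1]")
        if self.mode == "fixed" and (self.value < 1 or self.value != int(self.value)):
            raise ValueError("fixed k must be a positive integer")

    @classmethod
    def fixed(cls, k: int) -> "KRule":
        return cls(mode="fixed", value=int(k))

    @classmethod
    def variance(cls, fraction: float = 0.95) -> "KRule":
        return cls(mode="variance", value=fraction)

    def choose_k(self, eigenvalues: np.ndarray) -> int:
        n_avail = len(eigenvalues)
        if self.mode == "fixed":
            k = int(self.value)
            if k > n_avail:
                log.warning("requested k=%d exceeds available dimension %d; reduced", k, n_avail)
                k = n_avail
            return k
        total = eigenvalues.sum()
        if total <= 0:
            return 1
        frac = np.cumsum(eigenvalues) / total
        return int(np.searchsorted(frac, self.value - 1e-12) + 1)


def demean(samples: list[MotionSample]) -> tuple[list[np.ndarray], np.ndarray]:
    """Center samples by pooled per-column means over observed entries.

    The mean of each coordinate column is computed over mask=1 entries pooled
    across all samples, and subtracted at observed entries; masked entries are
    set to 0, i.e. they sit exactly at the pooled mean.

    Returns the list of centered matrices and the 3n mean vector.

    Raises
    ------
    ValueError
        If some column has no observed entry anywhere — its mean is undefined
        and the caller must supply a training mean via
        :func:`center_with_means`.
    """
    if not samples:
        raise ValueError("need at least one sample")
    sums = np.zeros(samples[0].values.shape[1])
    counts = np.zeros_like(sums)
    for s in samples:
        sums += (s.values * s.mask).sum(axis=0)
        counts += s.mask.sum(axis=0)
    if (counts == 0).any():
        bad = np.flatnonzero(counts == 0)
        raise ValueError(
            f"columns {bad.tolist()} have no observed entries; "
            "supply training means via center_with_means"
        )
    means = sums / counts
    centered = [center_with_means(s, means) for s in samples]
    return centered, means


def center_with_means(sample: MotionSample, means: np.ndarray) -> np.ndarray:
    """Subtract given column means at observed entries; masked entries -> 0.

    Test samples are centered with the *training* means so that missing
    columns remain consistently placed at the training mean.
    """
    return np.where(sample.mask == 1, sample.values - means, 0.0)


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|.| entry of each column is
    made positive (ties broken by lowest row index, which is what argmax on
    the absolute values returns)."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def pca_subspace(stacked: np.ndarray, k_rule: KRule | int = KRule()) -> EigenBasis:
    """Top-``k`` right-singular-vector basis of a centered stacked matrix.

    ``eigenvalues`` are squared singular values of ``stacked`` (= eigenvalues
    of ``stacked^T stacked``).  ``k`` beyond the numerical rank is allowed —
    trailing columns then span an (orthonormal) null-space complement with
    ~zero eigenvalue — but ``k`` is capped at ``min(stacked.shape)``.
    """
    stacked = np.asarray(stacked, dtype=float)
    if stacked.size == 0:
        raise ValueError("empty matrix")
    if isinstance(k_rule, (int, np.integer)):
        k_rule = KRule.fixed(int(k_rule))
    _, s, vt = np.linalg.svd(stacked, full_matrices=False)
    eig = s**2
    k = k_rule.choose_k(eig)
    return EigenBasis(basis=_fix_signs(vt[:k].T), eigenvalues=eig[:k])


def eigen_mapping(
    full_samples: list[np.ndarray],
    full_basis: EigenBasis,
    gapped_samples: list[np.ndarray],
    gapped_basis: EigenBasis,
) -> np.ndarray:
    """Closed-form ``k x k`` mapping ``T`` between gapped and full projections.

    Minimizes  ``sum_i || A_i U - A~_i U~ T ||_F^2``  over ``T`` via the
    stacked least-squares problem; when the stacked design is
    rank-deficient, the minimum-norm (pseudo-inverse) solution is returned.
    """
    if full_basis.k != gapped_basis.k:
        raise ValueError(f"basis dimensions differ: {full_basis.k} != {gapped_basis.k}")
    if len(full_samples) != len(gapped_samples):
        raise ValueError("sample lists must have equal length")
    X = np.vstack([a @ gapped_basis.basis for a in gapped_samples])
    Y = np.vstack([a @ full_basis.basis for a in full_samples])
    T, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return T
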