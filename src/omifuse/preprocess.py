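"""Per-layer feature extraction: min-max rescaling and kernel PCA.

Each omics layer is first rescaled feature-wise to [0, 1] so that layers
measured on different scales (RSEM abundances vs. methylation levels) become
comparable.  Kernel PCA with the cubic polynomial kernel

    K(x_i, x_j) = (x_i' x_j + 1)^3

then maps samples into the feature space implied by the kernel and keeps every
component with a non-negligible eigenvalue, reducing tens of thousands of
features to at most n_samples score dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.metrics.pairwise import linear_kernel as _sk_linear
from sklearn.metrics.pairwise import polynomial_kernel as _sk_poly

from .omics_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureScores",
    "KernelGram",
    "minmax_normalize",
    "polynomial_kernel",
    "linear_kernel",
    "center_kernel",
    "kpca_fit_transform",
]


@dataclass
class KernelGram:
    """Sample-by-sample Gram matrix of kernel inner products."""

    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Gram matrix must be square")
        asym = np.max(np.abs(self.values - self.values.T))
        if asym > 1e-8 * max(1.0, np.max(np.abs(self.values))):
            raise ValueError(f"Gram matrix not symmetric (max asymmetry {asym:.3g})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureScores:
    """Kernel-PCA sample scores: eigenvector columns scaled by sqrt(eigenvalue)."""

    scores: np.ndarray
    sample_ids: list[str]
    eigenvalues: np.ndarray
    layer: str = "gene"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.shape[0] != len(self.sample_ids):
            raise ValueError("score rows must match sample_ids")
        if self.scores.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("one eigenvalue per score column required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def minmax_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each feature to [0, 1]: x' = (x - min) / (max - min).

    The extrema are taken per feature across samples.  Constant features map
    to all-zeros (logged) rather than being dropped, keeping feature indices
    stable across layers.
    """
    if m.values.size == 0:
        raise ValueError("cannot normalize an empty expression matrix")
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.warning(
            "%d constant feature(s) mapped to 0 during min-max normalization",
            int(const.sum()),
        )
    span = np.where(const, 1.0, span)
    out = (m.values - lo) / span
    out[:, const] = 0.0
    return ExpressionMatrix(out, m.sample_ids, m.feature_ids, m.layer)


def polynomial_kernel(
    a: np.ndarray, b: np.ndarray | None = None, degree: int = 3, gamma: float = 1.0
) -> KernelGram:
    """Cubic polynomial Gram matrix K(x, y) = (gamma * x'y + 1)^degree.

    The default (gamma=1, degree=3) is the coefficient-free cubic kernel; a
    slope-scaled variant is available through ``gamma`` but is not default.
    """
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}"
        )
    return KernelGram(_sk_poly(a, b, degree=degree, gamma=gamma, coef0=1.0))


def linear_kernel(a: np.ndarray, b: np.ndarray | None = None) -> KernelGram:
    """Plain inner-product Gram matrix (test hook: reduces KPCA to PCA)."""
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}"
        )
    return KernelGram(_sk_linear(a, b))


def center_kernel(k: KernelGram) -> KernelGram:
    """Center the Gram matrix in feature space:

    K' = K - 1_n K - K 1_n + 1_n K 1_n,  with 1_n the n x n matrix of 1/n.
    """
    K = k.values
    n = K.shape[0]
    col_mean = K.mean(axis=0, keepdims=True)
    row_mean = K.mean(axis=1, keepdims=True)
    total = K.mean()
    Kc = K - col_mean - row_mean + total
    Kc = (Kc + Kc.T) / 2.0  # enforce exact symmetry against roundoff
    return KernelGram(Kc, centered=True)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (reproducible)."""
    idx = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def kpca_fit_transform(
    m: ExpressionMatrix,
    eigval_tol_ratio: float = 1e-10,
    kernel: str = "poly",
    degree: int = 3,
    gamma: float = 1.0,
    center: bool = True,
) -> FeatureScores:
    """Kernel PCA of a (min-max normalized) expression matrix.

    Builds the sample Gram matrix, centers it in feature space, and
    eigendecomposes.  Every eigenvalue above ``eigval_tol_ratio`` times the
    largest is kept — the operational reading of preserving all non-zero
    components.  Scores are eigenvector columns scaled by sqrt(eigenvalue), so
    pairwise score distances reproduce centered-kernel-induced distances.

    ``kernel='linear'`` is a test hook under which the scores equal classical
    PCA scores up to per-component sign.  ``center=False`` skips feature-space
    centering for strict-literal replication.
    """
    if m.n_samples < 2:
        raise ValueError("kernel PCA needs at least 2 samples")
    if kernel == "poly":
        gram = polynomial_kernel(m.values, degree=degree, gamma=gamma)
    elif kernel == "linear":
        gram = linear_kernel(m.values)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    if center:
        gram = center_kernel(gram)
    evals, evecs = scipy.linalg.eigh(gram.values)
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending
    lam_max = evals[0]
    if lam_max <= 0:
        raise ValueError("degenerate input: no positive kernel eigenvalues")
    keep = evals > eigval_tol_ratio * lam_max
    if not keep.any():
        raise ValueError("degenerate input: all eigenvalues below tolerance")
    evals, evecs = evals[keep], _fix_signs(evecs[:, keep])
    scores = evecs * np.sqrt(evals)
    return FeatureScores(scores, list(m.sample_ids), evals, m.layer)
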