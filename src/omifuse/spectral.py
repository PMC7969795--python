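"""Normalized-Laplacian spectral clustering of a fused similarity kernel.

Given the fused kernel K with degree matrix D (row sums of K), the symmetric
normalized Laplacian L_sym = D^{-1/2} (D - K) D^{-1/2} is eigendecomposed; the
eigenvectors of its k smallest eigenvalues, row-normalized to unit length,
embed the samples, and k-means on the embedding yields the subtype partition.
The number of clusters can be chosen by scanning k and picking the partition
with the lowest survival-separation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from .kernels import SimilarityKernel
from .omics_io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "LaplacianPair",
    "ClusterAssignment",
    "normalized_laplacian",
    "spectral_embed",
    "spectral_cluster",
    "select_k",
]


@dataclass
class LaplacianPair:
    """Symmetric normalized Laplacian together with the kernel's degree vector."""

    laplacian: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        self.laplacian = np.asarray(self.laplacian, dtype=float)
        self.degree = np.asarray(self.degree, dtype=float)
        if np.max(np.abs(self.laplacian - self.laplacian.T)) > 1e-10:
            raise ValueError("Laplacian must be symmetric")
        if np.any(self.degree <= 0):
            raise ValueError("degrees must be positive")


@dataclass
class ClusterAssignment:
    """Subtype labels 1..k plus the spectral embedding they were derived from."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int
    embedding: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("one label per sample required")
        present = set(self.labels.tolist())
        if not present.issubset(set(range(1, self.k + 1))):
            raise ValueError(f"labels must lie in 1..{self.k}")
        if len(present) != self.k:
            raise ValueError("every cluster 1..k must be non-empty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})


def normalized_laplacian(k: SimilarityKernel) -> LaplacianPair:
    """L_sym = D^{-1/2} (D - K) D^{-1/2}; D = diag of row sums of K."""
    K = k.values
    deg = K.sum(axis=1)
    if np.any(deg <= 0):
        bad = [k.sample_ids[i] for i in np.nonzero(deg <= 0)[0]]
        raise ValueError(f"zero-degree (isolated) sample(s): {bad}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.diag(deg) - K
    L_sym = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    L_sym = (L_sym + L_sym.T) / 2.0
    return LaplacianPair(L_sym, deg)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def spectral_embed(
    k: SimilarityKernel, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized eigenvector embedding Y of the n_clusters smallest
    eigenvalues of L_sym.  Returns (Y, eigenvalues ascending)."""
    n = k.n_samples
    if not 2 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [2, {n}], got {n_clusters}")
    pair = normalized_laplacian(k)
    evals, evecs = scipy.linalg.eigh(
        pair.laplacian, subset_by_index=[0, n_clusters - 1]
    )
    evecs = _fix_signs(evecs)
    norms = np.linalg.norm(evecs, axis=1)
    zero = norms < 1e-300
    if zero.any():
        logger.warning(
            "%d zero-norm embedding row(s) left unnormalized", int(zero.sum())
        )
    Y = evecs / np.where(zero, 1.0, norms)[:, None]
    return Y, evals


def _canonical_relabel(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first occurrence (stable identity)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def spectral_cluster(
    k: SimilarityKernel,
    n_clusters: int,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterAssignment:
    """Partition the spectral embedding with k-means (k-means++ init,
    ``n_restarts`` restarts, best inertia wins), then relabel canonically."""
    if n_clusters == 1:
        Y = np.ones((k.n_samples, 1))
        return ClusterAssignment(
            list(k.sample_ids), np.ones(k.n_samples, dtype=int), 1, Y
        )
    Y, _ = spectral_embed(k, n_clusters)
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=n_restarts,
        random_state=int(seed) % (2**31),
    ).fit(Y)
    raw = km.labels_
    if len(set(raw.tolist())) < n_clusters:
        raise ValueError(f"k-means produced an empty cluster at k={n_clusters}")
    labels = _canonical_relabel(raw)
    return ClusterAssignment(list(k.sample_ids), labels, n_clusters, Y)


def select_k(
    k: SimilarityKernel,
    clinical: ClinicalTable,
    k_range: range | list[int],
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Scan cluster counts and pick the one whose partition best separates
    survival (lowest log-rank p-value); ties break toward smaller k.

    Returns (best_k, scan table with columns k, p_value, chosen).
    """
    from .evaluate import logrank_test  # local import avoids a cycle

    ks = sorted(set(int(x) for x in k_range))
    if not ks:
        raise ValueError("empty k range")
    n = k.n_samples
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    rows = []
    best_k, best_p = None, np.inf
    for kk in ks:
        assignment = spectral_cluster(k, kk, seed=seed, n_restarts=n_restarts)
        res = logrank_test(clinical, assignment)
        rows.append({"k": kk, "p_value": res.p_value})
        if res.p_value < best_p:  # strict: ties stay with the smaller k
            best_k, best_p = kk, res.p_value
    table = pd.DataFrame(rows)
    table["chosen"] = table["k"] == best_k
    return int(best_k), table
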