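"""Gaussian similarity kernels over KPCA scores, and average kernel fusion.

Each omics layer contributes one N x N patient-similarity matrix

    K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2)

computed on that layer's kernel-PCA scores.  Layer kernels are fused by an
entrywise (weighted) mean into one global similarity matrix — the convex
combination of positive semidefinite matrices stays positive semidefinite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import euclidean_distances

from .preprocess import FeatureScores

__all__ = [
    "SimilarityKernel",
    "gaussian_kernel",
    "median_heuristic_gamma",
    "fuse_kernels",
    "write_kernel",
    "read_kernel",
]


@dataclass
class SimilarityKernel:
    """Symmetric PSD patient-similarity matrix with unit diagonal."""

    values: np.ndarray
    sample_ids: list[str]
    gamma: float | None = None
    source: str = "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} sample ids"
            )
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("similarity kernel must be symmetric")
        if np.max(np.abs(np.diag(self.values) - 1.0)) > 1e-10:
            raise ValueError("similarity kernel must have unit diagonal")
        # Gaussian kernels are strictly positive; exact zeros are allowed so
        # hand-built disconnected block kernels remain representable.
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def median_heuristic_gamma(scores: np.ndarray) -> float:
    """gamma = 1 / median of the nonzero pairwise squared distances.

    A per-layer bandwidth choice that adapts to each layer's score scale.
    """
    d2 = euclidean_distances(scores, squared=True)
    iu = np.triu_indices_from(d2, k=1)
    vals = d2[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("all pairwise distances are zero; cannot set gamma")
    return float(1.0 / np.median(vals))


def gaussian_kernel(
    s: FeatureScores, gamma: float | str = "median"
) -> SimilarityKernel:
    """Gaussian similarity kernel exp(-gamma * ||x_i - x_j||^2) over scores.

    ``gamma='median'`` (default) uses the median heuristic; a fixed positive
    value may be given instead.  The gamma actually used is recorded on the
    result.
    """
    if s.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if gamma == "median":
        g = median_heuristic_gamma(s.scores)
    else:
        g = float(gamma)
        if g <= 0:
            raise ValueError(f"gamma must be positive, got {g}")
    d2 = euclidean_distances(s.scores, squared=True)
    K = np.exp(-g * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return SimilarityKernel(K, list(s.sample_ids), gamma=g, source=s.layer)


def fuse_kernels(
    ks: Sequence[SimilarityKernel], weights: Sequence[float] | None = None
) -> SimilarityKernel:
    """Entrywise weighted mean of similarity kernels (default: flat average).

    All kernels must share an identical sample order; no silent realignment.
    """
    if not ks:
        raise ValueError("need at least one kernel to fuse")
    ids = ks[0].sample_ids
    for k in ks[1:]:
        if k.sample_ids != ids:
            raise ValueError("kernels have mismatched sample orders")
    if weights is None:
        w = np.full(len(ks), 1.0 / len(ks))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(ks),) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per kernel")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
    fused = sum(wi * k.values for wi, k in zip(w, ks))
    return SimilarityKernel(fused, list(ids), gamma=None, source="fused")


def write_kernel(k: SimilarityKernel, path: str | Path) -> None:
    """TSV with sample_id header row/column; gamma and provenance to a JSON sidecar."""
    df = pd.DataFrame(k.values, index=k.sample_ids, columns=k.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")
    meta = {"gamma": k.gamma, "source": k.source, "n_samples": k.n_samples}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_kernel(path: str | Path) -> SimilarityKernel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(str(path) + ".json")
    gamma, source = None, "fused"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        gamma, source = meta.get("gamma"), meta.get("source", "fused")
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityKernel(vals, [str(i) for i in df.index], gamma=gamma, source=source)
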