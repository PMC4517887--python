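"""Laplacian Exponential Diffusion kernel on the global network.

The similarity between two nodes is the amount of heat found in one node at
time alpha when a unit quantity starts diffusing from the other at time zero:
``K = exp(-alpha * L)`` with ``L = D - A`` the (unweighted) graph Laplacian.
Because ``exp(-alpha L)`` preserves the constant vector, the unnormalized
kernel is doubly stochastic: symmetric, entrywise nonnegative, rows summing
to 1.  A cosine normalization ``K_N(i,j) = k_ij / sqrt(k_ii * k_jj)`` scales
self-similarity to 1 before sample × gene submatrices are extracted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .network import DATASET_GENE, NET, SAMPLE, GlobalNetwork, NodeRegistry

__all__ = [
    "KernelMatrix",
    "SimilaritySubmatrix",
    "laplacian",
    "led_kernel",
    "normalize_kernel",
    "extract_submatrix",
    "compute_similarities",
    "kernel_cache_key",
]

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
ROWSUM_TOL = 1e-8
DIAG_TOL = 1e-10
NEG_CLAMP = 1e-12


@dataclass
class KernelMatrix:
    """Diffusion-kernel similarity matrix over the global-network nodes."""

    values: np.ndarray
    alpha: float
    registry: NodeRegistry | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel must be a square matrix")
        if np.abs(v - v.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("kernel must be symmetric")
        if self.registry is not None and len(self.registry) != v.shape[0]:
            raise ValueError("kernel size does not match registry")
        self.values = v


@dataclass
class SimilaritySubmatrix:
    """Samples × genes-of-one-datatype block of the normalized kernel."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    datatype: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("submatrix shape does not match id lists")

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def laplacian(g: GlobalNetwork | np.ndarray | sp.spmatrix) -> np.ndarray:
    """Dense graph Laplacian L = D - A of the (global) network adjacency."""
    if isinstance(g, GlobalNetwork):
        a = g.to_dense()
    elif sp.issparse(g):
        a = g.toarray().astype(float)
    else:
        a = np.asarray(g, dtype=float)
    return np.diag(a.sum(axis=1)) - a


def led_kernel(
    L: np.ndarray,
    alpha: float,
    registry: NodeRegistry | None = None,
    method: str = "expm",
) -> KernelMatrix:
    """Laplacian Exponential Diffusion kernel exp(-alpha * L).

    ``method='expm'`` uses scaling-and-squaring; ``method='eig'`` uses the
    symmetric eigendecomposition (the two agree to high precision and the
    eig route doubles as an independent cross-check).  Tiny negative entries
    from floating point (magnitude < 1e-12) are clamped to zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    L = np.asarray(L, dtype=float)
    if np.abs(L - L.T).max(initial=0.0) > SYMMETRY_TOL:
        raise ValueError("Laplacian must be symmetric")
    if method == "expm":
        k = sla.expm(-alpha * L)
    elif method == "eig":
        w, v = sla.eigh(L)
        k = (v * np.exp(-alpha * w)) @ v.T
    else:
        raise ValueError(f"unknown method {method!r}")
    k = (k + k.T) / 2.0  # enforce exact symmetry
    neg = (k < 0) & (k > -NEG_CLAMP)
    if neg.any():
        log.debug("led_kernel: clamped %d tiny negative entries", int(neg.sum()))
        k[neg] = 0.0
    return KernelMatrix(k, alpha, registry, normalized=False)


def normalize_kernel(k: KernelMatrix) -> KernelMatrix:
    """Cosine normalization k_ij / sqrt(k_ii k_jj); diagonal becomes exactly 1."""
    if k.normalized:
        raise ValueError("kernel is already normalized")
    d = np.diag(k.values)
    if (d <= 0).any():
        raise ValueError("kernel diagonal must be positive for normalization")
    s = 1.0 / np.sqrt(d)
    v = k.values * np.outer(s, s)
    np.fill_diagonal(v, 1.0)
    v = (v + v.T) / 2.0
    return KernelMatrix(v, k.alpha, k.registry, normalized=True)


def extract_submatrix(k: KernelMatrix, datatype: str) -> SimilaritySubmatrix:
    """Sample-rows × gene-columns block of the normalized kernel for one datatype.

    For an expression dataset merged into the prior network, the columns are
    the NET nodes whose identifiers occur in the expression dataset.
    """
    if k.registry is None:
        raise ValueError("kernel has no registry; cannot extract submatrices")
    if not k.normalized:
        raise ValueError("extract_submatrix expects a normalized kernel")
    reg = k.registry
    srows = reg.indices(SAMPLE)
    if not srows:
        raise ValueError("registry contains no sample nodes")
    if datatype == "expression" and reg.merged_expression_genes is not None:
        gene_ids = list(reg.merged_expression_genes)
        gcols = [reg.index_of(NET, None, g) for g in gene_ids]
    else:
        gcols = reg.indices(DATASET_GENE, datatype)
        gene_ids = [reg.identifiers[i] for i in gcols]
        if not gcols:
            raise ValueError(f"no gene nodes for datatype {datatype!r}")
    block = k.values[np.ix_(srows, gcols)]
    return SimilaritySubmatrix(block, reg.sample_ids, gene_ids, datatype)


def compute_similarities(
    g: GlobalNetwork,
    alpha: float = 0.01,
    method: str = "expm",
    datatypes: list[str] | None = None,
) -> dict[str, SimilaritySubmatrix]:
    """Full pipeline: Laplacian → LED kernel → normalization → submatrices."""
    kn = normalize_kernel(led_kernel(laplacian(g), alpha, g.registry, method=method))
    if datatypes is None:
        datatypes = sorted({d for d in g.registry.datatypes if d is not None})
        if g.registry.merged_expression_genes is not None:
            datatypes = ["expression"] + [d for d in datatypes if d != "expression"]
    return {d: extract_submatrix(kn, d) for d in datatypes}


def kernel_cache_key(g: GlobalNetwork, alpha: float) -> str:
    """Content hash of (adjacency, alpha) for kernel caching across runs."""
    a = g.adjacency.tocoo()
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(a.row, dtype=np.int64).tobytes())
    h.update(np.ascontiguousarray(a.col, dtype=np.int64).tobytes())
    h.update(np.float64(alpha).tobytes())
    h.update(np.int64(g.n_nodes).tobytes())
    return h.hexdigest()


def cached_kernel(
    g: GlobalNetwork, alpha: float, cache_dir: str | Path | None, method: str = "expm"
) -> KernelMatrix:
    """Normalized kernel, persisted under ``cache_dir`` keyed by content hash."""
    if cache_dir is None:
        return normalize_kernel(led_kernel(laplacian(g), alpha, g.registry, method=method))
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"kernel-{kernel_cache_key(g, alpha)}.npy"
    if path.exists():
        values = np.load(path)
        return KernelMatrix(values, alpha, g.registry, normalized=True)
    kn = normalize_kernel(led_kernel(laplacian(g), alpha, g.registry, method=method))
    np.save(path, kn.values)
    return kn
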