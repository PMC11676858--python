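"""Laplacian heat-kernel diffusion and gene rescoring.

This is the mathematical core of the package.  For an undirected gene
network with adjacency matrix ``A`` and degree matrix ``D``, the combinatorial
graph Laplacian is ``L = D - A``.  The diffusion kernel is the matrix
exponential

    W = exp(-alpha * L)

with decay factor ``alpha`` (default 0.1).  W is symmetric, entrywise
nonnegative and doubly stochastic (every row/column sums to 1, since
``L @ 1 = 0``).  Seeding the network with a biological-relevance vector S
(log2 fold changes on signature genes, 0 elsewhere) and computing

    P = W @ S,   P_g = sum_k w_gk * S_k

rescores every gene by its diffusion-weighted connectivity to the input
signature.  Because rows of W sum to 1 and W is symmetric, total input mass
is conserved: sum(P) == sum(S).

W is computed per connected component via symmetric eigendecomposition
(``W_c = Q exp(-alpha Lambda) Q^T`` on each component block), which both
exploits symmetry and makes cross-component kernel entries exactly zero —
diffusion never leaks between disconnected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .errors import OrderMismatchError
from .netio import GeneNetwork
from .sig import RelevanceVector

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1
DEFAULT_TOP_N = 200

#: negative kernel entries larger in magnitude than this are a numerical bug,
#: not round-off, and are left in place to fail validation downstream
_CLIP_TOL = 1e-10


@dataclass(frozen=True)
class LaplacianMatrix:
    """Combinatorial Laplacian L = D - A in canonical node order."""

    matrix: np.ndarray
    nodes: tuple[str, ...]


@dataclass(frozen=True)
class DiffusionKernel:
    """Heat kernel W = exp(-alpha L) with its decay factor and node order."""

    matrix: np.ndarray
    alpha: float
    nodes: tuple[str, ...]


@dataclass(frozen=True)
class DiffusionResult:
    """Per-gene diffusion scores in canonical node order.

    ``frame`` columns: gene, score (P), rank (1 = highest, ties broken
    lexicographically by symbol), in_signature, and — after
    :func:`scale_scores` — scaled_score.
    """

    frame: pd.DataFrame
    alpha: float
    nodes: tuple[str, ...]


def laplacian(network: GeneNetwork) -> LaplacianMatrix:
    """L = D - A: degrees on the diagonal, -1 for adjacent pairs, 0 otherwise."""
    a = network.adjacency
    lap = np.diag(a.sum(axis=1)) - a
    return LaplacianMatrix(lap, network.nodes)


def heat_kernel(lap: LaplacianMatrix, alpha: float = DEFAULT_ALPHA) -> DiffusionKernel:
    """Compute W = exp(-alpha L) by per-component symmetric eigendecomposition.

    Requires a symmetric L (the kernel is defined only for undirected
    networks) and alpha >= 0.  alpha == 0 returns the exact identity.
    Entries within ``1e-10`` below zero are clipped to 0; anything more
    negative would indicate a defect and is deliberately left alone.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    m = lap.matrix
    if not np.array_equal(m, m.T):
        raise ValueError(
            "Laplacian is asymmetric: the heat kernel is defined only for "
            "undirected networks (directed graphs give an asymmetric L)"
        )
    n = m.shape[0]
    if alpha == 0:
        return DiffusionKernel(np.eye(n), 0.0, lap.nodes)

    # connected components from the off-diagonal sparsity pattern of L
    adj = scipy.sparse.csr_matrix((np.abs(m) > 0) & ~np.eye(n, dtype=bool))
    n_comp, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)

    w = np.zeros_like(m, dtype=float)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        block = m[np.ix_(idx, idx)]
        if len(idx) == 1:
            w[idx[0], idx[0]] = 1.0  # singleton: L block is 0, exp(0) = 1
            continue
        evals, evecs = scipy.linalg.eigh(block)
        wb = (evecs * np.exp(-alpha * evals)) @ evecs.T
        wb[(wb < 0) & (wb > -_CLIP_TOL)] = 0.0
        w[np.ix_(idx, idx)] = wb
    return DiffusionKernel(w, float(alpha), lap.nodes)


def diffuse(kernel: DiffusionKernel, relevance: RelevanceVector) -> DiffusionResult:
    """P = W @ S with ranks descending by score, ties broken by gene symbol.

    The relevance vector must carry the kernel's exact node order; a mismatch
    is a hard error — scores are never silently reindexed.
    """
    if kernel.nodes != relevance.nodes:
        raise OrderMismatchError(
            "kernel and relevance vector disagree on node order; rebuild the "
            "relevance vector against this network"
        )
    p = kernel.matrix @ relevance.scores
    genes = np.asarray(kernel.nodes)
    order = np.lexsort((genes, -p))
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    frame = pd.DataFrame(
        {
            "gene": genes,
            "score": p,
            "rank": ranks,
            "in_signature": relevance.scores > 0,
        }
    )
    return DiffusionResult(frame, kernel.alpha, kernel.nodes)


def scale_scores(result: DiffusionResult, method: str = "zscore") -> DiffusionResult:
    """Attach scaled diffusion scores.

    ``zscore`` (default) standardises to mean 0, population sd 1; ``minmax``
    maps onto [0, 1].  Both are affine monotone, so ranks are unchanged.
    A constant score vector yields all-zero scaled scores with a warning.
    """
    p = result.frame["score"].to_numpy()
    if method == "zscore":
        sd = p.std(ddof=0)
        if sd == 0:
            logger.warning("diffusion scores have zero variance; scaled scores set to 0")
            scaled = np.zeros_like(p)
        else:
            scaled = (p - p.mean()) / sd
    elif method == "minmax":
        span = p.max() - p.min()
        if span == 0:
            logger.warning("diffusion scores have zero range; scaled scores set to 0")
            scaled = np.zeros_like(p)
        else:
            scaled = (p - p.min()) / span
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    frame = result.frame.copy()
    frame["scaled_score"] = scaled
    return replace(result, frame=frame)


def top_n(result: DiffusionResult, n: int = DEFAULT_TOP_N) -> pd.DataFrame:
    """First ``n`` genes by rank.

    Input-signature genes remain eligible (they visibly persist at the top of
    real propagation results); the in_signature flag is carried along so a
    caller can separate them.
    """
    if n > len(result.nodes):
        raise ValueError(f"n={n} exceeds network size {len(result.nodes)}")
    return (
        result.frame.sort_values("rank").head(n).reset_index(drop=True)
    )
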