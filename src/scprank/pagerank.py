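"""Power-iteration PageRank solvers: the modified MPR and the classic variant.

The modified PageRank walks the co-localization-weighted PPI network and
teleports according to the IPSC prior.  Its iteration matrix is

    M = alpha * M1 + (1 - alpha) * M2

where ``M1[i, j] = w(i, j) / sum_k w(i, k)`` for j a neighbour of i (the
hyperlink part, normalized over the neighbours of i) and ``M2``'s action is
rank-one: ``(M2 v)_i = r_i * sum(v)`` with ``r`` the IPSC vector normalized to
sum 1.  Each step renormalizes the iterate, so the fixed point is the
dominant eigenvector of M regardless of which side is stochastic.  The
``orientation`` switch transposes the hyperlink part to the classic
random-walk convention (normalize over the neighbours of j).

The classic solver is a separate, deliberately simple implementation
(unweighted edges, uniform 1/N reset) kept as a baseline and cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import scipy.sparse as sp

from .datatypes import PPINetwork, RankVector, ScoreVector

__all__ = ["TransitionModel", "build_transition_model", "mpr",
           "classic_pagerank", "dense_transition_matrix"]


@dataclass
class TransitionModel:
    """Sparse hyperlink matrix plus rank-one reset, over an explicit node order."""

    nodes: List[str]
    hyperlink: sp.csr_matrix  # rows already normalized per the orientation
    reset: np.ndarray         # r, non-negative, sums to 1
    alpha: float
    orientation: str = "row"


def build_transition_model(network: PPINetwork, ipsc: ScoreVector,
                           alpha: float = 0.85, orientation: str = "row",
                           uniform_reset: bool = False) -> TransitionModel:
    """Assemble the iteration operator from a weighted network and IPSC prior.

    ``orientation="row"`` normalizes each hyperlink entry by the weighted
    degree of its own row's protein; ``"column"`` by the neighbour's weighted
    degree (the classic random-walk convention).  ``uniform_reset=True``
    replaces the IPSC reset by 1/N — required when every IPSC is zero.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if orientation not in ("row", "column"):
        raise ValueError(f"orientation must be 'row' or 'column', got {orientation!r}")
    nodes = sorted(network.graph.nodes)
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")

    rows, cols, vals = [], [], []
    strength = np.zeros(n)
    for u, v, d in network.graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        if not w > 0:
            raise ValueError(f"non-positive weight on edge ({u}, {v})")
        i, j = index[u], index[v]
        strength[i] += w
        strength[j] += w
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    vals = np.asarray(vals, dtype=float)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if vals.size:
        denom_idx = rows if orientation == "row" else cols
        vals = vals / strength[denom_idx]
    hyperlink = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    if uniform_reset:
        reset = np.full(n, 1.0 / n)
    else:
        r = np.array([float(ipsc.scores.get(p, 0.0)) for p in nodes])
        if np.any(r < 0):
            raise ValueError("IPSC values must be non-negative")
        total = r.sum()
        if total <= 0:
            raise ValueError("all IPSC values are zero; pass uniform_reset=True "
                             "to fall back to a uniform teleport distribution")
        reset = r / total
    return TransitionModel(nodes, hyperlink, reset, alpha, orientation)


def mpr(model: TransitionModel, tol: float = 1e-10, max_iter: int = 1000,
        init: str = "uniform", norm: str = "l1") -> RankVector:
    """Run the normalized power iteration to its dominant eigenvector.

    Iterates ``v <- alpha * M1 v + (1 - alpha) * r * sum(v)`` followed by
    ``v <- v / ||v||`` until the L1 distance between successive normalized
    iterates drops below ``tol``.  Deterministic for fixed inputs.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if norm not in ("l1", "l2"):
        raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")
    n = len(model.nodes)
    if init == "uniform":
        v = np.full(n, 1.0 / n)
    elif init == "reset":
        v = model.reset.copy()
        if v.sum() <= 0:
            raise ValueError("reset vector is degenerate; cannot init from it")
        v = v / v.sum()
    else:
        raise ValueError(f"init must be 'uniform' or 'reset', got {init!r}")

    alpha = model.alpha
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        new = alpha * (model.hyperlink @ v) + (1.0 - alpha) * model.reset * v.sum()
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("non-finite values in power iteration; "
                                     "check edge weights")
        denom = np.abs(new).sum() if norm == "l1" else np.linalg.norm(new)
        if denom == 0:
            raise FloatingPointError("iterate collapsed to zero")
        new /= denom
        residual = float(np.abs(new - v).sum())
        v = new
        if residual < tol:
            converged = True
            break
    scores = {p: float(s) for p, s in zip(model.nodes, v)}
    return RankVector(scores, name="MPR", iterations_used=it,
                      converged=converged, residual=residual)


def classic_pagerank(network: PPINetwork, alpha: float = 0.85,
                     tol: float = 1e-10, max_iter: int = 1000,
                     orientation: str = "column") -> RankVector:
    """Classic PageRank: unit edge weights and a uniform 1/N reset.

    Defaults to the column (random-walk) convention — each entry is the
    reciprocal out-degree of the *source* node — which is the classic
    definition; with the row convention and a uniform reset the uniform
    vector is a fixed point, so every connected graph would score flat.
    Independent of :func:`mpr`'s code path on purpose — a dense iteration over
    the plain adjacency matrix — so the two can cross-validate each other.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    import networkx as nx

    adj = nx.to_numpy_array(network.graph, nodelist=nodes, weight=None)
    deg = adj.sum(axis=1)
    trans = np.zeros_like(adj)
    nz = deg > 0
    if orientation == "row":
        trans[nz, :] = adj[nz, :] / deg[nz, None]
    else:
        trans[:, nz] = adj[:, nz] / deg[None, nz]
    v = np.full(n, 1.0 / n)
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        new = alpha * trans @ v + (1.0 - alpha) / n * v.sum()
        new /= np.abs(new).sum()
        residual = float(np.abs(new - v).sum())
        v = new
        if residual < tol:
            converged = True
            break
    scores = {p: float(s) for p, s in zip(nodes, v)}
    return RankVector(scores, name="PR", iterations_used=it,
                      converged=converged, residual=residual)


def dense_transition_matrix(model: TransitionModel) -> np.ndarray:
    """Densely assembled M = alpha*M1 + (1-alpha)*M2, mainly for diagnostics."""
    n = len(model.nodes)
    m2 = np.tile(model.reset[:, None], (1, n))
    return model.alpha * model.hyperlink.toarray() + (1.0 - model.alpha) * m2
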