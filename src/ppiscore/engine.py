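"""Line-graph construction and PPI essentiality propagation.

The pathway network is inverted: each protein-protein interaction (PPI,
an edge of the context network) becomes a node of the *dual graph* (the
line graph), and two dual nodes are adjacent iff their PPIs share a
protein. The dual edge through shared protein ``s`` is weighted by the
exponential kernel ``exp(w * p_s)`` of that protein's normalized
essentiality, so essentiality diffuses preferentially through lethal
proteins.

Scores are the stationary point of a smoothed weighted random walk on the
dual graph (a PageRank-style propagation without teleportation):

    e(t+1) = (1 - alpha) * e(t) + alpha * P^T e(t)          (mass mode)

with P the row-stochastic matrix of dual-edge weights. On an undirected
positively-weighted component the walk is reversible, so the stationary
distribution is proportional to node strength; ``closed_form_scores``
computes it directly and serves as the closed form of the iteration.

``update_mode="averaging"`` applies the neighbor-averaging operator
``e(t+1) = (1-alpha) e(t) + alpha * P e(t)`` instead. On a connected dual
graph that operator converges to consensus (all scores equal, dependent on
the start vector); it is provided for completeness, not as the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .pathway_network import ContextNetwork

logger = logging.getLogger(__name__)

PPI = tuple[str, str]


@dataclass
class PropagationConfig:
    """Parameters of the smoothed propagation.

    alpha : smoothing weight in (0, 1]; the update keeps (1 - alpha) of the
        previous score and takes alpha from the neighbors.
    w : kernel coefficient >= 0; dual-edge weight is exp(w * p_shared), so
        w = 0 ignores protein essentiality and larger w trusts it more.
    """

    alpha: float = 0.5
    w: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000
    update_mode: str = "mass"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.w < 0:
            raise ValueError(f"kernel coefficient w must be >= 0, got {self.w}")
        if self.update_mode not in ("mass", "averaging"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")


@dataclass
class DualGraph:
    """Line graph of a context network.

    ``dual_edges`` holds ``(i, j, shared_protein, weight)`` with i, j
    indices into ``dual_nodes``; weight = exp(w * p_shared).
    """

    dual_nodes: list[PPI]
    dual_edges: list[tuple[int, int, str, float]]
    cell_line: str | None = None

    def weight_matrix(self) -> sp.csr_array:
        """Symmetric sparse weight matrix of the dual graph."""
        n = len(self.dual_nodes)
        if not self.dual_edges:
            return sp.csr_array((n, n))
        i, j, _, w = zip(*self.dual_edges)
        i, j, w = np.asarray(i), np.asarray(j), np.asarray(w, dtype=float)
        m = sp.coo_array((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
        return m.tocsr()


@dataclass
class ScoreVector:
    """Converged PPI essentiality scores, normalized so max = 1."""

    scores: dict[PPI, float]
    iterations_used: int
    converged: bool
    cell_line: str | None = None

    def as_array(self, order: list[PPI]) -> np.ndarray:
        return np.array([self.scores[p] for p in order])


def build_dual_graph(net: ContextNetwork, w: float = 0.5) -> DualGraph:
    """Construct the weighted line graph of a context network.

    One dual node per PPI; for every protein of degree d >= 2, all C(d, 2)
    pairs of its incident PPIs become dual-adjacent with weight
    exp(w * p) of that shared protein. In a simple graph two distinct
    edges share at most one endpoint, so duplicate dual edges cannot arise.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("context network has no PPIs to score")
    dual_nodes: list[PPI] = sorted(tuple(sorted(e)) for e in g.edges())
    index = {ppi: k for k, ppi in enumerate(dual_nodes)}
    dual_edges: list[tuple[int, int, str, float]] = []
    for s in sorted(g.nodes()):
        incident = sorted(tuple(sorted((s, nb))) for nb in g.neighbors(s))
        if len(incident) < 2:
            continue
        weight = exp(w * net.node_essentiality[s])
        for a in range(len(incident)):
            ia = index[incident[a]]
            for b in range(a + 1, len(incident)):
                ib = index[incident[b]]
                dual_edges.append((min(ia, ib), max(ia, ib), s, weight))
    return DualGraph(dual_nodes=dual_nodes, dual_edges=dual_edges, cell_line=net.cell_line)


def _row_stochastic(W: sp.csr_array) -> sp.csr_array:
    """P[i, j] = W[i, j] / strength_i; isolated rows get a unit self-loop."""
    strength = np.asarray(W.sum(axis=1)).ravel()
    n = W.shape[0]
    isolated = strength == 0
    inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, strength))
    P = sp.diags_array(inv) @ W
    if isolated.any():
        P = P + sp.diags_array(isolated.astype(float))
    return sp.csr_array(P)


def propagate(
    dg: DualGraph,
    cfg: PropagationConfig | None = None,
    start: np.ndarray | None = None,
) -> ScoreVector:
    """Iterate the smoothed propagation to its stationary scores.

    Mass mode conserves total score per iteration and converges, on each
    connected component, to the component's stationary distribution scaled
    by its share of the initial mass; the result is independent of alpha
    and (per component mass) of the start vector. Scores are normalized by
    the maximum so the most essential PPI scores exactly 1.
    """
    cfg = cfg or PropagationConfig()
    n = len(dg.dual_nodes)
    if n == 0:
        raise ValueError("empty dual graph")
    P = _row_stochastic(dg.weight_matrix())
    if start is None:
        e = np.full(n, 1.0 / n)
    else:
        e = np.asarray(start, dtype=float).copy()
        if e.shape != (n,):
            raise ValueError("start vector length mismatch")
    op = P.T if cfg.update_mode == "mass" else P
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        e_new = (1.0 - cfg.alpha) * e + cfg.alpha * (op @ e)
        delta = np.max(np.abs(e_new - e))
        e = e_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "propagation did not converge in %d iterations (last delta above tol)",
            cfg.max_iter,
        )
    scores = normalize_scores(e)
    return ScoreVector(
        scores=dict(zip(dg.dual_nodes, scores)),
        iterations_used=it,
        converged=converged,
        cell_line=dg.cell_line,
    )


def closed_form_scores(
    dg: DualGraph, cfg: PropagationConfig | None = None
) -> ScoreVector:
    """Stationary scores without iteration.

    The fixed point of the mass-mode update satisfies P^T e = e; on an
    undirected positively-weighted component the walk is reversible, so the
    stationary distribution is proportional to node strength. Each
    component's distribution is scaled by that component's share of the
    uniform initial mass (isolated dual nodes keep their 1/n), matching the
    iteration's limit exactly; the result is then normalized by the max.
    """
    cfg = cfg or PropagationConfig()
    n = len(dg.dual_nodes)
    if n == 0:
        raise ValueError("empty dual graph")
    W = dg.weight_matrix()
    n_comp, labels = csgraph.connected_components(W, directed=False)
    strength = np.asarray(W.sum(axis=1)).ravel()
    e = np.zeros(n)
    for c in range(n_comp):
        mask = labels == c
        comp_mass = mask.sum() / n
        s = strength[mask]
        if s.sum() == 0:  # isolated dual node
            e[mask] = comp_mass
        else:
            e[mask] = comp_mass * s / s.sum()
    scores = normalize_scores(e)
    return ScoreVector(
        scores=dict(zip(dg.dual_nodes, scores)),
        iterations_used=0,
        converged=True,
        cell_line=dg.cell_line,
    )


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Scale a nonnegative score vector by its maximum into (0, 1]."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty score vector")
    if np.any(raw < 0):
        raise ValueError("scores must be nonnegative")
    m = raw.max()
    if m == 0:
        raise ValueError("all-zero score vector cannot be normalized")
    return raw / m


def score_context_network(
    net: ContextNetwork, cfg: PropagationConfig | None = None
) -> ScoreVector:
    """Convenience: dual-graph construction + propagation in one call."""
    cfg = cfg or PropagationConfig()
    dg = build_dual_graph(net, w=cfg.w)
    return propagate(dg, cfg)
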