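"""Insulated heat diffusion and subnetwork extraction.

The substrate is an undirected gene-interaction graph built from a
STRING-style edge list after discarding combined scores below a threshold
(default 400, inclusive).  On each connected component the insulated diffusion
kernel is

    F = beta * (I - (1 - beta) * W)^-1

where W is the column-degree-normalised adjacency and beta the restart
probability of the underlying random walk (default 0.4).  Columns of F sum to
one, so diffusing a heat vector h through E = F @ diag(h) conserves heat:
E[i, j] is the heat gene j passes to gene i.

Subnetworks are the strongly connected components of the directed graph with
an arc j -> i wherever E[i, j] >= delta; their statistical significance comes
from permuting the heat-to-gene assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 400
DEFAULT_BETA = 0.4


@dataclass
class InteractionNetwork:
    """Thresholded undirected gene graph; node order is sorted gene id."""

    graph: nx.Graph
    score_threshold: int
    meta: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, int]]:
        """Canonical (a < b, sorted) scored edge list."""
        out = [
            (a, b, int(d["score"])) if a < b else (b, a, int(d["score"]))
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(out)


@dataclass
class DiffusionKernel:
    nodes: list[str]
    F: np.ndarray
    beta: float


@dataclass
class Subnetwork:
    index: int
    genes: list[str]
    size: int


@dataclass
class SignificanceReport:
    delta: float
    table: pd.DataFrame  # columns: size_threshold, observed, expected, p
    n_perm: int


def build_network(
    edges: list[tuple[str, str, int]] | pd.DataFrame,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
) -> InteractionNetwork:
    """Build the interaction graph, keeping edges with score >= threshold.

    Self-loops are dropped; duplicate undirected pairs keep the maximum score.
    Nodes appear only through surviving edges, so isolated genes never enter.
    """
    if isinstance(edges, pd.DataFrame):
        edges = list(edges.itertuples(index=False, name=None))
    g = nx.Graph()
    n_input = 0
    for a, b, score in edges:
        n_input += 1
        score = int(score)
        if not (0 <= score <= 1000):
            raise ValueError(f"combined score {score} outside [0, 1000]")
        if a == b or score < score_threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no edges survive the score threshold {score_threshold} "
            f"({n_input} input edges)"
        )
    net = InteractionNetwork(graph=g, score_threshold=score_threshold)
    logger.info(
        "network: %d nodes, %d edges (from %d input rows, threshold %d)",
        net.n_nodes, net.n_edges, n_input, score_threshold,
    )
    return net


def diffusion_kernel(network: InteractionNetwork, beta: float = DEFAULT_BETA) -> DiffusionKernel:
    """Insulated-diffusion kernel F = beta (I - (1-beta) W)^-1, per component.

    W is the column-normalised (out-degree) adjacency of each connected
    component; F is assembled block-diagonally over the sorted node order and
    every column sums to one.
    """
    if not (0 < beta < 1):
        raise ValueError("beta must lie in (0, 1)")
    nodes = network.nodes
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    F = np.zeros((n, n))
    for comp in nx.connected_components(network.graph):
        idx = np.array(sorted(index[g] for g in comp))
        if idx.size == 1:
            F[idx[0], idx[0]] = 1.0  # isolated node keeps all its heat
            continue
        sub = [nodes[i] for i in idx]
        A = nx.to_numpy_array(network.graph, nodelist=sub, weight=None)
        W = A / A.sum(axis=0, keepdims=True)
        block = beta * np.linalg.inv(np.eye(idx.size) - (1.0 - beta) * W)
        F[np.ix_(idx, idx)] = block
    colsums = F.sum(axis=0)
    assert np.allclose(colsums, 1.0, atol=1e-9), "kernel columns must sum to 1"
    return DiffusionKernel(nodes=nodes, F=F, beta=beta)


def exchanged_heat(kernel: DiffusionKernel, heat: np.ndarray) -> np.ndarray:
    """E = F @ diag(heat): E[i, j] is heat that gene j passes to gene i."""
    heat = np.asarray(heat, dtype=float)
    if heat.shape != (len(kernel.nodes),):
        raise ValueError("heat vector must align with the kernel node order")
    if (heat < 0).any():
        raise ValueError("heat must be nonnegative")
    return kernel.F * heat[np.newaxis, :]


def _strong_components(E: np.ndarray, delta: float) -> list[np.ndarray]:
    """Index sets of strongly connected components of the arc-thresholded digraph.

    Arc j -> i iff E[i, j] >= delta and i != j; csgraph wants M[i, j] = arc
    i -> j, hence the transpose.
    """
    mask = E >= delta
    np.fill_diagonal(mask, False)
    m = sp.csr_matrix(mask.T)
    n_comp, labels = connected_components(m, directed=True, connection="strong")
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp))
    return [order[bounds[c]: bounds[c + 1] if c + 1 < n_comp else None]
            for c in range(n_comp)]


def extract_subnetworks(
    E: np.ndarray,
    delta: float,
    nodes: list[str],
    min_size: int = 3,
) -> list[Subnetwork]:
    """Strongly connected components of the delta-thresholded exchanged-heat digraph.

    Components of size >= ``min_size`` are returned sorted by size descending
    (ties by gene list), with 1-based indices assigned in that order.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    comps = [c for c in _strong_components(E, delta) if c.size >= min_size]
    genes = [sorted(nodes[i] for i in c) for c in comps]
    genes.sort(key=lambda gs: (-len(gs), gs))
    return [Subnetwork(index=i + 1, genes=gs, size=len(gs))
            for i, gs in enumerate(genes)]


def _component_sizes(E: np.ndarray, delta: float) -> np.ndarray:
    return np.array([c.size for c in _strong_components(E, delta)])


def _counts_at_thresholds(sizes: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#components of size >= s for each s (components of size 1 never count)."""
    sizes = sizes[sizes >= 2]
    return np.array([(sizes >= s).sum() for s in thresholds])


def permutation_significance(
    network: InteractionNetwork,
    heat: np.ndarray,
    delta: float,
    beta: float = DEFAULT_BETA,
    n_perm: int = 100,
    seed: int | None = None,
    kernel: DiffusionKernel | None = None,
) -> SignificanceReport:
    """Permutation test of subnetwork counts.

    The heat-to-gene assignment is shuffled ``n_perm`` times; for each size
    threshold s (2 .. largest observed component) the add-one P-value is the
    fraction of permutations producing at least as many components of size
    >= s as observed.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    if kernel is None:
        kernel = diffusion_kernel(network, beta)
    rng = np.random.default_rng(seed)
    obs_sizes = _component_sizes(exchanged_heat(kernel, heat), delta)
    s_max = int(obs_sizes.max(initial=1))
    thresholds = np.arange(2, max(s_max, 2) + 1)
    observed = _counts_at_thresholds(obs_sizes, thresholds)
    perm_counts = np.zeros((n_perm, thresholds.size), dtype=int)
    for r in range(n_perm):
        h_perm = rng.permutation(heat)
        sizes = _component_sizes(exchanged_heat(kernel, h_perm), delta)
        perm_counts[r] = _counts_at_thresholds(sizes, thresholds)
    p = (1 + (perm_counts >= observed[np.newaxis, :]).sum(axis=0)) / (n_perm + 1)
    table = pd.DataFrame(
        {
            "size_threshold": thresholds,
            "observed": observed,
            "expected": perm_counts.mean(axis=0),
            "p": p,
        }
    )
    return SignificanceReport(delta=float(delta), table=table, n_perm=n_perm)


def choose_delta(
    network: InteractionNetwork,
    heat: np.ndarray,
    beta: float = DEFAULT_BETA,
    n_perm: int = 20,
    target_max_size: int = 10,
    seed: int | None = None,
    kernel: DiffusionKernel | None = None,
) -> float:
    """Data-driven edge-weight cutoff for the exchanged-heat digraph.

    For each permuted heat assignment, binary-search the sorted distinct
    positive off-diagonal exchanged-heat values for the smallest delta at
    which the largest strongly connected component falls below
    ``target_max_size``.  The returned delta is the largest of these
    per-permutation values: the smallest cutoff at which NO permuted
    assignment retains a component of the target size, so that observed
    components at or above it are rare under the null.  The result always
    lies on (or immediately above) one of the permuted value grids.
    """
    heat = np.asarray(heat, dtype=float)
    if not (heat > 0).any():
        raise ValueError("heat vector is all zero")
    if kernel is None:
        kernel = diffusion_kernel(network, beta)
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_perm):
        E = exchanged_heat(kernel, rng.permutation(heat))
        off = E[~np.eye(E.shape[0], dtype=bool)]
        values = np.unique(off[off > 0])
        if values.size == 0:
            continue
        if values.size == 1:
            logger.warning("degenerate exchanged heat (single value); using max(E)")
            deltas.append(float(values[0]))
            continue
        # predicate is monotone in delta: larger delta -> smaller components
        lo, hi = 0, values.size - 1
        if _component_sizes(E, values[lo]).max(initial=1) < target_max_size:
            deltas.append(float(values[lo]))
            continue
        if _component_sizes(E, values[hi]).max(initial=1) >= target_max_size:
            # even the sparsest grid point keeps a large component: step past it
            deltas.append(float(np.nextafter(values[hi], np.inf)))
            continue
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _component_sizes(E, values[mid]).max(initial=1) < target_max_size:
                hi = mid
            else:
                lo = mid
        deltas.append(float(values[hi]))
    if not deltas:
        raise ValueError("exchanged heat is identically zero")
    return max(deltas)


def significant_subnetworks(
    subnetworks: list[Subnetwork],
    report: SignificanceReport,
    alpha: float = 0.05,
) -> list[Subnetwork]:
    """The reported discovery set: components at the tightest significant scale.

    Takes the largest size threshold s with permutation P <= alpha and
    returns the subnetworks of size >= s; empty when no threshold is
    significant.
    """
    sig = report.table[report.table["p"] <= alpha]
    if sig.empty:
        return []
    s_star = int(sig["size_threshold"].max())
    return [s for s in subnetworks if s.size >= s_star]
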