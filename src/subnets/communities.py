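"""Community detection on thresholded connectivity graphs.

Communities found at sparse graph densities (top 0.1% of each row/column)
represent subnetworks; communities found at denser thresholds represent
large-scale networks. The optimizer is a pluggable contract: the
map-equation backend (igraph Infomap) is the reference, with a
modularity-Louvain fallback (networkx).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np

from subnets.spaces import ConnectivityMatrix, LabelMap, NodeSpace

logger = logging.getLogger(__name__)


@dataclass
class CommunitySolution:
    """A community labeling at one graph density, with its quality score."""

    labels: LabelMap
    density: float
    quality: float  # codelength (map equation) or modularity (Louvain)
    method: str
    seed: int


def _weighted_edges(values: np.ndarray, mask: np.ndarray):
    iu = np.triu_indices_from(mask, k=1)
    keep = mask[iu]
    rows, cols = iu[0][keep], iu[1][keep]
    w = values[rows, cols]
    w = np.where(np.isfinite(w), w, 0.0)
    w = np.maximum(w, 0.0)  # community detection uses positive weights only
    return rows, cols, w


def detect_communities(
    cm: ConnectivityMatrix,
    mask: np.ndarray,
    method: str = "map_equation",
    seed: int = 0,
    min_community_size: int = 10,
    node_subset: np.ndarray | None = None,
) -> CommunitySolution:
    """Detect communities in the retained (masked) connectivity graph.

    Parameters
    ----------
    cm : ConnectivityMatrix
        Fisher-z connectivity; only entries where ``mask`` is True enter the
        graph, with the z value as edge weight (negative weights floored to
        0, matching the positive-connectivity-only philosophy).
    mask : (N, N) bool array
        Symmetric retention mask from density thresholding.
    method : {"map_equation", "modularity"}
        Optimizer backend.
    seed : int
        Makes the stochastic optimizers deterministic.
    min_community_size : int
        Communities smaller than this are relabeled 0 (unassigned).
    node_subset : bool array, optional
        Restrict the graph to these nodes (e.g. cortex only); excluded nodes
        receive label 0.

    Returns
    -------
    CommunitySolution with labels 1..K sorted by descending community size.
    """
    n = cm.n_nodes
    if node_subset is None:
        node_subset = np.ones(n, dtype=bool)
    idx = np.flatnonzero(node_subset)
    if idx.size == 0:
        raise ValueError("empty graph: no nodes selected")
    sub_mask = mask[np.ix_(idx, idx)]
    rows, cols, w = _weighted_edges(cm.values[np.ix_(idx, idx)], sub_mask)
    if rows.size == 0:
        raise ValueError("empty graph: no edges retained at this density")

    if method == "map_equation":
        membership, quality = _run_infomap(len(idx), rows, cols, w, seed)
    elif method == "modularity":
        membership, quality = _run_louvain(len(idx), rows, cols, w, seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    labels = np.zeros(n, dtype=int)
    labels[idx] = membership + 1
    labels = _relabel_by_size(labels, min_community_size)
    lm = LabelMap(labels=labels)
    return CommunitySolution(
        labels=lm, density=float("nan"), quality=quality, method=method, seed=seed
    )


def _run_infomap(n, rows, cols, w, seed):
    import igraph

    g = igraph.Graph(n=n, edges=list(zip(rows.tolist(), cols.tolist())))
    state = random.getstate()
    try:
        random.seed(seed)  # python-igraph draws from the stdlib RNG
        comm = g.community_infomap(edge_weights=w.tolist(), trials=5)
    finally:
        random.setstate(state)
    return np.array(comm.membership), float(comm.codelength)


def _run_louvain(n, rows, cols, w, seed):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_weighted_edges_from(zip(rows.tolist(), cols.tolist(), w.tolist()))
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    membership = np.zeros(n, dtype=int)
    for c, nodes in enumerate(parts):
        membership[list(nodes)] = c
    q = nx.community.modularity(g, parts, weight="weight")
    return membership, float(q)


def _relabel_by_size(labels: np.ndarray, min_size: int) -> np.ndarray:
    """1..K by descending size; communities below ``min_size`` -> 0."""
    out = np.zeros_like(labels)
    vals, counts = np.unique(labels[labels != 0], return_counts=True)
    order = np.argsort(-counts, kind="stable")
    next_label = 1
    for i in order:
        if counts[i] < min_size:
            continue
        out[labels == vals[i]] = next_label
        next_label += 1
    return out


def extract_parent_subnetworks(
    solution: CommunitySolution,
    parent_mask: LabelMap,
    overlap_fraction: float = 0.5,
) -> dict[int, frozenset[int]]:
    """Keep communities represented within the parent network.

    A community is kept when at least ``overlap_fraction`` of its nodes fall
    inside the parent mask (>= at the boundary). Each kept community becomes
    one subnetwork restricted to its own nodes.

    Returns ``{community label: node set}``; empty dict (with a warning) when
    nothing passes.
    """
    if solution.labels.n_nodes != parent_mask.n_nodes:
        raise ValueError("solution and parent mask live in different spaces")
    in_parent = parent_mask.labels != 0
    out: dict[int, frozenset[int]] = {}
    for lab in solution.labels.present_labels():
        members = solution.labels.labels == lab
        frac = in_parent[members].mean()
        if frac >= overlap_fraction:
            out[lab] = frozenset(np.flatnonzero(members).tolist())
    if not out:
        logger.warning("no community overlaps the parent network at fraction >= %s",
                       overlap_fraction)
    return out


def identify_parent_network(
    solution: CommunitySolution, template: LabelMap, target_label: int
) -> LabelMap:
    """Find the detected network corresponding to a template network.

    Each detected community is assigned to the template network with maximal
    Jaccard overlap; the mask of the community assigned to ``target_label``
    is returned (all-zero, with a warning, if no community overlaps it).
    """
    from subnets.matching import jaccard

    if solution.labels.n_nodes != template.n_nodes:
        raise ValueError("solution and template live in different spaces")
    best_for_target = 0
    best_j = 0.0
    target_set = template.node_set(target_label)
    if not target_set:
        raise ValueError(f"template has no nodes with label {target_label}")
    for lab in solution.labels.present_labels():
        comm = solution.labels.node_set(lab)
        # assign this community to its best template network
        assigned, assigned_j = 0, 0.0
        for t in template.present_labels():
            j = jaccard(comm, template.node_set(t))
            if j > assigned_j:
                assigned, assigned_j = t, j
        if assigned == target_label and assigned_j > best_j:
            best_for_target, best_j = lab, assigned_j
    mask = np.zeros(template.n_nodes, dtype=int)
    if best_for_target == 0:
        logger.warning("no detected community maps onto template label %d", target_label)
    else:
        mask[solution.labels.labels == best_for_target] = 1
    return LabelMap(labels=mask)
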