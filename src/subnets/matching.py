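"""Match subnetworks across subjects into clusters; build overlap maps.

Per-subject subnetwork instances are compared by spatial Jaccard overlap,
the resulting instance x instance matrix is clustered with iterative Louvain
(repeated until modularity no longer increases), clusters present in fewer
than half of subjects are discarded, and the surviving clusters are rendered
as cross-subject density maps and a winner-take-all map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from subnets.spaces import LabelMap

logger = logging.getLogger(__name__)


def jaccard(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|a ∩ b| / |a ∪ b|. Raises when both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / union


@dataclass
class SubnetworkInstance:
    """One subject's one subnetwork: a node set tagged with its origin."""

    subject_id: str
    subnetwork_id: int
    nodes: frozenset[int]


@dataclass
class OverlapMatrix:
    """Instance x instance Jaccard coefficients."""

    instances: list[SubnetworkInstance]
    values: np.ndarray

    @classmethod
    def from_instances(cls, instances: list[SubnetworkInstance]) -> "OverlapMatrix":
        n = len(instances)
        m = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = jaccard(instances[i].nodes, instances[j].nodes)
        return cls(instances=instances, values=m)


@dataclass
class MatchedCluster:
    """A group of matched subnetwork instances across subjects."""

    cluster_id: int
    members: list[SubnetworkInstance]
    name: str = ""

    @property
    def subjects(self) -> set[str]:
        return {m.subject_id for m in self.members}


def instances_from_subnetworks(
    per_subject: dict[str, dict[int, frozenset[int]]]
) -> list[SubnetworkInstance]:
    """Flatten ``{subject: {subnetwork label: node set}}`` to instances."""
    out = []
    for subj in sorted(per_subject):
        for lab in sorted(per_subject[subj]):
            out.append(SubnetworkInstance(subj, lab, frozenset(per_subject[subj][lab])))
    return out


def cluster_overlap_matrix(
    om: OverlapMatrix,
    n_subjects: int,
    min_subject_fraction: float = 0.5,
    seed: int = 0,
    resolution: float = 1.0,
) -> list[MatchedCluster]:
    """Cluster the Jaccard matrix with iterative Louvain; filter rare clusters.

    Louvain passes are repeated until the modularity of the new partition is
    no longer higher than the previous one; the best partition wins. Clusters
    represented in fewer than ``min_subject_fraction * n_subjects`` subjects
    are discarded (with a warning if nothing survives). Deterministic given
    ``seed``.
    """
    n = len(om.instances)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        w = om.values[i, j]
        if w > 0:
            g.add_edge(int(i), int(j), weight=float(w))
    if g.number_of_edges() == 0:
        logger.warning("overlap matrix has no positive entries; nothing to cluster")
        return []

    best_parts: list[set[int]] | None = None
    best_q = -np.inf
    for it in range(20):  # iterate until modularity stops increasing
        parts = nx.community.louvain_communities(
            g, weight="weight", seed=seed + it, resolution=resolution
        )
        q = nx.community.modularity(g, parts, weight="weight")
        if q > best_q + 1e-12:
            best_parts, best_q = parts, q
        else:
            break

    clusters: list[MatchedCluster] = []
    min_subjects = min_subject_fraction * n_subjects
    # deterministic ordering: by size desc, then smallest member index
    keyed = sorted(
        best_parts, key=lambda p: (-len(p), min(p))
    )
    cid = 1
    for part in keyed:
        members = [om.instances[i] for i in sorted(part)]
        cluster = MatchedCluster(cluster_id=cid, members=members)
        if len(cluster.subjects) >= min_subjects:
            cluster.name = f"cluster_{cid}"
            clusters.append(cluster)
            cid += 1
        else:
            logger.info(
                "discarding cluster with %d/%d subjects (below fraction %.2f)",
                len(cluster.subjects), n_subjects, min_subject_fraction,
            )
    if not clusters:
        logger.warning("all clusters fell below the subject-fraction filter")
    return clusters


def density_map(cluster: MatchedCluster, n_nodes: int) -> np.ndarray:
    """Per-node count of distinct subjects whose matched subnetwork covers it.

    A subject contributing two instances to the cluster still counts once
    per node: counts are numbers of individuals.
    """
    counts = np.zeros(n_nodes, dtype=int)
    per_subject_nodes: dict[str, set[int]] = {}
    for inst in cluster.members:
        per_subject_nodes.setdefault(inst.subject_id, set()).update(inst.nodes)
    for nodes in per_subject_nodes.values():
        counts[sorted(nodes)] += 1
    return counts


def threshold_density(
    counts: np.ndarray,
    mode: str = "min_subjects",
    min_subjects: int = 3,
    fraction: float = 0.10,
    n_subjects: int | None = None,
) -> frozenset[int]:
    """Binarize a density map.

    ``min_subjects`` mode keeps nodes with count >= k (at-least rule);
    ``fraction`` mode keeps nodes with count strictly > fraction * n_subjects
    (the ">10% of participants" rule).
    """
    counts = np.asarray(counts)
    if mode == "min_subjects":
        keep = counts >= min_subjects
    elif mode == "fraction":
        if n_subjects is None:
            raise ValueError("fraction mode needs n_subjects")
        keep = counts > fraction * n_subjects
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return frozenset(np.flatnonzero(keep).tolist())


def winner_take_all(
    density_maps: dict[int, np.ndarray],
) -> tuple[LabelMap, np.ndarray]:
    """Assign each node to the cluster with the maximal subject count.

    Zero-count nodes stay unassigned. Ties are broken by cluster order
    (ascending cluster id) and flagged in the returned boolean tie mask.
    """
    if not density_maps:
        raise ValueError("no density maps supplied")
    cluster_ids = sorted(density_maps)
    stack = np.vstack([density_maps[c] for c in cluster_ids])
    best = stack.argmax(axis=0)  # first max wins -> cluster-order tie break
    maxval = stack.max(axis=0)
    ties = (stack == maxval).sum(axis=0) > 1
    ties &= maxval > 0
    labels = np.where(maxval > 0, np.array(cluster_ids)[best], 0)
    return LabelMap(labels=labels), ties
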