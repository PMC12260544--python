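"""Subnetwork connectivity/activation profiles and the ANOVA machinery.

Profiles are Fisher-z correlations between a subnetwork's mean time course
and each large-scale network's mean time course (nodes overlapping the
subnetwork are excluded from the network average). Profiles and task means
are compared with a repeated-measures ANOVA (level fixed, subject as block),
Bonferroni-corrected over the declared family, with paired t post hocs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from subnets.spaces import NodeSpace, Timeseries, fisher_z

logger = logging.getLogger(__name__)


@dataclass
class StatResult:
    effect: str
    f_stat: float
    df: tuple[int, int]
    p: float
    p_bonferroni: float
    post_hoc: list[tuple[tuple[str, str], float, int, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def subnetwork_network_fc(
    ts: Timeseries,
    subnetwork_nodes: frozenset[int] | set[int],
    network_nodes: frozenset[int] | set[int],
    space: NodeSpace | None = None,
    short_distance_mm: float = 0.0,
    r_max: float = 0.999999,
) -> float:
    """Fisher-z connectivity between a subnetwork and a target network.

    Network nodes overlapping the subnetwork are excluded from the network
    average. Default mode correlates the two mean time courses. When
    ``short_distance_mm > 0`` (requires ``space``), the estimate is instead
    the mean Fisher-z over node pairs farther apart than the cutoff, since a
    mean time course cannot be pair-masked.

    Returns NaN (with a log entry) when the target is empty after exclusion.
    """
    sub = sorted(subnetwork_nodes)
    tgt = sorted(set(network_nodes) - set(subnetwork_nodes))
    if not sub:
        raise ValueError("empty subnetwork")
    if not tgt:
        logger.warning(
            "subject %s: target network empty after overlap exclusion", ts.subject_id
        )
        return float("nan")
    if short_distance_mm > 0:
        if space is None:
            raise ValueError("short-distance exclusion requires a NodeSpace")
        d = np.linalg.norm(
            space.coords[sub][:, None, :] - space.coords[tgt][None, :, :], axis=2
        )
        x = ts.values[sub] - ts.values[sub].mean(axis=1, keepdims=True)
        y = ts.values[tgt] - ts.values[tgt].mean(axis=1, keepdims=True)
        sx = x.std(axis=1)
        sy = y.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x @ y.T) / ts.n_frames / np.outer(sx, sy)
        keep = (d >= short_distance_mm) & np.isfinite(r)
        if not keep.any():
            logger.warning(
                "subject %s: no node pair survives the %.0f mm exclusion",
                ts.subject_id, short_distance_mm,
            )
            return float("nan")
        return float(np.mean(fisher_z(r[keep], r_max=r_max)))
    a = ts.values[sub].mean(axis=0)
    b = ts.values[tgt].mean(axis=0)
    if a.std() == 0 or b.std() == 0:
        logger.warning("subject %s: constant mean time course", ts.subject_id)
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(fisher_z(r, r_max=r_max))


def task_condition_means(
    z_map: np.ndarray, subnetworks: dict[int, frozenset[int]]
) -> dict[int, float]:
    """Mean activation z within each subnetwork's nodes (NaN when empty)."""
    z_map = np.asarray(z_map, dtype=float)
    out = {}
    for lab, nodes in subnetworks.items():
        if not nodes:
            logger.warning("subnetwork %s empty; mean undefined", lab)
            out[lab] = float("nan")
        else:
            out[lab] = float(z_map[sorted(nodes)].mean())
    return out


def rm_anova(table: dict[str, dict[str, float]], effect: str = "level",
             n_tests: int = 1) -> StatResult:
    """Repeated-measures ANOVA: level fixed, subject as a blocking factor.

    ``table[subject][level]`` holds one value per cell; NaN cells and missing
    cells are omitted from the sums of squares (the additive two-way model is
    fit by least squares, and the partial F for the level factor is
    reported — equal to the classical within-subject F when the design is
    balanced). Levels observed in fewer than two subjects are dropped with a
    warning. A zero residual (level differences identical in every subject)
    yields F = inf with a flag.
    """
    # collect long-format observations
    obs: list[tuple[str, str, float]] = []
    level_counts: dict[str, int] = {}
    for subj, cells in table.items():
        for lev, val in cells.items():
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            obs.append((subj, str(lev), float(val)))
            level_counts[str(lev)] = level_counts.get(str(lev), 0) + 1
    keep_levels = sorted(l for l, c in level_counts.items() if c >= 2)
    dropped = sorted(set(level_counts) - set(keep_levels))
    flags = []
    if dropped:
        logger.warning("levels dropped (<2 subjects): %s", dropped)
        flags.append(f"dropped_levels:{','.join(dropped)}")
    obs = [o for o in obs if o[1] in keep_levels]
    subjects = sorted({o[0] for o in obs})
    if len(keep_levels) < 2 or len(subjects) < 2:
        raise ValueError("need >=2 levels and >=2 subjects")

    y = np.array([o[2] for o in obs])
    n = len(y)

    def design(with_level: bool) -> np.ndarray:
        cols = [np.ones(n)]
        for s in subjects[1:]:
            cols.append(np.array([1.0 if o[0] == s else 0.0 for o in obs]))
        if with_level:
            for l in keep_levels[1:]:
                cols.append(np.array([1.0 if o[1] == l else 0.0 for o in obs]))
        return np.column_stack(cols)

    def ssr(X: np.ndarray) -> tuple[float, int]:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), int(rank)

    ssr_full, rank_full = ssr(design(True))
    ssr_red, _ = ssr(design(False))
    df1 = len(keep_levels) - 1
    df2 = n - rank_full
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_level = max(ssr_red - ssr_full, 0.0)
    if ssr_full <= 1e-12 * max(ss_level, 1.0):
        if ss_level <= 1e-12:
            f = 0.0
            p = 1.0
        else:
            f = float("inf")
            p = 0.0
            flags.append("zero_residual")
            logger.warning("zero interaction residual: within-subject differences constant")
    else:
        f = (ss_level / df1) / (ssr_full / df2)
        p = float(stats.f.sf(f, df1, df2))
    return StatResult(
        effect=effect,
        f_stat=float(f),
        df=(df1, df2),
        p=p,
        p_bonferroni=min(1.0, p * n_tests),
        flags=flags,
    )


def paired_t(
    values_a: dict[str, float], values_b: dict[str, float]
) -> tuple[float, int, float]:
    """Paired t test on subject-wise differences; missing/NaN pairs dropped."""
    subjects = sorted(set(values_a) & set(values_b))
    diffs = []
    for s in subjects:
        a, b = values_a[s], values_b[s]
        if math.isnan(a) or math.isnan(b):
            continue
        diffs.append(a - b)
    if len(diffs) < 2:
        raise ValueError("need >=2 complete pairs")
    diffs = np.array(diffs)
    df = len(diffs) - 1
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.all(diffs == 0):
            return 0.0, df, 1.0
        return math.copysign(float("inf"), diffs.mean()), df, 0.0
    t = diffs.mean() / (sd / math.sqrt(len(diffs)))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), df, p


def post_hoc_paired(
    per_level: dict[str, dict[str, float]]
) -> list[tuple[tuple[str, str], float, int, float]]:
    """All pairwise paired t tests between levels (``per_level[level][subject]``)."""
    levels = sorted(per_level)
    out = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            t, df, p = paired_t(per_level[a], per_level[b])
            out.append(((a, b), t, df, p))
    return out


# ---------------------------------------------------------------------------
# spring-graph export


@dataclass
class GraphCluster:
    """A node for graph export: a contiguous cluster of one structure."""

    name: str
    structure: str  # owning subnetwork/network name
    nodes: frozenset[int]
    is_network: bool = False


def spring_graph_export(
    ts: Timeseries,
    clusters: list[GraphCluster],
    declared_networks: list[str],
    density: float = 0.10,
    step: float = 0.05,
    r_max: float = 0.999999,
) -> tuple[nx.Graph, float, list[str]]:
    """Cluster-level connectivity graph thresholded for spring-embedded plots.

    Pairwise Fisher-z correlations between cluster mean time courses are
    thresholded to the top ``density`` fraction of edges. If all clusters of
    any declared network fall outside the giant connected component, the
    density is raised by ``step`` and the graph rebuilt, until every declared
    network connects or density reaches 1.0 (then exported with a disconnect
    warning). Returns (graph, final density, warnings).
    """
    if len(clusters) < 2:
        raise ValueError("need >=2 clusters")
    means = np.vstack([ts.values[sorted(c.nodes)].mean(axis=0) for c in clusters])
    r = np.corrcoef(means)
    z = np.asarray(fisher_z(r, r_max=r_max))
    n = len(clusters)
    iu = np.triu_indices(n, k=1)
    order = np.lexsort((iu[1], iu[0], -z[iu]))  # value desc, then pair index asc
    n_pairs = len(order)

    warnings: list[str] = []
    d = density
    while True:
        k = max(1, int(np.ceil(d * n_pairs)))
        g = nx.Graph()
        for i, c in enumerate(clusters):
            g.add_node(
                i,
                label=c.name,
                structure=c.structure,
                is_network=c.is_network,
                size=len(c.nodes),
            )
        for idx in order[:k]:
            i, j = int(iu[0][idx]), int(iu[1][idx])
            g.add_edge(i, j, weight=float(z[i, j]))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        giant = comps[0]
        missing = [
            name
            for name in declared_networks
            if not any(
                i in giant for i, c in enumerate(clusters) if c.structure == name
            )
        ]
        if not missing:
            break
        if d >= 1.0 - 1e-12:
            msg = f"networks still disconnected at full density: {missing}"
            logger.warning(msg)
            warnings.append(msg)
            break
        d = min(1.0, round(d + step, 10))
        logger.info("raising graph density to %.0f%% (disconnected: %s)", 100 * d, missing)
    return g, d, warnings


def export_graph(g: nx.Graph, prefix) -> None:
    """Write the cluster graph as GEXF and as a weighted edge-list TSV."""
    from pathlib import Path

    prefix = Path(prefix)
    nx.write_gexf(g, str(prefix.with_suffix(".gexf")))
    with open(prefix.with_suffix(".edges.tsv"), "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in g.edges(data=True):
            fh.write(f"{g.nodes[u]['label']}\t{g.nodes[v]['label']}\t{data['weight']:.6g}\n")
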