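"""Meta-analytic network annotation (MANA) of distributed subnetworks.

A subnetwork's group-level topography is reduced to its connected regions;
studies in a coordinate database (Neurosynth layout: an activations table of
study peaks in MNI152 mm and a study x term weight table) "match" the
subnetwork when their peaks land near a sufficient fraction of those
regions; each curated term's weights are then compared across subnetworks
with a one-way ANOVA and Benjamini-Hochberg control over terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from subnets.spaces import NodeSpace

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """One connected component of a thresholded density map."""

    nodes: frozenset[int]
    centroid: np.ndarray  # mm
    area_mm2: float
    representative: np.ndarray  # coordinate of the node nearest the centroid


@dataclass
class TermAssociation:
    """Result of the per-term across-subnetwork weight ANOVA."""

    term: str
    f_stat: float
    df: tuple[int, int]
    p: float
    q: float  # FDR-adjusted
    significant: bool
    assigned_subnetwork: int
    group_means: dict[int, float]
    magnitude: float  # max group mean - grand mean (presentation only)


def extract_regions(
    nodes: frozenset[int] | set[int],
    space: NodeSpace,
    min_area_mm2: float = 20.0,
) -> list[Region]:
    """Connected components of a node set under mesh adjacency.

    Components with summed node area below ``min_area_mm2`` are dropped.
    Regions are returned sorted by descending area.
    """
    if not nodes:
        raise ValueError("empty node set: no regions to extract")
    node_list = sorted(nodes)
    index = {n: i for i, n in enumerate(node_list)}
    # union-find over edges internal to the set
    parent = list(range(len(node_list)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    node_set = set(node_list)
    for a, b in space.edges:
        if a in node_set and b in node_set:
            ra, rb = find(index[int(a)]), find(index[int(b)])
            if ra != rb:
                parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for n, i in index.items():
        comps.setdefault(find(i), []).append(n)
    regions = []
    for members in comps.values():
        area = float(space.area[members].sum())
        if area < min_area_mm2:
            continue
        coords = space.coords[members]
        centroid = coords.mean(axis=0)
        rep = coords[np.argmin(np.linalg.norm(coords - centroid, axis=1))]
        regions.append(
            Region(
                nodes=frozenset(members),
                centroid=centroid,
                area_mm2=area,
                representative=rep,
            )
        )
    regions.sort(key=lambda r: -r.area_mm2)
    return regions


def match_studies(
    activations: pd.DataFrame,
    regions: list[Region],
    space: NodeSpace,
    radius_mm: float = 2.0,
    fraction: float = 0.40,
    distance_mode: str = "nodes",
) -> list[int]:
    """Studies whose peaks cover enough of the subnetwork's regions.

    A region is "hit" when any peak of the study lies strictly closer than
    ``radius_mm`` to any node of the region (``distance_mode="nodes"``) or to
    its centroid (``distance_mode="centroid"``). A study matches when its
    hit-region count is at least ``ceil(fraction * n_regions)``.

    Monotone: enlarging the radius or shrinking the fraction never removes a
    matched study.
    """
    if not regions:
        raise ValueError("no regions to match against")
    need = int(np.ceil(fraction * len(regions)))
    trees = []
    for reg in regions:
        if distance_mode == "nodes":
            pts = space.coords[sorted(reg.nodes)]
        elif distance_mode == "centroid":
            pts = reg.centroid[None, :]
        else:
            raise ValueError(f"unknown distance_mode {distance_mode!r}")
        trees.append(cKDTree(pts))
    matched = []
    for sid, group in activations.groupby("study_id", sort=True):
        peaks = group[["x", "y", "z"]].to_numpy(dtype=float)
        hits = 0
        for tree in trees:
            d, _ = tree.query(peaks, k=1)
            if np.min(d) < radius_mm:
                hits += 1
        if hits >= need:
            matched.append(sid)
    return matched


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """Fixed-effects one-way ANOVA: F, (df_between, df_within), p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise ZeroDivisionError("zero within-group variance: F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), (df_b, df_w), p


def term_anova(
    features: pd.DataFrame,
    matches: dict[int, list[int]],
    term: str,
) -> TermAssociation | None:
    """Across-subnetwork one-way ANOVA on one term's study weights.

    A study matching several subnetworks contributes its weight to each
    matched group. Degenerate groupings (fewer than two usable groups, or
    zero within-group variance) return None and are logged as skipped.
    """
    weights = features.set_index("study_id")[term]
    labels = sorted(matches)
    groups, kept = [], []
    for lab in labels:
        ids = [s for s in matches[lab] if s in weights.index]
        if len(ids) >= 2:
            groups.append(weights.loc[ids].to_numpy(dtype=float))
            kept.append(lab)
    if len(groups) < 2:
        logger.info("term %r skipped: fewer than 2 groups with >=2 studies", term)
        return None
    try:
        f, df, p = one_way_anova(groups)
    except ZeroDivisionError:
        logger.info("term %r skipped: zero within-group variance", term)
        return None
    means = {lab: float(g.mean()) for lab, g in zip(kept, groups)}
    assigned = max(means, key=lambda l: (means[l], -l))  # ties -> first listed
    grand = float(np.concatenate(groups).mean())
    return TermAssociation(
        term=term,
        f_stat=f,
        df=df,
        p=p,
        q=np.nan,
        significant=False,
        assigned_subnetwork=assigned,
        group_means=means,
        magnitude=means[assigned] - grand,
    )


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q values, rejection flags)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return q, reject


def annotate_terms(
    features: pd.DataFrame,
    matches: dict[int, list[int]],
    terms: list[str] | None = None,
    alpha: float = 0.05,
) -> list[TermAssociation]:
    """Run the term ANOVA over a curated term list and apply FDR control.

    FDR is corrected for the number of terms actually tested (skipped
    degenerate terms do not count).
    """
    if terms is None:
        terms = [c for c in features.columns if c != "study_id"]
    results = [r for t in terms if (r := term_anova(features, matches, t)) is not None]
    if not results:
        return []
    q, reject = fdr_correct(np.array([r.p for r in results]), alpha=alpha)
    for r, qi, rej in zip(results, q, reject):
        r.q = float(qi)
        r.significant = bool(rej)
    return results


def peak_density_map(
    activations: pd.DataFrame, space: NodeSpace, radius_mm: float = 4.0
) -> np.ndarray:
    """Per-node count of database activation peaks within ``radius_mm`` (<=)."""
    counts = np.zeros(space.n_nodes, dtype=int)
    if len(activations) == 0:
        return counts
    peaks = activations[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(peaks)
    hits = tree.query_ball_point(space.coords, r=radius_mm)
    counts[:] = [len(h) for h in hits]
    return counts


def term_filter(
    terms: list[str],
    include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> list[str]:
    """Apply a user-supplied curation lexicon; curation is data, not code.

    Duplicates are collapsed (first occurrence kept). ``include``, when
    given, whitelists terms; ``exclude`` then removes terms.
    """
    seen = set()
    out = []
    include_set = set(include) if include is not None else None
    exclude_set = set(exclude or [])
    for t in terms:
        if t in seen:
            continue
        seen.add(t)
        if include_set is not None and t not in include_set:
            continue
        if t in exclude_set:
            continue
        out.append(t)
    return out
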