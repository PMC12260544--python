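"""Core data model: node spaces, timeseries, connectivity matrices, label maps.

Conventions used throughout the toolkit:

* nodes are indexed 0..N-1 within a :class:`NodeSpace`; coordinates are mm in
  one declared space per analysis (MNI152 by convention);
* connectivity is stored as Fisher-z transformed Pearson correlation with the
  diagonal and any excluded pair set to NaN (the "undefined/excluded marker");
* label 0 always means "unassigned".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STRUCTURE_TAGS = ("cortex_left", "cortex_right", "subcortex")


@dataclass
class NodeSpace:
    """Geometric substrate: node coordinates, mesh adjacency, per-node area.

    Parameters
    ----------
    coords : (N, 3) float array
        Node coordinates in mm.
    edges : (E, 2) int array
        Undirected mesh adjacency (each pair once, either order).
    area : (N,) float array, optional
        Surface area represented by each node, mm^2. Defaults to 1 mm^2 per
        node (with a warning) when the source format carries no geometry.
    structure : (N,) array of str, optional
        One of ``cortex_left``, ``cortex_right``, ``subcortex`` per node.
        Defaults to ``cortex_left``.
    space : str
        Name of the coordinate space; mixing spaces is an error, not an
        implicit transform.
    """

    coords: np.ndarray
    edges: np.ndarray
    area: np.ndarray | None = None
    structure: np.ndarray | None = None
    space: str = "MNI152"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[0]
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge endpoints out of node range")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("adjacency must be irreflexive (no self-loops)")
        # canonicalize: sorted pairs, deduplicated -> symmetric by construction
        if self.edges.size:
            e = np.sort(self.edges, axis=1)
            self.edges = np.unique(e, axis=0)
        if self.area is None:
            logger.warning("no per-node area supplied; defaulting to 1 mm^2 per node")
            self.area = np.ones(n)
        else:
            self.area = np.asarray(self.area, dtype=float)
            if self.area.shape != (n,):
                raise ValueError("area must be length N")
        if self.structure is None:
            self.structure = np.full(n, "cortex_left", dtype=object)
        else:
            self.structure = np.asarray(self.structure, dtype=object)
            bad = set(self.structure) - set(STRUCTURE_TAGS)
            if bad:
                raise ValueError(f"unknown structure tags: {sorted(bad)}")
        cortical = self.structure != "subcortex"
        if np.any(self.area[cortical] <= 0):
            raise ValueError("cortical node areas must be > 0")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def adjacency_sets(self) -> list[set[int]]:
        """Neighbor sets, symmetric."""
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].add(int(j))
            adj[j].add(int(i))
        return adj

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(axis=2))

    def require_same(self, other: "NodeSpace") -> None:
        if self.space != other.space:
            raise ValueError(
                f"coordinate-space mismatch: {self.space!r} vs {other.space!r}; "
                "cross-space mixing requires an explicit transform"
            )
        if self.n_nodes != other.n_nodes:
            raise ValueError(
                f"node-count mismatch: {self.n_nodes} vs {other.n_nodes}"
            )


@dataclass
class Timeseries:
    """Per-subject node x time signal matrix.

    ``run_boundaries`` lists the start frame of every run (first entry 0);
    filters and lag estimates never cross a run boundary.
    """

    subject_id: str
    values: np.ndarray
    tr: float
    run_boundaries: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be node x time")
        if not self.tr > 0:
            raise ValueError(f"tr must be > 0 s, got {self.tr}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries contains non-finite frames")
        rb = tuple(int(b) for b in self.run_boundaries)
        if not rb or rb[0] != 0 or list(rb) != sorted(set(rb)):
            raise ValueError("run_boundaries must start at 0 and be strictly increasing")
        if rb[-1] >= self.n_frames:
            raise ValueError("run boundary beyond last frame")
        self.run_boundaries = rb

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def run_slices(self) -> list[slice]:
        bounds = list(self.run_boundaries) + [self.n_frames]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class ConnectivityMatrix:
    """Node x node Fisher-z correlation matrix; NaN marks undefined/excluded."""

    values: np.ndarray
    space_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelMap:
    """Integer label per node (0 = unassigned) plus a label table."""

    labels: np.ndarray
    label_table: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one integer per node")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")
        for lab in np.unique(self.labels):
            if lab != 0 and int(lab) not in self.label_table:
                self.label_table[int(lab)] = (f"label_{int(lab)}", "#808080")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    def node_set(self, label: int) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.labels == label).tolist())

    def present_labels(self) -> list[int]:
        return [int(l) for l in np.unique(self.labels) if l != 0]


# ---------------------------------------------------------------------------
# connectivity operations


def fisher_z(r: np.ndarray | float, r_max: float = 0.999999) -> np.ndarray | float:
    """arctanh with |r| clipped to ``r_max`` so duplicated rows stay bounded."""
    return np.arctanh(np.clip(r, -r_max, r_max))


def compute_connectivity(
    ts: Timeseries, r_max: float = 0.999999, space_ref: str = ""
) -> ConnectivityMatrix:
    """Fisher-z Pearson correlation between every pair of node time courses.

    Constant (zero-variance) rows cannot be correlated: their row and column
    are set to NaN and reported in the log rather than silently zeroed.
    """
    if ts.n_frames < 2:
        raise ValueError("need at least 2 frames to correlate")
    x = ts.values
    sd = x.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    z = fisher_z(r, r_max=r_max)
    z = np.asarray(z, dtype=float)
    if constant.size:
        logger.warning(
            "subject %s: %d constant node time courses set to NaN: %s",
            ts.subject_id,
            constant.size,
            constant[:10].tolist(),
        )
        z[constant, :] = np.nan
        z[:, constant] = np.nan
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # corrcoef is symmetric up to fp noise
    return ConnectivityMatrix(values=z, space_ref=space_ref)


def density_threshold_rowcol(
    cm: ConnectivityMatrix, density: float
) -> np.ndarray:
    """Keep, for every row and column, its top ``density`` fraction of values.

    Each row retains its ``ceil(density * (N - 1))`` largest off-diagonal
    entries; an entry survives if it is top-k in its row OR its column (union
    rule), and the result is symmetric. Ties at the cutoff are broken by
    descending value then ascending partner index, so the output is
    deterministic.

    Returns
    -------
    (N, N) bool array
        Symmetric retention mask, diagonal False.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must lie in (0, 1], got {density}")
    v = cm.values
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    k = math.ceil(density * (n - 1))
    if k < 1:
        raise ValueError(
            f"density {density} retains 0 entries per row at N={n}"
        )
    # NaN (diagonal / excluded) never retained: rank with -inf
    vv = np.where(np.isfinite(v), v, -np.inf)
    np.fill_diagonal(vv, -np.inf)
    # per-row ranking: descending value, ties -> ascending column index
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), -vv), axis=1)
    topk = order[:, :k]
    keep = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    keep[rows, topk.ravel()] = True
    keep &= np.isfinite(v)  # excluded entries stay excluded even at full density
    return keep | keep.T  # union over rows and columns, symmetric


def exclude_short_distance_edges(
    cm: ConnectivityMatrix, space: NodeSpace, d_mm: float
) -> ConnectivityMatrix:
    """NaN-out entries for node pairs strictly closer than ``d_mm`` (Euclidean).

    Idempotent; ``d_mm = 0`` leaves the matrix unchanged.
    """
    if cm.n_nodes != space.n_nodes:
        raise ValueError("connectivity matrix and node space disagree on N")
    if d_mm == 0:
        return ConnectivityMatrix(values=cm.values.copy(), space_ref=cm.space_ref)
    dist = space.pairwise_distances()
    out = cm.values.copy()
    mask = dist < d_mm
    np.fill_diagonal(mask, True)
    out[mask] = np.nan
    return ConnectivityMatrix(values=out, space_ref=cm.space_ref)
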