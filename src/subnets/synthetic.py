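"""Synthetic multi-subject fixtures with planted ground truth.

Everything the pipeline consumes can be generated here: node spaces on a
toy cortical grid, block-correlated Gaussian timeseries with a nested
network -> subnetwork hierarchy, jittered per-subject subnetwork
topographies, planted inter-structure signal lags carried by a shared
infraslow component, Neurosynth-layout meta-analytic databases with planted
term-subnetwork associations, and task z-maps with planted subnetwork
effects. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subnets.spaces import LabelMap, NodeSpace, Timeseries

logger = logging.getLogger(__name__)


@dataclass
class PlantedDesign:
    """Ground-truth generative design shared by all synthetic fixtures.

    The node hierarchy covers ``n_nodes`` nodes contiguously with
    ``n_networks`` large-scale networks, each split into
    ``subnetworks_per_network`` equal subnetworks (an int applies to every
    network; a tuple gives per-network counts, e.g. ``(3, 3, 2)`` for a
    3-network / 8-subnetwork hierarchy). Correlation levels must satisfy
    ``0 <= background_r < within_network_r < within_subnetwork_r < 1``.

    ``planted_lags`` maps structure label ("net<i>" or "sub<j>") to a delay in
    seconds applied to the shared infraslow component; ``lag_snr`` is the
    amplitude ratio of that shared component to the node noise.
    """

    n_subjects: int = 10
    n_nodes: int = 400
    n_networks: int = 3
    subnetworks_per_network: int | tuple[int, ...] = 3
    within_subnetwork_r: float = 0.6
    within_network_r: float = 0.3
    background_r: float = 0.0
    label_jitter_fraction: float = 0.1
    planted_lags: dict[str, float] = field(default_factory=dict)
    lag_snr: float = 1.0
    planted_terms: dict[str, tuple[int, float]] = field(default_factory=dict)
    n_studies: int = 500
    n_terms: int = 250
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0.0 <= self.background_r < self.within_network_r < self.within_subnetwork_r < 1.0
        ):
            raise ValueError(
                "need 0 <= background_r < within_network_r < within_subnetwork_r < 1"
            )

    def per_network_counts(self) -> tuple[int, ...]:
        if isinstance(self.subnetworks_per_network, int):
            return (self.subnetworks_per_network,) * self.n_networks
        counts = tuple(self.subnetworks_per_network)
        if len(counts) != self.n_networks:
            raise ValueError("subnetworks_per_network tuple must have n_networks entries")
        if any(c > 9 for c in counts):
            raise ValueError("at most 9 subnetworks per network (10*net+k label encoding)")
        return counts

    @property
    def n_subnetworks(self) -> int:
        return sum(self.per_network_counts())

    def network_labels(self) -> np.ndarray:
        """Ground-truth large-scale network label (1-based) per node."""
        return self.subnetwork_labels_flat() // 10

    def subnetwork_labels_flat(self) -> np.ndarray:
        """Ground-truth subnetwork labels encoded as ``10*network + k``."""
        labels = np.zeros(self.n_nodes, dtype=int)
        counts = self.per_network_counts()
        pairs = [
            (net + 1, k + 1) for net, c in enumerate(counts) for k in range(c)
        ]
        bounds = np.linspace(0, self.n_nodes, self.n_subnetworks + 1).astype(int)
        for s, (net, k) in enumerate(pairs):
            labels[bounds[s] : bounds[s + 1]] = 10 * net + k
        return labels

    def truth_maps(self) -> tuple[LabelMap, LabelMap]:
        """(network-level, subnetwork-level) ground-truth label maps."""
        sub = self.subnetwork_labels_flat()
        net = sub // 10
        return LabelMap(labels=net), LabelMap(labels=sub)


def grid_nodespace(n_nodes: int, spacing_mm: float = 6.0) -> NodeSpace:
    """A square 4-connected grid standing in for a cortical mesh.

    Node areas are ``spacing_mm**2``; coordinates lie in the z=0 plane.
    """
    side = int(np.ceil(np.sqrt(n_nodes)))
    ii, jj = np.divmod(np.arange(n_nodes), side)
    coords = np.column_stack([jj * spacing_mm, ii * spacing_mm, np.zeros(n_nodes)])
    edges = []
    for idx in range(n_nodes):
        i, j = divmod(idx, side)
        if j + 1 < side and idx + 1 < n_nodes:
            edges.append((idx, idx + 1))
        if (i + 1) * side + j < n_nodes:
            edges.append((idx, (i + 1) * side + j))
    return NodeSpace(
        coords=coords,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        area=np.full(n_nodes, spacing_mm**2),
    )


def _block_covariance(design: PlantedDesign) -> np.ndarray:
    sub = design.subnetwork_labels_flat()
    net = sub // 10
    same_sub = sub[:, None] == sub[None, :]
    same_net = net[:, None] == net[None, :]
    cov = np.full((design.n_nodes, design.n_nodes), design.background_r)
    cov[same_net] = design.within_network_r
    cov[same_sub] = design.within_subnetwork_r
    np.fill_diagonal(cov, 1.0)
    return cov


def floor_psd(cov: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by eigenvalue flooring."""
    w, v = np.linalg.eigh(cov)
    if w.min() < floor:
        logger.warning(
            "requested covariance not positive definite (min eig %.3g); flooring",
            w.min(),
        )
        w = np.maximum(w, floor)
        cov = (v * w) @ v.T
    return cov


def _fractional_shift(signal: np.ndarray, shift_frames: float) -> np.ndarray:
    """Delay a 1-D signal by a possibly fractional number of frames.

    Implemented as a phase ramp in the Fourier domain (circular sinc
    interpolation); positive shift moves the signal later in time.
    """
    n = len(signal)
    freqs = np.fft.rfftfreq(n)
    spec = np.fft.rfft(signal)
    return np.fft.irfft(spec * np.exp(-2j * np.pi * freqs * shift_frames), n=n)


def _infraslow_component(rng: np.random.Generator, n_frames: int, tr: float) -> np.ndarray:
    """Unit-variance band-limited (0.01-0.1 Hz) Gaussian signal."""
    white = rng.standard_normal(n_frames)
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    spec = np.fft.rfft(white)
    band = (freqs >= 0.01) & (freqs <= 0.1)
    spec[~band] = 0.0
    sig = np.fft.irfft(spec, n=n_frames)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def simulate_timeseries(
    design: PlantedDesign,
    subject: int,
    n_frames: int = 2000,
    tr: float = 1.0,
) -> Timeseries:
    """Zero-mean Gaussian draw with nested block-structured covariance.

    When ``design.planted_lags`` is nonempty, a shared infraslow component is
    added to every node, delayed per structure by fractional (sinc) shifting;
    its amplitude relative to the block-noise is ``design.lag_snr``. Sample
    correlations converge to the design levels as frames grow.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.rng_seed, 1, subject]))
    cov = floor_psd(_block_covariance(design))
    chol = np.linalg.cholesky(cov)
    values = chol @ rng.standard_normal((design.n_nodes, n_frames))
    if design.planted_lags:
        shared = _infraslow_component(rng, n_frames, tr)
        sub = design.subnetwork_labels_flat()
        net = sub // 10
        delays = np.zeros(design.n_nodes)
        for key, lag_s in design.planted_lags.items():
            if key.startswith("net"):
                mask = net == int(key[3:])
            elif key.startswith("sub"):
                mask = sub == int(key[3:])
            else:
                raise ValueError(f"planted_lags key must be net<i> or sub<j>, got {key!r}")
            delays[mask] = lag_s
        for d in np.unique(delays):
            shifted = _fractional_shift(shared, d / tr)
            values[delays == d] += design.lag_snr * shifted
    return Timeseries(subject_id=f"sub-{subject:02d}", values=values, tr=tr)


def jitter_labels(truth: LabelMap, fraction: float, rng: np.random.Generator) -> LabelMap:
    """Reassign exactly ``round(fraction * N)`` nodes to another present label.

    Emulates inter-subject topographic variability. Deterministic given the
    generator state; ``fraction = 0`` returns an identical copy.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    labels = truth.labels.copy()
    n_move = int(round(fraction * truth.n_nodes))
    if n_move == 0:
        return LabelMap(labels=labels, label_table=dict(truth.label_table))
    present = truth.present_labels()
    if len(present) < 2:
        raise ValueError("need at least two labels to jitter between")
    movable = np.flatnonzero(labels != 0)
    chosen = rng.choice(movable, size=n_move, replace=False)
    for idx in chosen:
        options = [l for l in present if l != labels[idx]]
        labels[idx] = options[rng.integers(len(options))]
    return LabelMap(labels=labels, label_table=dict(truth.label_table))


def simulate_subject_subnetworks(
    design: PlantedDesign, rare_label: int | None = None, rare_in_first: int = 3
) -> list[LabelMap]:
    """Per-subject jittered subnetwork label maps.

    If ``rare_label`` is given, that planted subnetwork is absent (nodes left
    unassigned) in all but the first ``rare_in_first`` subjects, emulating a
    subnetwork present in only a minority of subjects.
    """
    _, truth = design.truth_maps()
    maps = []
    for s in range(design.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([design.rng_seed, 2, s]))
        lm = jitter_labels(truth, design.label_jitter_fraction, rng)
        if rare_label is not None and s >= rare_in_first:
            labels = lm.labels.copy()
            labels[labels == rare_label] = 0
            lm = LabelMap(labels=labels, label_table=dict(lm.label_table))
        maps.append(lm)
    return maps


def simulate_meta_database(
    design: PlantedDesign,
    subnetwork_regions: dict[int, list[np.ndarray]],
    peak_noise_mm: float = 0.5,
    region_hit_fraction: float = 0.8,
    studies_per_subnetwork: int = 60,
    base_weight: float = 0.3,
    weight_sd: float = 0.1,
    exclusion_coords: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Neurosynth-layout database with planted term-subnetwork associations.

    Parameters
    ----------
    subnetwork_regions : dict
        Subnetwork label -> list of representative region coordinates (mm),
        one per region; use an actual region node so planted peaks land
        within the match radius. An "associated" study places peaks within
        ``peak_noise_mm`` of ``region_hit_fraction`` of one subnetwork's
        regions (so it matches at the <2 mm / 40%-of-regions criterion);
        every study also scatters background peaks far from
        ``exclusion_coords`` (default: all representative coordinates; pass
        the full node coordinate array to keep background peaks clear of
        extended regions).
    design.planted_terms : dict
        term name -> (subnetwork label, weight shift). Studies associated
        with that subnetwork receive weights elevated by the shift; all other
        weights are ``base_weight`` + noise, clipped to [0, 1].

    Returns
    -------
    (activations, features) DataFrames in the on-disk schema.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.rng_seed, 3]))
    sub_labels = sorted(subnetwork_regions)
    n_assoc = studies_per_subnetwork * len(sub_labels)
    if design.n_studies < n_assoc:
        raise ValueError(
            f"n_studies={design.n_studies} < {n_assoc} associated studies requested"
        )
    study_group: dict[int, int] = {}  # study -> subnetwork label (0 = unassociated)
    act_rows = []
    all_centroids = np.vstack([np.vstack(v) for v in subnetwork_regions.values()])
    avoid = all_centroids if exclusion_coords is None else np.asarray(exclusion_coords)
    lo = avoid.min(axis=0) - 80.0
    hi = avoid.max(axis=0) + 80.0
    for sid in range(design.n_studies):
        group = 0
        if sid < n_assoc:
            group = sub_labels[sid % len(sub_labels)]
        study_group[sid] = group
        if group:
            centroids = subnetwork_regions[group]
            n_hit = max(1, int(np.ceil(region_hit_fraction * len(centroids))))
            hit_idx = rng.choice(len(centroids), size=n_hit, replace=False)
            for ci in hit_idx:
                jitter = rng.normal(0, peak_noise_mm / 3.0, size=3)
                act_rows.append((sid, *(centroids[ci] + jitter)))
        # every study also reports background peaks far from the regions
        n_bg = int(rng.integers(3, 9))
        for _ in range(n_bg):
            while True:
                p = rng.uniform(lo, hi)
                if np.min(np.linalg.norm(avoid - p, axis=1)) > 15.0:
                    break
            act_rows.append((sid, *p))
    activations = pd.DataFrame(act_rows, columns=["study_id", "x", "y", "z"])

    terms = [f"term_{t:03d}" for t in range(design.n_terms)]
    planted = dict(design.planted_terms)
    # planted term names replace the first len(planted) generic names
    for i, name in enumerate(planted):
        terms[i] = name
    weights = np.clip(
        rng.normal(base_weight, weight_sd, size=(design.n_studies, design.n_terms)),
        0.0,
        1.0,
    )
    groups = np.array([study_group[s] for s in range(design.n_studies)])
    for j, name in enumerate(terms):
        if name in planted:
            target, shift = planted[name]
            weights[groups == target, j] = np.clip(
                weights[groups == target, j] + shift, 0.0, 1.0
            )
    features = pd.DataFrame(weights, columns=terms)
    features.insert(0, "study_id", np.arange(design.n_studies))
    return activations, features


def simulate_task_maps(
    design: PlantedDesign,
    truth: LabelMap,
    effects: dict[str, dict[int, float]],
    noise_sd: float = 1.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-condition, per-subject z-maps: planted subnetwork effect + noise.

    ``effects`` maps condition name -> {subnetwork label: mean z}. Returns
    ``{condition: {subject_id: z_map}}``; identical seeds give identical maps.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for c, cond in enumerate(sorted(effects)):
        per_subj = {}
        for s in range(design.n_subjects):
            rng = np.random.default_rng(
                np.random.SeedSequence([design.rng_seed, 4, c, s])
            )
            zmap = rng.normal(0.0, noise_sd, size=truth.n_nodes)
            for label, mean in effects[cond].items():
                zmap[truth.labels == label] += mean
            per_subj[f"sub-{s:02d}"] = zmap
        out[cond] = per_subj
    return out
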