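"""Analysis configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Pipeline constants with their conventional defaults.

    Attributes
    ----------
    subnetwork_density : float
        Graph density used at the subnetwork-detection tier; each row/column of
        the connectivity matrix retains this top fraction of its values
        (0.001 = the top 0.1%).
    network_density : float
        Denser tier used to delineate large-scale networks. Must exceed the
        subnetwork block size as a fraction of N so that the graph bridges
        sibling subnetworks; 0.30 does so at every scale this toolkit runs
        at (very large cortical matrices can use much lower values).
    jaccard_binarize : bool
        Compute overlap between subnetwork node sets as plain (binary) Jaccard.
    min_subject_fraction : float
        Matched clusters represented in fewer than this fraction of subjects
        are discarded (half-of-subjects rule).
    densitymap_min_subjects : int
        Minimum subject count when thresholding a density map in
        ``min_subjects`` mode.
    region_fraction_threshold : float
        Fraction-of-subjects threshold (strict >) used to binarize density
        maps before region extraction.
    peak_match_radius_mm : float
        A study activation peak "hits" a region when it lies strictly closer
        than this distance (mm) to any node of the region.
    region_match_fraction : float
        A study matches a subnetwork when it hits at least this fraction of
        the subnetwork's regions.
    short_distance_mm : float
        Node pairs closer than this (mm, Euclidean) are excluded from
        connectivity estimates to suppress shared local signal.
    min_cluster_area_mm2 : float
        Connected components smaller than this surface area are dropped when
        extracting regions / graph nodes.
    graph_density : float
        Starting edge density for spring-graph export.
    graph_density_step : float
        Increment applied when a declared network is disconnected at the
        current graph density.
    peak_density_radius_mm : float
        Radius for the per-node activation-peak density census.
    fdr_alpha : float
        Benjamini-Hochberg false-discovery level for term tests.
    max_lag_s : float
        Lagged cross-covariance search window half-width, seconds.
    lag_band_hz : tuple
        Band-pass applied before lag estimation, Hz. ``(0.01, 0.1)`` is the
        conventional infraslow band; ``(0.08, 0.1)`` is also meaningful and
        selectable.
    lag_min_abs_r : float
        Minimum |r| at the cross-covariance extremum for a node's delay to be
        considered valid.
    min_community_size : int
        Communities smaller than this are relabeled 0 (unassigned).
    parent_overlap_fraction : float
        A community counts as "represented within" the parent network when at
        least this fraction of its nodes fall inside the parent mask.
    r_max : float
        Correlations are clipped to +/- this bound before the Fisher
        transform (arctanh diverges at |r| = 1).
    rng_seed : int
        Seed for every stochastic stage.
    """

    subnetwork_density: float = 0.001
    network_density: float = 0.30
    jaccard_binarize: bool = True
    min_subject_fraction: float = 0.5
    densitymap_min_subjects: int = 3
    region_fraction_threshold: float = 0.10
    peak_match_radius_mm: float = 2.0
    region_match_fraction: float = 0.40
    short_distance_mm: float = 20.0
    min_cluster_area_mm2: float = 20.0
    graph_density: float = 0.10
    graph_density_step: float = 0.05
    peak_density_radius_mm: float = 4.0
    fdr_alpha: float = 0.05
    max_lag_s: float = 8.0
    lag_band_hz: tuple = (0.01, 0.1)
    lag_min_abs_r: float = 0.1
    min_community_size: int = 10
    parent_overlap_fraction: float = 0.5
    r_max: float = 0.999999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "subnetwork_density",
            "network_density",
            "min_subject_fraction",
            "region_fraction_threshold",
            "region_match_fraction",
            "graph_density",
            "graph_density_step",
            "fdr_alpha",
            "parent_overlap_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        for name in (
            "peak_match_radius_mm",
            "short_distance_mm",
            "peak_density_radius_mm",
            "max_lag_s",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        lo, hi = self.lag_band_hz
        if not (0 < lo < hi):
            raise ValueError(f"lag_band_hz must satisfy 0 < low < high, got {self.lag_band_hz!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lag_band_hz"] = list(self.lag_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "lag_band_hz" in d:
            d["lag_band_hz"] = tuple(d["lag_band_hz"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
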