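"""Infraslow signal-lag estimation between brain structures.

The estimator follows the lagged cross-covariance approach: signals are
band-pass filtered, the cross-covariance between a seed's mean time course
and each node is evaluated at integer-frame lags within a window, and a
three-point parabolic fit around the extremum of |cov| gives a sub-frame
delay. Positive delay means the node's signal lags (comes after) the seed.
Runs are processed separately and combined by frame-weighted average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from subnets.config import AnalysisConfig
from subnets.spaces import Timeseries

logger = logging.getLogger(__name__)


@dataclass
class LagMap:
    """Per-node delay (seconds) relative to a seed structure."""

    seed_id: str
    delay_s: np.ndarray
    valid: np.ndarray
    peak_r: np.ndarray
    anticorrelated: np.ndarray


@dataclass
class OrderingResult:
    """Group-level temporal ordering of structures."""

    mean_delay_s: dict[str, float]  # centered: mean over structures is 0
    per_subject: dict[str, dict[str, float]]
    f_stat: float
    df: tuple[int, int]
    p: float
    post_hoc: list[tuple[tuple[str, str], float, int, float]]


def bandpass(ts: Timeseries, band_hz: tuple[float, float], order: int = 2) -> Timeseries:
    """Zero-phase Butterworth band-pass, applied within each run separately."""
    lo, hi = band_hz
    nyq = 0.5 / ts.tr
    if hi >= nyq:
        raise ValueError(f"band upper edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    out = np.empty_like(ts.values)
    for sl in ts.run_slices():
        seg = ts.values[:, sl]
        out[:, sl] = sps.sosfiltfilt(sos, seg - seg.mean(axis=1, keepdims=True), axis=1)
    return Timeseries(
        subject_id=ts.subject_id,
        values=out,
        tr=ts.tr,
        run_boundaries=ts.run_boundaries,
    )


def lagged_delay(
    x: np.ndarray,
    y: np.ndarray,
    tr: float,
    max_lag_s: float = 8.0,
) -> tuple[float, float, bool]:
    """Delay of ``y`` relative to ``x`` by interpolated lagged cross-covariance.

    Cross-covariance is evaluated at integer-frame lags tau in
    [-max_lag, +max_lag]; the extremum of |cov| and its two neighbors are fit
    with a parabola, giving a sub-frame delay in seconds. Positive when y
    lags x (y(t) ~ x(t - delay)).

    Returns
    -------
    (delay_s, r_at_extremum, valid)
        ``valid`` is False when the extremum sits at the window edge (the
        parabolic fit is then meaningless and the true extremum may lie
        outside the window).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    max_lag = int(round(max_lag_s / tr))
    if len(x) < 3 * max_lag:
        raise ValueError(f"need >= {3 * max_lag} frames for max_lag {max_lag_s} s")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return 0.0, 0.0, False
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.empty(len(lags))
    for i, tau in enumerate(lags):
        # c(tau) = sum_t x(t) y(t + tau): peaks at tau = +d when y(t) = x(t-d)
        if tau >= 0:
            cc[i] = x[: len(x) - tau] @ y[tau:]
        else:
            cc[i] = x[-tau:] @ y[: len(y) + tau]
    cc /= denom
    i0 = int(np.argmax(np.abs(cc)))
    r_peak = float(cc[i0])
    if i0 == 0 or i0 == len(lags) - 1:
        return float(lags[i0] * tr), r_peak, False
    ym, y0, yp = np.abs(cc[i0 - 1]), np.abs(cc[i0]), np.abs(cc[i0 + 1])
    denom_p = ym - 2 * y0 + yp
    frac = 0.0 if denom_p == 0 else 0.5 * (ym - yp) / denom_p
    return float((lags[i0] + frac) * tr), r_peak, True


def seed_lag_map(
    ts: Timeseries,
    seed_nodes: frozenset[int] | set[int],
    config: AnalysisConfig | None = None,
    prefilter: bool = True,
) -> LagMap:
    """Per-node delay relative to the seed subnetwork's mean time course.

    Nodes whose |r| at the cross-covariance extremum falls below
    ``config.lag_min_abs_r``, or whose extremum sits at the window edge, are
    masked invalid. Anticorrelated nodes (negative r at the extremum) keep
    their delay but are flagged. Multiple runs are estimated separately and
    combined by frame-weighted average (a node is valid if valid in every
    run).
    """
    config = config or AnalysisConfig()
    if not seed_nodes:
        raise ValueError("empty seed")
    work = bandpass(ts, config.lag_band_hz) if prefilter else ts
    n = work.n_nodes
    delays = np.zeros(n)
    peak_r = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    seed_idx = sorted(seed_nodes)
    slices = work.run_slices()
    weights = np.array([sl.stop - sl.start for sl in slices], dtype=float)
    weights /= weights.sum()
    per_run_delay = np.zeros((len(slices), n))
    per_run_r = np.zeros((len(slices), n))
    for ri, sl in enumerate(slices):
        seed_sig = work.values[seed_idx, sl].mean(axis=0)
        for node in range(n):
            d, r, ok = lagged_delay(
                seed_sig, work.values[node, sl], work.tr, config.max_lag_s
            )
            per_run_delay[ri, node] = d
            per_run_r[ri, node] = r
            if not ok or abs(r) < config.lag_min_abs_r:
                valid[node] = False
    delays = weights @ per_run_delay
    peak_r = weights @ per_run_r
    anticorr = peak_r < 0
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("subject %s: %d/%d nodes masked invalid", ts.subject_id, n_invalid, n)
    return LagMap(
        seed_id=ts.subject_id,
        delay_s=delays,
        valid=valid,
        peak_r=peak_r,
        anticorrelated=anticorr,
    )


def structure_mean_delays(
    lag_maps: list[LagMap], structures: dict[str, frozenset[int]]
) -> dict[str, float]:
    """Average delay over valid nodes within each structure, then over seed maps."""
    out = {}
    for name, nodes in structures.items():
        per_map = []
        idx = sorted(nodes)
        for lm in lag_maps:
            ok = lm.valid[idx]
            if ok.any():
                per_map.append(float(lm.delay_s[idx][ok].mean()))
        out[name] = float(np.mean(per_map)) if per_map else float("nan")
    return out


def group_ordering(
    per_subject_maps: dict[str, list[LagMap]],
    structures: dict[str, frozenset[int]],
) -> OrderingResult:
    """Group-level temporal ordering of structures from per-subject lag maps.

    Per subject: delays are averaged over each structure's valid nodes, then
    over that subject's seed lag maps, then centered (the zero point of a lag
    map is arbitrary, so only relative ordering is meaningful). A one-way
    ANOVA across structures with subjects as observations tests for any
    ordering; paired t tests give the pairwise ordering.
    """
    from subnets.mana import one_way_anova
    from subnets.profiling import post_hoc_paired

    names = sorted(structures)
    per_subject: dict[str, dict[str, float]] = {}
    for subj, maps in per_subject_maps.items():
        means = structure_mean_delays(maps, structures)
        vals = np.array([means[n] for n in names])
        center = np.nanmean(vals)
        per_subject[subj] = {n: float(means[n] - center) for n in names}
    groups = []
    for n in names:
        groups.append(
            np.array(
                [per_subject[s][n] for s in sorted(per_subject)
                 if not np.isnan(per_subject[s][n])]
            )
        )
    f, df, p = one_way_anova(groups)
    mean_delay = {n: float(np.nanmean(g)) for n, g in zip(names, groups)}
    grand = np.mean(list(mean_delay.values()))
    mean_delay = {n: v - grand for n, v in mean_delay.items()}
    per_level = {
        n: {s: per_subject[s][n] for s in per_subject if not np.isnan(per_subject[s][n])}
        for n in names
    }
    return OrderingResult(
        mean_delay_s=mean_delay,
        per_subject=per_subject,
        f_stat=f,
        df=df,
        p=p,
        post_hoc=post_hoc_paired(per_level),
    )
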