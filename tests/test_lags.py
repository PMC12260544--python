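"""Band-pass filtering, lagged-delay estimation, lag maps, group ordering."""

import numpy as np
import pytest

from subnets.config import AnalysisConfig
from subnets.lags import (
    bandpass,
    group_ordering,
    lagged_delay,
    seed_lag_map,
    structure_mean_delays,
)
from subnets.spaces import Timeseries
from subnets.synthetic import PlantedDesign, simulate_timeseries


def _tone(freq_hz, n=1200, tr=1.0):
    return np.sin(2 * np.pi * freq_hz * np.arange(n) * tr)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        ts = Timeseries("s", _tone(0.05)[None, :], tr=1.0)
        out = bandpass(ts, (0.01, 0.1))
        # FFT amplitude at the tone frequency within 5% of input
        in_amp = np.abs(np.fft.rfft(ts.values[0]))
        out_amp = np.abs(np.fft.rfft(out.values[0]))
        k = np.argmax(in_amp)
        assert out_amp[k] == pytest.approx(in_amp[k], rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        ts = Timeseries("s", _tone(0.2)[None, :], tr=1.0)
        out = bandpass(ts, (0.01, 0.1))
        assert out.values.std() <= 0.1 * ts.values.std()

    def test_zero_signal_stays_zero(self):
        ts = Timeseries("s", np.zeros((2, 300)), tr=1.0)
        out = bandpass(ts, (0.01, 0.1))
        assert np.allclose(out.values, 0)

    def test_band_above_nyquist_rejected(self):
        ts = Timeseries("s", np.zeros((1, 100)), tr=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, (0.01, 0.3))

    def test_runs_filtered_independently(self, rng):
        v = rng.standard_normal((2, 400))
        joint = bandpass(Timeseries("s", v, tr=1.0), (0.01, 0.1))
        split = bandpass(Timeseries("s", v, tr=1.0, run_boundaries=(0, 200)), (0.01, 0.1))
        # first run of the split version equals filtering the first half alone
        alone = bandpass(Timeseries("s", v[:, :200], tr=1.0), (0.01, 0.1))
        assert np.allclose(split.values[:, :200], alone.values)
        assert not np.allclose(split.values, joint.values)


class TestLaggedDelay:
    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(0)
        x = np.convolve(rng.standard_normal(1300), np.ones(12) / 12, mode="same")
        y = np.roll(x, 3)[:1200]
        d, r, ok = lagged_delay(x[:1200], y, tr=1.0, max_lag_s=8.0)
        assert ok
        assert d == pytest.approx(3.0, abs=0.1)
        assert r > 0.9

    def test_identity_zero(self, rng):
        x = rng.standard_normal(600)
        d, r, ok = lagged_delay(x, x, tr=1.0)
        assert ok and r == pytest.approx(1.0)
        assert d == pytest.approx(0.0, abs=0.1)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        x = np.convolve(rng.standard_normal(900), np.ones(10) / 10, mode="same")
        y = np.roll(x, 2)
        d_xy, _, _ = lagged_delay(x, y, tr=1.0)
        d_yx, _, _ = lagged_delay(y, x, tr=1.0)
        assert d_xy == pytest.approx(-d_yx, abs=0.05)

    def test_extremum_at_window_edge_invalid(self):
        rng = np.random.default_rng(3)
        x = np.convolve(rng.standard_normal(700), np.ones(20) / 20, mode="same")
        y = np.roll(x, 12)  # true lag beyond the 8 s window
        d, _, ok = lagged_delay(x[:600], y[:600], tr=1.0, max_lag_s=8.0)
        assert not ok

    def test_parabolic_beats_integer_argmax(self):
        # fractional shifts on a smooth signal: interpolation strictly
        # reduces mean absolute quantization error
        t = np.arange(2000)
        errs_int, errs_par = [], []
        for true in (0.3, 0.7, 1.2, 1.6, 2.4):
            x = np.sin(2 * np.pi * t / 40)
            y = np.sin(2 * np.pi * (t - true) / 40)
            d, _, ok = lagged_delay(x, y, tr=1.0, max_lag_s=8.0)
            assert ok
            errs_par.append(abs(d - true))
            errs_int.append(abs(round(true) - true))
        assert np.mean(errs_par) < np.mean(errs_int)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lagged_delay(np.zeros(10), np.zeros(10), tr=1.0, max_lag_s=8.0)


class TestSeedLagMap:
    @pytest.fixture
    def lagged_design(self):
        return PlantedDesign(
            n_nodes=60, n_networks=3, subnetworks_per_network=1,
            planted_lags={"net1": -1.0, "net2": 0.0, "net3": 1.0},
            lag_snr=1.0, rng_seed=21,
        )

    def test_seed_on_itself_near_zero(self, lagged_design):
        ts = simulate_timeseries(lagged_design, 0, n_frames=800)
        net = lagged_design.network_labels()
        seed = frozenset(np.flatnonzero(net == 2).tolist())
        lm = seed_lag_map(ts, seed, AnalysisConfig())
        own = lm.delay_s[sorted(seed)][lm.valid[sorted(seed)]]
        assert abs(own.mean()) < 0.15

    def test_planted_signs_recovered(self, lagged_design):
        ts = simulate_timeseries(lagged_design, 0, n_frames=800)
        net = lagged_design.network_labels()
        seed = frozenset(np.flatnonzero(net == 2).tolist())
        lm = seed_lag_map(ts, seed, AnalysisConfig())
        early = lm.delay_s[net == 1][lm.valid[net == 1]].mean()
        late = lm.delay_s[net == 3][lm.valid[net == 3]].mean()
        assert early < -0.5 and late > 0.5

    def test_low_correlation_nodes_masked(self, rng):
        # seed uncorrelated with a pure-noise node: that node is invalid
        v = rng.standard_normal((3, 800))
        v[1] = v[0] * 0.9 + 0.1 * rng.standard_normal(800)
        ts = Timeseries("s", v, tr=1.0)
        lm = seed_lag_map(ts, {0}, AnalysisConfig(lag_min_abs_r=0.4))
        assert lm.valid[1]
        assert not lm.valid[2]


class TestGroupOrdering:
    def _maps_for(self, delays_by_structure, structures, n_subjects=6, noise=0.05):
        rng = np.random.default_rng(9)
        per_subject = {}
        n_nodes = max(max(v) for v in structures.values()) + 1
        from subnets.lags import LagMap
        for s in range(n_subjects):
            delay = np.zeros(n_nodes)
            for name, nodes in structures.items():
                delay[sorted(nodes)] = delays_by_structure[name] + rng.normal(0, noise)
            per_subject[f"s{s}"] = [LagMap(
                seed_id=f"s{s}", delay_s=delay, valid=np.ones(n_nodes, bool),
                peak_r=np.ones(n_nodes), anticorrelated=np.zeros(n_nodes, bool))]
        return per_subject

    def test_identical_delays_f_zero_like(self):
        structures = {"a": frozenset({0, 1}), "b": frozenset({2, 3})}
        maps = self._maps_for({"a": 0.5, "b": 0.5}, structures, noise=0.0)
        # zero within-group variance after centering -> ANOVA degenerate
        with pytest.raises(ZeroDivisionError):
            group_ordering(maps, structures)

    def test_planted_ordering_recovered(self):
        structures = {"a": frozenset({0, 1}), "b": frozenset({2, 3}),
                      "c": frozenset({4, 5})}
        maps = self._maps_for({"a": -0.5, "b": 0.0, "c": 0.5}, structures,
                              n_subjects=15)
        res = group_ordering(maps, structures)
        assert res.p < 0.05
        order = sorted(res.mean_delay_s, key=res.mean_delay_s.get)
        assert order == ["a", "b", "c"]
        assert all(p < 0.05 for _, _, _, p in res.post_hoc)

    def test_centering(self):
        structures = {"a": frozenset({0}), "b": frozenset({1}), "c": frozenset({2})}
        maps = self._maps_for({"a": 1.0, "b": 2.0, "c": 3.0}, structures)
        res = group_ordering(maps, structures)
        assert sum(res.mean_delay_s.values()) == pytest.approx(0.0, abs=1e-9)
        for subj_vals in res.per_subject.values():
            assert sum(subj_vals.values()) == pytest.approx(0.0, abs=1e-9)


def test_structure_mean_delays_skips_invalid():
    from subnets.lags import LagMap

    lm = LagMap("s", delay_s=np.array([1.0, 2.0, 9.0]),
                valid=np.array([True, True, False]),
                peak_r=np.ones(3), anticorrelated=np.zeros(3, bool))
    out = structure_mean_delays([lm], {"x": frozenset({0, 1, 2})})
    assert out["x"] == pytest.approx(1.5)
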