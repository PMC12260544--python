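"""Region extraction, study matching, term ANOVA, FDR, peak density."""

import numpy as np
import pandas as pd
import pytest

from subnets.mana import (
    annotate_terms,
    extract_regions,
    fdr_correct,
    match_studies,
    one_way_anova,
    peak_density_map,
    term_anova,
    term_filter,
)
from subnets.synthetic import grid_nodespace


def brute_force_bh(p, alpha):
    """Independent step-up oracle: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestOneWayAnova:
    def test_hand_computed_f(self):
        # SSB = 14, SSW = 6 -> F = (14/2)/(6/6) = 7.0 on df (2, 6)
        f, df, p = one_way_anova([np.array([1, 2, 3]), np.array([2, 3, 4]),
                                  np.array([4, 5, 6])])
        assert f == pytest.approx(7.0, abs=1e-10)
        assert df == (2, 6)

    def test_matches_scipy(self, rng):
        from scipy.stats import f_oneway

        groups = [rng.normal(i, 1, 10) for i in range(3)]
        f, _, p = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            one_way_anova([np.array([1.0, 1.0]), np.array([1.0, 1.0])])

    def test_label_permutation_preserves_null_f_distribution(self, rng):
        # under exchangeability, permuting group labels leaves F's
        # distribution unchanged: compare medians over many draws
        pooled = rng.normal(0, 1, 30)
        f_orig = []
        f_perm = []
        for _ in range(200):
            x = rng.permutation(pooled)
            f_orig.append(one_way_anova([x[:10], x[10:20], x[20:]])[0])
            y = rng.permutation(pooled)
            f_perm.append(one_way_anova([y[:10], y[10:20], y[20:]])[0])
        assert abs(np.median(f_orig) - np.median(f_perm)) < 0.5


class TestFdr:
    def test_known_rejections(self):
        q, reject = fdr_correct(np.array([0.001, 0.02, 0.03, 0.2]), alpha=0.05)
        assert reject.tolist() == [True, True, True, False]
        assert np.array_equal(reject, brute_force_bh([0.001, 0.02, 0.03, 0.2], 0.05))

    def test_all_ones_no_rejection(self):
        _, reject = fdr_correct(np.ones(5), alpha=0.05)
        assert not reject.any()

    def test_single_p_q_equals_p(self):
        q, _ = fdr_correct(np.array([0.03]), alpha=0.05)
        assert q[0] == pytest.approx(0.03)

    def test_matches_brute_force_on_random_p(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 15)
            _, reject = fdr_correct(p, alpha=0.05)
            assert np.array_equal(reject, brute_force_bh(p, 0.05))

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 50)
        q, _ = fdr_correct(p)
        assert (q >= p - 1e-12).all()


class TestExtractRegions:
    def test_single_blob(self, small_space):
        regions = extract_regions(frozenset({0, 1, 5, 6}), small_space, min_area_mm2=20)
        assert len(regions) == 1
        assert regions[0].nodes == frozenset({0, 1, 5, 6})
        assert regions[0].area_mm2 == pytest.approx(4 * 36.0)

    def test_two_separated_blobs(self, small_space):
        regions = extract_regions(frozenset({0, 1, 23, 24}), small_space, min_area_mm2=20)
        assert len(regions) == 2
        assert {frozenset(r.nodes) for r in regions} == {frozenset({0, 1}), frozenset({23, 24})}

    def test_small_area_dropped(self, small_space):
        # single 36 mm^2 node passes min 20; pretend nodes are 15 mm^2
        space = grid_nodespace(25, spacing_mm=np.sqrt(15))
        regions = extract_regions(frozenset({0}), space, min_area_mm2=20)
        assert regions == []

    def test_empty_set_raises(self, small_space):
        with pytest.raises(ValueError):
            extract_regions(frozenset(), small_space, 20)


class TestMatchStudies:
    @pytest.fixture
    def five_regions(self, medium_space):
        # five well-separated single-node regions on the 400-node grid
        nodes = [0, 19, 200, 380, 399]
        regions = extract_regions(frozenset(nodes), medium_space, min_area_mm2=20)
        assert len(regions) == 5
        return regions

    def _study(self, coords):
        return pd.DataFrame(
            [{"study_id": 0, "x": x, "y": y, "z": z} for x, y, z in coords]
        )

    def test_two_of_five_matches_at_40pc(self, five_regions, medium_space):
        hits = [five_regions[0].centroid, five_regions[1].centroid]
        matched = match_studies(self._study(hits), five_regions, medium_space,
                                radius_mm=2.0, fraction=0.40)
        assert matched == [0]

    def test_one_of_five_does_not_match(self, five_regions, medium_space):
        matched = match_studies(self._study([five_regions[0].centroid]),
                                five_regions, medium_space, 2.0, 0.40)
        assert matched == []

    def test_peak_exactly_at_node_is_hit(self, five_regions, medium_space):
        # distance 0 < 2 mm: counts
        hits = [five_regions[i].centroid for i in (0, 1)]
        matched = match_studies(self._study(hits), five_regions, medium_space, 2.0, 0.4)
        assert matched == [0]

    def test_strict_distance(self, five_regions, medium_space):
        # peaks exactly radius_mm away do not count (< is strict)
        off = [c + np.array([2.0, 0, 0]) for c in
               (five_regions[0].centroid, five_regions[1].centroid)]
        matched = match_studies(self._study(off), five_regions, medium_space, 2.0, 0.4)
        assert matched == []

    def test_monotone_in_radius_and_fraction(self, five_regions, medium_space, rng):
        peaks = self._study(rng.uniform(0, 120, (12, 3)))
        base = set(match_studies(peaks, five_regions, medium_space, 4.0, 0.4))
        wider = set(match_studies(peaks, five_regions, medium_space, 8.0, 0.4))
        looser = set(match_studies(peaks, five_regions, medium_space, 4.0, 0.2))
        assert base <= wider and base <= looser


class TestTermAnova:
    def test_assignment_to_argmax_mean(self):
        features = pd.DataFrame({
            "study_id": range(6),
            "t": [0.1, 0.2, 0.15, 0.8, 0.9, 0.85],
        })
        matches = {1: [0, 1, 2], 2: [3, 4, 5]}
        res = term_anova(features, matches, "t")
        assert res.assigned_subnetwork == 2
        assert res.magnitude == pytest.approx(
            np.mean([0.8, 0.9, 0.85]) - np.mean(features["t"]))
        assert res.p < 0.01

    def test_degenerate_grouping_skipped(self):
        features = pd.DataFrame({"study_id": [0, 1, 2], "t": [0.5, 0.5, 0.5]})
        assert term_anova(features, {1: [0], 2: [1, 2]}, "t") is None
        # constant weights across both groups: zero variance -> skipped
        features2 = pd.DataFrame({"study_id": range(4), "t": [0.5] * 4})
        assert term_anova(features2, {1: [0, 1], 2: [2, 3]}, "t") is None

    def test_multi_match_study_contributes_to_both(self):
        features = pd.DataFrame({"study_id": range(4), "t": [0.2, 0.4, 0.6, 0.8]})
        res = term_anova(features, {1: [0, 1, 2], 2: [2, 3]}, "t")
        assert res.group_means[2] == pytest.approx(0.7)
        assert res.group_means[1] == pytest.approx(0.4)


class TestAnnotateTerms:
    def test_planted_terms_assigned_to_true_group(self, rng):
        n = 80
        features = pd.DataFrame({
            "study_id": range(n),
            "planted": np.clip(np.r_[rng.normal(0.6, 0.1, 40),
                                     rng.normal(0.3, 0.1, 40)], 0, 1),
            "null": np.clip(rng.normal(0.3, 0.1, n), 0, 1),
        })
        matches = {1: list(range(40)), 2: list(range(40, 80))}
        results = annotate_terms(features, matches, alpha=0.05)
        by_term = {r.term: r for r in results}
        assert by_term["planted"].significant
        assert by_term["planted"].assigned_subnetwork == 1


class TestPeakDensity:
    def test_empty_db_all_zero(self, small_space):
        counts = peak_density_map(pd.DataFrame(columns=["study_id", "x", "y", "z"]),
                                  small_space, 4.0)
        assert (counts == 0).all()

    def test_single_peak_counts_at_node(self, small_space):
        db = pd.DataFrame([{"study_id": 0, "x": 0.0, "y": 0.0, "z": 0.0}])
        counts = peak_density_map(db, small_space, 4.0)
        assert counts[0] == 1
        assert counts.sum() == 1  # 6 mm grid: only the origin node is within 4 mm

    def test_matches_exhaustive_census(self, small_space, rng):
        peaks = rng.uniform(-5, 30, (40, 3))
        db = pd.DataFrame(peaks, columns=["x", "y", "z"])
        db.insert(0, "study_id", range(40))
        counts = peak_density_map(db, small_space, 4.0)
        for i in range(small_space.n_nodes):
            d = np.linalg.norm(peaks - small_space.coords[i], axis=1)
            assert counts[i] == (d <= 4.0).sum()


class TestTermFilter:
    def test_empty_exclude_identity(self):
        assert term_filter(["a", "b"]) == ["a", "b"]

    def test_exclusion_applied(self):
        assert term_filter(["memory", "male", "effort"], exclude=["male"]) == \
            ["memory", "effort"]

    def test_duplicates_collapsed(self):
        assert term_filter(["a", "b", "a"]) == ["a", "b"]

    def test_include_whitelist(self):
        assert term_filter(["a", "b", "c"], include=["b", "c"], exclude=["c"]) == ["b"]
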