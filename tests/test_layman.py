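"""Community-wide niche metrics: geometry and posterior propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull

import isoniche as iso


def fan_area_oracle(points: np.ndarray) -> float:
    """Independent hull-area oracle: scipy hull vertices, fan triangulation
    from the first vertex, summed triangle areas."""
    try:
        hull = ConvexHull(points)
    except Exception:  # degenerate (collinear) input
        return 0.0
    v = points[hull.vertices]
    o = v[0]
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b = v[i] - o, v[i + 1] - o
        total += 0.5 * abs(a[0] * b[1] - a[1] * b[0])
    return total


class TestHullArea:
    def test_right_triangle_and_unit_square(self):
        assert iso.convex_hull_area([(0, 0), (1, 0), (0, 1)]) == pytest.approx(0.5)
        assert iso.convex_hull_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(1.0)

    def test_interior_points_do_not_change_area(self):
        square = [(0, 0), (2, 0), (2, 2), (0, 2), (1.0, 1.0), (0.5, 1.5)]
        assert iso.convex_hull_area(square) == pytest.approx(4.0)

    def test_collinear_points_give_zero(self):
        assert iso.convex_hull_area([(0, 0), (1, 1), (2, 2), (3, 3)]) == 0.0

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            iso.convex_hull_area([(0, 0), (1, 1)])

    @settings(derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 10 ** 6), n=st.integers(3, 40))
    def test_matches_independent_fan_oracle(self, seed, n):
        pts = np.random.default_rng(seed).normal(size=(n, 2)) * [2.0, 3.0]
        assert iso.convex_hull_area(pts) == pytest.approx(
            fan_area_oracle(pts), abs=1e-9)


class TestRangesAndCentroid:
    def test_ranges_are_plain_extrema_differences(self):
        pts = [(-18, 12), (-16, 15), (-17, 13)]
        assert iso.nitrogen_range(pts) == pytest.approx(3.0)
        assert iso.carbon_range(pts) == pytest.approx(2.0)

    def test_duplicated_single_point_has_zero_ranges(self):
        pts = [(-17.0, 13.0)] * 4
        assert iso.nitrogen_range(pts) == 0.0
        assert iso.carbon_range(pts) == 0.0
        assert iso.centroid_distance(pts) == 0.0

    def test_two_points_two_apart_have_unit_centroid_distance(self):
        assert iso.centroid_distance([(0, 0), (0, 2)]) == pytest.approx(1.0)

    def test_equilateral_triangle_cd_is_circumradius(self):
        s = 2.5
        pts = [(0, 0), (s, 0), (s / 2, s * np.sqrt(3) / 2)]
        assert iso.centroid_distance(pts) == pytest.approx(s / np.sqrt(3))

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10 ** 6),
           dx=st.floats(-50, 50), dy=st.floats(-50, 50),
           c=st.floats(min_value=0.1, max_value=10.0))
    def test_translation_invariance_and_scaling(self, seed, dx, dy, c):
        pts = np.random.default_rng(seed).normal(size=(8, 2))
        moved = pts + [dx, dy]
        assert iso.nitrogen_range(moved) == pytest.approx(iso.nitrogen_range(pts), abs=1e-9)
        assert iso.carbon_range(moved) == pytest.approx(iso.carbon_range(pts), abs=1e-9)
        assert iso.centroid_distance(moved) == pytest.approx(
            iso.centroid_distance(pts), abs=1e-9)
        assert iso.convex_hull_area(moved) == pytest.approx(
            iso.convex_hull_area(pts), abs=1e-9)
        assert iso.convex_hull_area(pts * c) == pytest.approx(
            c ** 2 * iso.convex_hull_area(pts), rel=1e-9)
        assert iso.centroid_distance(pts * c) == pytest.approx(
            c * iso.centroid_distance(pts), rel=1e-9)


def _posterior_at(mu, spread, n_draws, seed, label="sp"):
    """Niche posterior stub with mean draws around mu (for community tests)."""
    rng = np.random.default_rng(seed)
    mu_draws = np.asarray(mu, float) + spread * rng.standard_normal((n_draws, 2))
    sigma = np.tile(np.eye(2) * max(spread, 1e-6) ** 2, (n_draws, 1, 1))
    sea = np.full(n_draws, np.pi * max(spread, 1e-6) ** 2)
    return iso.NichePosterior(label=label, n=10, mu_draws=mu_draws,
                              sigma_draws=sigma, sea_draws=sea,
                              sea_c_draws=sea * 9 / 8, seed=seed)


class TestCommunityPosterior:
    def test_degenerate_community_has_near_zero_metrics(self):
        posts = [_posterior_at((-17, 13), 1e-6, 400, s, f"sp{s}") for s in range(3)]
        c = iso.community_posterior("MPA", posts)
        assert np.all(c.ta_draws < 1e-9)
        assert np.all(c.nr_draws < 1e-4) and np.all(c.cd_draws < 1e-4)

    def test_large_n_concentrates_on_true_mean_hull(self):
        # true means (0,0), (2,0), (0,2): TA = 2, NR = CR = 2
        posts = [_posterior_at(m, 0.02, 2000, i, f"sp{i}")
                 for i, m in enumerate([(0, 0), (2, 0), (0, 2)])]
        c = iso.community_posterior("A", posts)
        assert np.median(c.ta_draws) == pytest.approx(2.0, abs=0.05)
        assert np.median(c.nr_draws) == pytest.approx(2.0, abs=0.05)
        assert np.median(c.cr_draws) == pytest.approx(2.0, abs=0.05)

    def test_metrics_invariant_under_species_relabeling(self):
        posts = [_posterior_at(m, 0.3, 500, 7 + i, f"sp{i}")
                 for i, m in enumerate([(0, 0), (2, 1), (1, 3)])]
        a = iso.community_posterior("A", posts)
        b = iso.community_posterior("A", posts[::-1])
        np.testing.assert_allclose(a.ta_draws, b.ta_draws)
        np.testing.assert_allclose(a.cd_draws, b.cd_draws)

    def test_hull_inside_bounding_box_on_every_draw(self, h3_dataset):
        _, records, _ = h3_dataset
        cfg = iso.RunConfig(seed=2, n_draws=400)
        posts = iso.fit_all_groups(records, cfg)
        for area in ("MPA", "Fished North", "Fished South"):
            group = [p for (sp, ar), p in posts.items() if ar == area]
            c = iso.community_posterior(area, group)
            assert np.all(c.ta_draws <= c.nr_draws * c.cr_draws + 1e-9)
            # CD never exceeds the maximal pairwise spread
            assert np.all(c.cd_draws <= np.hypot(c.cr_draws, c.nr_draws))

    def test_two_species_community_lacks_ta_but_keeps_ranges(self):
        posts = [_posterior_at((0, 0), 0.1, 300, 1, "a"),
                 _posterior_at((1, 1), 0.1, 300, 2, "b")]
        c = iso.community_posterior("A", posts)
        assert c.ta_draws is None
        assert np.all(c.nr_draws >= 0)

    def test_mismatched_draw_counts_rejected(self):
        posts = [_posterior_at((0, 0), 0.1, 300, 1, "a"),
                 _posterior_at((1, 1), 0.1, 400, 2, "b")]
        with pytest.raises(iso.ConfigurationError):
            iso.community_posterior("A", posts)

    def test_individual_cd_mode_uses_fish_positions(self, h3_dataset):
        _, records, _ = h3_dataset
        cfg = iso.RunConfig(seed=2, n_draws=200)
        posts = [p for (sp, ar), p in iso.fit_all_groups(records, cfg).items()
                 if ar == "MPA"]
        c_sp = iso.community_posterior("MPA", posts, records=records)
        c_ind = iso.community_posterior("MPA", posts, records=records,
                                        cd_mode="individual")
        # individual clouds are wider than the species-mean point set
        assert np.median(c_ind.cd_draws) > np.median(c_sp.cd_draws)


class TestPointEstimates:
    def test_hand_set_species_means_reproduce_hand_geometry(self):
        recs = []
        for sp, (c, n) in {"a": (0.0, 0.0), "b": (2.0, 0.0), "c": (0.0, 2.0)}.items():
            for i in range(2):
                recs.append(iso.IsotopeRecord(f"{sp}{i}", sp, "S1", "A", "fished",
                                              20.0, c, n))
        pt = iso.community_point_estimates("A", recs)
        assert pt["TA"] == pytest.approx(2.0)
        assert pt["NR"] == pytest.approx(2.0) and pt["CR"] == pytest.approx(2.0)

    def test_collinear_species_means_give_zero_ta(self):
        recs = [iso.IsotopeRecord(f"f{i}", f"sp{i}", "S1", "A", "fished",
                                  20.0, float(i), float(i))
                for i in range(4)]
        assert iso.community_point_estimates("A", recs)["TA"] == 0.0

    def test_point_estimates_match_posterior_medians_at_large_n(self):
        spec = iso.ScenarioSpec.from_hypothesis("H3", seed=5,
                                                fish_per_species_site=80)
        records, _ = iso.generate_isotope_dataset(spec)
        cfg = iso.RunConfig(seed=5, n_draws=600)
        posts = [p for (sp, ar), p in iso.fit_all_groups(records, cfg).items()
                 if ar == "MPA"]
        c = iso.community_posterior("MPA", posts)
        pt = iso.community_point_estimates("MPA", records)
        # TA carries a small upward max-statistic bias at finite posterior
        # width, noticeable because the species means are near-collinear
        assert np.median(c.ta_draws) == pytest.approx(pt["TA"], rel=0.2)
        assert np.median(c.nr_draws) == pytest.approx(pt["NR"], rel=0.1)
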