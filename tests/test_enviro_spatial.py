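"""IDW, LOOCV, forest-cover sampling, correlations and multiple testing,
each cross-checked against an independent direct-formula oracle."""

import numpy as np
import pandas as pd
import pytest

from palaeofeed.datamodel import Site
from palaeofeed.enviro_spatial import (
    IDWConfig,
    ProxyGrid,
    anova_oneway,
    build_isoscape,
    correlation_screen,
    haversine_km,
    idw_predict,
    loocv_select_power,
    mean_forest_cover_at_site,
    multiple_testing_adjust,
    pearson_test,
    spearman_test,
)

EUC = IDWConfig(metric="euclidean_deg")


def test_haversine_one_degree_of_latitude():
    assert haversine_km(10.0, 48.0, 10.0, 49.0) == pytest.approx(111.2, abs=0.3)


class TestIDW:
    def test_exact_at_data_point(self):
        v = idw_predict([1, 2, 3], [1, 2, 3], [10.0, 20.0, 30.0], 2, 2, power=2.5)
        assert v == 20.0

    def test_two_equidistant_points_average(self):
        for p in (1.0, 2.0, 3.7):
            v = idw_predict([0, 2], [0, 0], [10.0, 20.0], 1, 0, power=p, config=EUC)
            assert v == pytest.approx(15.0, abs=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            lons = rng.uniform(0, 10, 5)
            lats = rng.uniform(45, 50, 5)
            vals = rng.uniform(-30, -20, 5)
            t = (rng.uniform(0, 10), rng.uniform(45, 50))
            for p, cfg in ((2.0, EUC), (3.0, IDWConfig())):
                if cfg.metric == "euclidean_deg":
                    d = np.hypot(lons - t[0], lats - t[1])
                else:
                    d = np.array([haversine_km(lo, la, t[0], t[1])
                                  for lo, la in zip(lons, lats)])
                oracle = np.sum(d ** -p * vals) / np.sum(d ** -p)
                got = idw_predict(lons, lats, vals, t[0], t[1], p, cfg)
                assert got == pytest.approx(oracle, abs=1e-12)
                assert vals.min() - 1e-12 <= got <= vals.max() + 1e-12

    def test_empty_point_set(self):
        with pytest.raises(ValueError, match="empty"):
            idw_predict([], [], [], 0, 0, power=2)


class TestLOOCV:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        lons = rng.uniform(0, 10, 8)
        lats = rng.uniform(45, 50, 8)
        vals = -25.0 + 0.5 * lons + rng.normal(0, 0.2, 8)
        cfg = IDWConfig()
        best, rmse = loocv_select_power(lons, lats, vals, cfg)
        oracle = {}
        for p in cfg.power_candidates:
            errs = []
            for i in range(8):
                keep = [j for j in range(8) if j != i]
                pred = idw_predict(lons[keep], lats[keep], vals[keep],
                                   lons[i], lats[i], p, cfg)
                errs.append(pred - vals[i])
            oracle[p] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse == pytest.approx(oracle)
        assert best == min(sorted(oracle), key=lambda p: oracle[p])

    def test_duplicated_coordinates_tie_to_smallest_power(self):
        lons = [0.0, 0.0, 5.0, 5.0]
        lats = [0.0, 0.0, 0.0, 0.0]
        vals = [10.0, 10.0, 20.0, 20.0]
        best, rmse = loocv_select_power(lons, lats, vals, EUC)
        assert all(v == 0.0 for v in rmse.values())
        assert best == EUC.power_candidates[0]

    def test_single_candidate(self):
        cfg = IDWConfig(power_candidates=(2.0,))
        best, _ = loocv_select_power([0, 1, 2], [0, 1, 0], [1.0, 2.0, 3.0], cfg)
        assert best == 2.0

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            loocv_select_power([0, 1], [0, 1], [1.0, 2.0])


class TestForestCover:
    @staticmethod
    def _grids(values_by_slice):
        grids = {}
        for ts, vals in values_by_slice.items():
            nodes = pd.DataFrame({
                "longitude": [10.0, 11.0, 12.0],
                "latitude": [48.0, 48.0, 48.0],
                "value": vals,
            })
            grids[ts] = ProxyGrid("mfc", nodes, time_slice=ts)
        return grids

    SITE = Site("A", longitude=10.1, latitude=48.0)

    def test_average_of_three_slices(self):
        grids = self._grids({"7500": [80, 0, 0], "7250": [82, 0, 0],
                             "7000": [84, 0, 0]})
        assert mean_forest_cover_at_site(self.SITE, grids) == pytest.approx(82.0)

    def test_identical_slices_return_slice_value(self):
        grids = self._grids({ts: [70, 0, 0] for ts in ("7500", "7250", "7000")})
        assert mean_forest_cover_at_site(self.SITE, grids) == 70.0

    def test_nearest_node_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        nodes = pd.DataFrame({
            "longitude": rng.uniform(0, 20, 50),
            "latitude": rng.uniform(45, 55, 50),
            "value": rng.uniform(0, 100, 50),
        })
        grid = ProxyGrid("mfc", nodes)
        for _ in range(10):
            lon, lat = rng.uniform(0, 20), rng.uniform(45, 55)
            d = haversine_km(nodes.longitude.to_numpy(), nodes.latitude.to_numpy(),
                             lon, lat)
            assert grid.nearest_value(lon, lat) == nodes.value.iloc[int(np.argmin(d))]

    def test_missing_slice_listed(self):
        grids = self._grids({"7500": [1, 2, 3], "7000": [1, 2, 3]})
        with pytest.raises(ValueError, match="7250"):
            mean_forest_cover_at_site(self.SITE, grids)


class TestIsoscape:
    @staticmethod
    def _site_values(values, lons):
        rows = []
        for i, (v, lo) in enumerate(zip(values, lons)):
            rows.append({"site_id": f"S{i}", "longitude": lo, "latitude": 48.0,
                         "value": v})
        return pd.DataFrame(rows)

    def test_constant_sites_give_constant_surface(self):
        sv = self._site_values([-26.0] * 4, [0.0, 3.0, 6.0, 9.0])
        grid, power, _ = build_isoscape(sv, (0, 9), (47, 49), resolution=1.0)
        assert np.allclose(grid.nodes.value, -26.0)

    def test_gradient_surface_monotone_and_bounded(self):
        lons = [0.0, 2.0, 4.0, 6.0, 8.0]
        vals = [-28.0, -27.0, -26.0, -25.0, -24.0]
        sv = self._site_values(vals, lons)
        grid, power, _ = build_isoscape(sv, (0, 8), (48, 48), resolution=0.5)
        transect = grid.nodes[grid.nodes.latitude == 48.0].sort_values("longitude")
        assert transect.value.is_monotonic_increasing
        assert transect.value.between(-28.0, -24.0).all()

    def test_median_taken_per_site_first(self):
        sv = pd.concat([
            self._site_values([-30.0, -20.0, -25.0], [0.0, 0.0, 0.0]).assign(site_id="A"),
            self._site_values([-24.0], [5.0]).assign(site_id="B"),
            self._site_values([-26.0], [9.0]).assign(site_id="C"),
        ])
        grid, _, _ = build_isoscape(sv, (0, 9), (48, 48), resolution=9.0)
        # surface at site A's coordinate equals A's median, not its mean
        at_a = grid.nodes[(grid.nodes.longitude == 0.0)].value.iloc[0]
        assert at_a == pytest.approx(-25.0)

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match=">= 3 sites"):
            build_isoscape(self._site_values([-25, -26], [0, 1]), (0, 1), (48, 48))


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_test(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        assert res.statistic == pytest.approx(r, abs=1e-12)

    def test_spearman_matches_rank_difference_formula(self):
        rng = np.random.default_rng(10)
        x = rng.permutation(20).astype(float)  # no ties
        y = rng.normal(size=20)
        res = spearman_test(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        n = 20
        s = float(np.sum((rx - ry) ** 2))
        rho = 1 - 6 * s / (n ** 3 - n)
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.s_statistic == pytest.approx(s, abs=1e-9)

    def test_antitone_sequence_s_statistic(self):
        x = np.arange(1.0, 13.0)
        res = spearman_test(x, -x)
        n = 12
        assert res.statistic == pytest.approx(-1.0)
        assert res.s_statistic == pytest.approx((n ** 3 - n) / 3, abs=1e-9)

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="y has zero variance"):
            pearson_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_anova_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = anova_oneway([g, g, g])
        assert res["F"] == pytest.approx(0.0)
        assert res["df_between"] == 2 and res["df_within"] == 6

    def test_anova_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.0)]
        res = anova_oneway(groups)
        allv = np.concatenate(groups)
        ssb = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        f = (ssb / 2) / (ssw / (len(allv) - 3))
        assert res["F"] == pytest.approx(f, abs=1e-10)


class TestMultipleTesting:
    def test_bonferroni_simple(self):
        adj = multiple_testing_adjust([0.01], m=5)
        assert adj["bonferroni"][0] == pytest.approx(0.05)

    def test_all_ones_stay_one(self):
        adj = multiple_testing_adjust([1.0, 1.0, 1.0])
        assert np.all(adj["bonferroni"] == 1.0) and np.all(adj["fdr_bh"] == 1.0)

    def test_bh_matches_step_up_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.2, 0.9])
        adj = multiple_testing_adjust(p)
        m = len(p)
        order = np.argsort(p)
        raw = p[order] * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]  # enforce monotone
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        assert adj["fdr_bh"] == pytest.approx(oracle, abs=1e-12)
        # adjusted values are monotone in raw-p order
        assert np.all(np.diff(adj["fdr_bh"][order]) >= -1e-15)

    def test_out_of_range_p(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            multiple_testing_adjust([0.5, 1.2])


class TestCorrelationScreen:
    def test_bonferroni_uses_screen_size(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        manifest = [
            {"pair": "a~b", "table": "t", "x": "a", "y": "b", "method": "pearson"},
            {"pair": "a~c", "table": "t", "x": "a", "y": "c", "method": "pearson"},
            {"pair": "a~d", "table": "t", "x": "a", "y": "d", "method": "spearman"},
        ]
        out = correlation_screen({"t": df}, manifest)
        assert len(out) == 3
        for _, row in out.iterrows():
            assert row.p_bonferroni == pytest.approx(min(1.0, 3 * row.p_raw))

    def test_unresolvable_pair_skipped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3]})
        manifest = [
            {"pair": "a~b", "table": "t", "x": "a", "y": "b"},
            {"pair": "a~ghost", "table": "t", "x": "a", "y": "ghost"},
        ]
        with pytest.warns(UserWarning, match="ghost"):
            out = correlation_screen({"t": df}, manifest)
        assert list(out.pair) == ["a~b"]

    def test_canopy_world_mfc_diet_negative(self, world):
        """In a canopy-effect world, forest cover correlates negatively with
        diet delta13C inferred from collagen."""
        from palaeofeed.diet_inference import estimate_diets

        truth = world.truth["sites"].set_index("site_id")
        coll = world.dataset.bulk_by_tissue("collagen", "cattle")
        df = pd.DataFrame({
            "mfc": [truth.loc[s.site_id, "mfc"] for s in coll],
            "diet": [e.d13c_diet for e in estimate_diets(coll)],
        })
        res = pearson_test(df.mfc, df.diet, pair="mfc~diet")
        assert res.statistic < 0
        assert res.p_raw < 0.05
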