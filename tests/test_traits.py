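"""Growth traits: areas, thermal time, regrowth, expansion slope, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ryeview.traits import (
    PlantObservation,
    TemperatureDay,
    genotype_means,
    lateral_expansion,
    leaf_growth,
    pearson_correlation,
    pixels_to_area,
    regrowth,
    thermal_time,
    trait_tables,
)


def _obs(week="W0", area=10.0, valid=True, tp="Y1C2", geno="G1", rep=1):
    return PlantObservation(geno, rep, tp, week, area, valid)


class TestPixelsToArea:
    @pytest.mark.parametrize(
        "count,scale,expected",
        [
            (10_000, 100.0, 1.0),
            (0, 74.36, 0.0),
            (5_531, 74.36, 5531 / 74.36**2),   # ~1.0003 cm^2
        ],
    )
    def test_closed_form(self, count, scale, expected):
        assert pixels_to_area(count, scale) == pytest.approx(expected, rel=1e-12)

    @given(count=st.integers(0, 10**6), scale=st.floats(1.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, count, scale):
        """Doubling the pixels-per-cm scale quarters the area."""
        assert pixels_to_area(count, 2 * scale) == pytest.approx(
            pixels_to_area(count, scale) / 4
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            pixels_to_area(10, 0.0)


class TestThermalTime:
    def test_constant_days(self):
        days = [TemperatureDay(i, 10.0, 10.0) for i in range(5)]
        assert thermal_time(days) == pytest.approx(50.0)

    def test_negative_mean_clipped_to_zero(self):
        assert thermal_time([TemperatureDay(0, -4.0, 2.0)]) == 0.0

    def test_mixed_example(self):
        assert thermal_time([TemperatureDay(0, 4.0, 10.0)] * 2) == pytest.approx(14.0)

    def test_base_temperature_shift(self):
        days = [TemperatureDay(0, 8.0, 12.0)]
        assert thermal_time(days, t_base=5.0) == pytest.approx(5.0)

    @given(st.lists(st.tuples(st.floats(-20, 25), st.floats(0, 15)),
                    min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_additive_over_consecutive_ranges(self, raw):
        days = [TemperatureDay(i, lo, lo + d) for i, (lo, d) in enumerate(raw)]
        k = len(days) // 2
        total = thermal_time(days)
        assert total >= 0.0
        assert total == pytest.approx(
            thermal_time(days[:k]) + thermal_time(days[k:])
        ) if k >= 1 and len(days) - k >= 1 else True

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            thermal_time([])


class TestRegrowth:
    def test_difference(self):
        res = regrowth(_obs("W0", 12.0), _obs("W1", 30.0))
        assert res.regrowth_cm2 == pytest.approx(18.0)
        assert res.regrowth_rate is None

    def test_per_degree_day(self):
        res = regrowth(_obs("W0", 12.0), _obs("W1", 30.0), gdd_week=90.0)
        assert res.regrowth_rate == pytest.approx(0.2)

    def test_invalid_observation_propagates(self):
        res = regrowth(_obs("W0", 12.0, valid=False), _obs("W1", 30.0))
        assert not res.valid and res.regrowth_cm2 is None

    def test_negative_regrowth_retained(self):
        res = regrowth(_obs("W0", 30.0), _obs("W1", 25.0))
        assert res.regrowth_cm2 == pytest.approx(-5.0)

    def test_mismatched_keys_raise(self):
        with pytest.raises(ValueError):
            regrowth(_obs("W0", tp="Y1C2"), _obs("W1", tp="Y1C3"))
        with pytest.raises(ValueError):
            regrowth(_obs("W0"), _obs("W0"))


class TestLateralExpansion:
    def test_exact_line(self):
        obs = [_obs(area=a) for a in (10.0, 20.0, 30.0, 40.0)]
        out = lateral_expansion(obs, [0.0, 100.0, 200.0, 300.0])
        assert out.lateral_expansion == pytest.approx(0.100, abs=1e-12)
        assert out.n_obs == 4

    def test_constant_offset_leaves_slope_unchanged(self):
        gdd = [0.0, 100.0, 250.0, 400.0]
        areas = [12.0, 19.0, 33.0, 41.0]
        s1 = lateral_expansion([_obs(area=a) for a in areas], gdd).lateral_expansion
        s2 = lateral_expansion(
            [_obs(area=a + 50.0) for a in areas], gdd
        ).lateral_expansion
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_fewer_than_three_valid_points_gives_no_estimate(self):
        obs = [
            _obs(area=10.0),
            _obs(area=20.0, valid=False),
            _obs(area=30.0, valid=False),
            _obs(area=40.0),
        ]
        out = lateral_expansion(obs, [0.0, 100.0, 200.0, 300.0])
        assert out.lateral_expansion is None
        assert out.n_obs == 2

    def test_ols_recovery_on_noisy_series(self):
        """Simulation oracle: mean OLS estimate over 500 noisy replicates of a
        4-point series (true slope 0.06, sigma 2 cm^2) is unbiased within
        0.005."""
        rng = np.random.default_rng(17)
        gdd = np.array([0.0, 150.0, 300.0, 450.0])
        estimates = []
        for _ in range(500):
            areas = 12.0 + 0.06 * gdd + rng.normal(0, 2.0, size=4)
            obs = [_obs(area=float(a)) for a in areas]
            estimates.append(lateral_expansion(obs, gdd).lateral_expansion)
        assert np.mean(estimates) == pytest.approx(0.06, abs=0.005)

    def test_non_increasing_axis_rejected(self):
        with pytest.raises(ValueError):
            lateral_expansion([_obs()] * 3, [0.0, 100.0, 100.0])


class TestLeafGrowth:
    @pytest.mark.parametrize(
        "height,gdd,expected", [(30.0, 150.0, 0.2), (0.0, 10.0, 0.0), (21.0, 140.0, 0.15)]
    )
    def test_closed_form(self, height, gdd, expected):
        assert leaf_growth(height, gdd) == pytest.approx(expected)

    def test_nonpositive_gdd_rejected(self):
        with pytest.raises(ValueError):
            leaf_growth(10.0, 0.0)


class TestGenotypeMeans:
    def test_mean_over_replicates(self):
        df = pd.DataFrame(
            {
                "genotype_id": ["G1"] * 3 + ["G2"] * 3,
                "x": [10.0, 20.0, 30.0, 1.0, 2.0, 3.0],
                "valid": [True] * 6,
            }
        )
        out = genotype_means(df, ["x"]).set_index("genotype_id")
        assert out.loc["G1", "x"] == pytest.approx(20.0)
        assert out.loc["G2", "x"] == pytest.approx(2.0)

    def test_invalid_replicate_dropped_from_mean(self):
        df = pd.DataFrame(
            {
                "genotype_id": ["G1"] * 3,
                "x": [10.0, 999.0, 30.0],
                "valid": [True, False, True],
            }
        )
        out = genotype_means(df, ["x"])
        assert out["x"].iloc[0] == pytest.approx(20.0)

    def test_all_invalid_genotype_excluded(self):
        df = pd.DataFrame(
            {
                "genotype_id": ["G1", "G2"],
                "x": [10.0, 11.0],
                "valid": [False, True],
            }
        )
        out = genotype_means(df, ["x"])
        assert list(out["genotype_id"]) == ["G2"]


class TestPearsonCorrelation:
    def test_exact_linear(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 0.05
        r2, _ = pearson_correlation(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_recovers_population_correlation(self):
        """Sampling oracle: bivariate normal with rho = 0.8 at n = 500."""
        rng = np.random.default_rng(99)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        r, p = pearson_correlation(xy[:, 0], xy[:, 1])
        assert r == pytest.approx(0.8, abs=0.05)
        assert p < 1e-6

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_or_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTraitTables:
    def _inputs(self):
        # 10 degree-days per day -> cut dates 30 days apart are 300 gdd apart
        temps = pd.DataFrame(
            {
                "date": pd.date_range("2014-04-01", periods=120, freq="D"),
                "tmin": 8.0,
                "tmax": 12.0,
            }
        )
        cuts = pd.DataFrame(
            {
                "timepoint": ["Y1C2", "Y1C3", "Y1C4", "Y1C5"],
                "date": ["2014-04-01", "2014-05-01", "2014-05-31", "2014-06-30"],
            }
        )
        rows = []
        for rep in (1, 2):
            for i, tp in enumerate(cuts["timepoint"]):
                w0 = 20.0 + 0.05 * (300 * i)
                rows.append(("G1", rep, tp, "W0", w0, True))
                rows.append(("G1", rep, tp, "W1", w0 + 7.0, True))
        det = pd.DataFrame(
            rows,
            columns=["genotype_id", "replicate", "timepoint", "week", "area_cm2", "valid"],
        )
        return det, temps, cuts

    def test_expansion_and_regrowth_from_linear_series(self):
        det, temps, cuts = self._inputs()
        tables = trait_tables(det, temps, cuts)
        exp = tables["lateral_expansion"]
        assert np.allclose(exp["lateral_expansion"], 0.05)
        # regrowth 7 cm^2 over 7 days x 10 gdd/day
        reg = tables["regrowth"]
        assert np.allclose(reg["regrowth_cm2"], 7.0)
        assert np.allclose(reg["regrowth_rate"], 0.1)
        geno = tables["genotype"].set_index("genotype_id")
        assert geno.loc["G1", "lateral_expansion"] == pytest.approx(0.05)

    def test_invalid_weeks_break_regrowth_but_not_slope(self):
        det, temps, cuts = self._inputs()
        det.loc[(det["week"] == "W1") & (det["replicate"] == 1), "valid"] = False
        tables = trait_tables(det, temps, cuts)
        reg = tables["regrowth"]
        assert not reg[reg["replicate"] == 1]["valid"].any()
        exp = tables["lateral_expansion"]
        assert exp["valid"].all()

    def test_correlation_table_with_manual_data(self):
        det, temps, cuts = self._inputs()
        # second genotype, scaled areas, to give the correlation 3+ points
        det2 = det.assign(genotype_id="G2", area_cm2=det["area_cm2"] * 1.5)
        det3 = det.assign(genotype_id="G3", area_cm2=det["area_cm2"] * 0.5)
        det_all = pd.concat([det, det2, det3], ignore_index=True)
        manual_rows = []
        for geno, scale in (("G1", 1.0), ("G2", 1.5), ("G3", 0.5)):
            for rep in (1, 2):
                for tp in cuts["timepoint"]:
                    manual_rows.append((geno, rep, tp, 100 * scale, 30.0 * scale))
        manual = pd.DataFrame(
            manual_rows,
            columns=["genotype_id", "replicate", "timepoint", "tiller_number", "height_cm"],
        )
        tables = trait_tables(det_all, temps, cuts, manual=manual)
        corr = tables["correlations"].set_index("x")
        # tillers scale exactly with base area across genotypes -> r = 1
        assert corr.loc["tiller_number", "r"] == pytest.approx(1.0, abs=1e-6)
        assert corr.loc["tiller_number", "p"] < 0.05
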