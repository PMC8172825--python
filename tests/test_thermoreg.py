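"""Set-points, Hertz indices, vulnerability indices and T_e summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermovuln import thermoreg as tr

finite_temp = st.floats(min_value=-50, max_value=60, allow_nan=False)


class TestExtractTset:
    def test_constant_trace(self):
        s = tr.extract_tset([37.0] * 10, "x")
        assert (s.t_pref_mean, s.t_set_lower, s.t_set_upper) == (37.0, 37.0, 37.0)

    def test_linear_interpolation_quartiles(self):
        # hand-computed: [34,36,38,40] -> Q1 = 35.5, Q3 = 38.5
        s = tr.extract_tset([34, 36, 38, 40])
        assert s.t_set_lower == pytest.approx(35.5)
        assert s.t_set_upper == pytest.approx(38.5)
        assert s.t_pref_mean == pytest.approx(37.0)

    def test_order_invariance(self, rng):
        trace = rng.normal(37, 1.5, 37)
        shuffled = rng.permutation(trace)
        a, b = tr.extract_tset(trace), tr.extract_tset(shuffled)
        assert a.t_pref_mean == pytest.approx(b.t_pref_mean)
        assert a.t_set_lower == pytest.approx(b.t_set_lower)
        assert a.t_set_upper == pytest.approx(b.t_set_upper)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            tr.extract_tset([37.0, 38.0, 36.0])


class TestDeviationFromRange:
    # set-point band fixture from the reported interquartile bounds
    LO, HI = 36.57, 38.40

    @pytest.mark.parametrize("x,expected", [
        (37.0, 0.0),          # inside
        (40.0, 1.60),         # above: 40 - 38.40
        (36.57, 0.0),         # boundary counts as inside
        (30.0, 6.57),         # below: 36.57 - 30
    ])
    def test_examples(self, x, expected):
        assert tr.deviation_from_range(x, self.LO, self.HI) == pytest.approx(expected)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            tr.deviation_from_range(37.0, 38.4, 36.57)

    @given(x=finite_temp, lo=finite_temp, width=st.floats(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_zero_iff_inside_and_continuous(self, x, lo, width):
        hi = lo + width
        d = tr.deviation_from_range(x, lo, hi)
        assert d >= 0
        assert (d == 0) == (lo <= x <= hi)
        # continuity at the nearer bound: deviation equals distance outside
        if x < lo:
            assert d == pytest.approx(lo - x)
        elif x > hi:
            assert d == pytest.approx(x - hi)

    def test_midpoint_mode(self):
        assert tr.deviation_from_range(37.0, 36.0, 38.0, mode="midpoint") == 0.0
        assert tr.deviation_from_range(40.0, 36.0, 38.0, mode="midpoint") == 3.0


class TestEffectiveness:
    def test_thermoconformity_is_zero(self):
        vals = [1.2, 3.4, 0.0, 5.0]
        assert tr.effectiveness(vals, vals) == pytest.approx(0.0)

    def test_perfect_regulation_is_one(self):
        assert tr.effectiveness([0.0, 0.0], [2.0, 4.0]) == pytest.approx(1.0)

    def test_zero_mean_de_rejected(self):
        with pytest.raises(ZeroDivisionError):
            tr.effectiveness([1.0], [0.0, 0.0])

    @given(db=st.floats(0.1, 10), de=st.floats(0.1, 10), bump=st.floats(0.01, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_both_arguments(self, db, de, bump):
        e = tr.effectiveness([db], [de])
        assert tr.effectiveness([db + bump], [de]) < e
        assert tr.effectiveness([db], [de + bump]) > e


class TestClassifyVsRange:
    def test_reported_te_partition(self):
        # 13 below / 2 within / 5 above out of 20 records
        vals = [30.0] * 13 + [37.0] * 2 + [40.0] * 5
        nb, nw, na, f = tr.classify_vs_range(vals, 36.57, 38.40)
        assert (nb, nw, na) == (13, 2, 5)
        assert f == pytest.approx((0.65, 0.10, 0.25))

    def test_all_inside(self):
        nb, nw, na, _ = tr.classify_vs_range([37.0] * 8, 36.0, 38.0)
        assert (nb, nw, na) == (0, 8, 0)

    def test_boundary_counts_within(self):
        _, nw, _, _ = tr.classify_vs_range([36.0, 38.0], 36.0, 38.0)
        assert nw == 2

    @given(values=st.lists(finite_temp, min_size=1, max_size=50),
           lo=finite_temp, width=st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_counts_partition_and_fractions_sum(self, values, lo, width):
        nb, nw, na, f = tr.classify_vs_range(values, lo, lo + width)
        assert nb + nw + na == len(values)
        assert abs(sum(f) - 1.0) < 1e-12


class TestVulnerabilityIndices:
    def test_warming_tolerance_arithmetic(self):
        assert tr.warming_tolerance(43.44, 43.44) == 0.0
        assert tr.warming_tolerance(43.44, 33.44) == pytest.approx(10.0)

    def test_tsm_arithmetic_and_ordering(self):
        assert tr.thermal_safety_margin(38.40, 38.40) == 0.0
        assert tr.thermal_safety_margin(38.40, 34.40) == pytest.approx(4.0)
        # TSM <= WT whenever upper set-point <= CT_max
        assert tr.thermal_safety_margin(38.40, 30.0) <= tr.warming_tolerance(43.44, 30.0)

    def test_breadth(self):
        assert tr.tolerance_breadth(43.44, 11.76) == pytest.approx(31.68)
        assert tr.tolerance_breadth(25.0, 25.0) == 0.0

    @given(ct_max=finite_temp, ct_min=finite_temp, te=finite_temp,
           c=st.floats(-20, 20))
    @settings(max_examples=100, deadline=None)
    def test_translation_identities(self, ct_max, ct_min, te, c):
        assert tr.tolerance_breadth(ct_max + c, ct_min + c) == pytest.approx(
            tr.tolerance_breadth(ct_max, ct_min))
        assert tr.warming_tolerance(ct_max + c, te + c) == pytest.approx(
            tr.warming_tolerance(ct_max, te))
        assert tr.thermal_safety_margin(ct_max + c, te + c) == pytest.approx(
            tr.thermal_safety_margin(ct_max, te))


class TestAggregateTe:
    def test_matches_brute_force_oracle(self, rng):
        n = 100
        df = pd.DataFrame({
            "habitat": rng.choice(["sun", "shade"], n),
            "time": rng.uniform(8, 19, n),
            "T_e": rng.normal(30, 6, n),
        })
        out = tr.aggregate_te(df).set_index(["hour", "habitat"])
        # independent loop-based aggregation
        for (hour, habitat), row in out.iterrows():
            sel = df[(np.floor(df["time"]).astype(int) == hour)
                     & (df["habitat"] == habitat)]["T_e"].to_numpy()
            assert row["n"] == len(sel)
            assert row["mean"] == pytest.approx(sel.mean())
            if len(sel) > 1:
                expected_sem = sel.std(ddof=1) / np.sqrt(len(sel))
                assert row["sem"] == pytest.approx(expected_sem)
            else:
                assert np.isnan(row["sem"])

    def test_constant_series_sem_zero(self):
        df = pd.DataFrame({"habitat": "sun", "time": [9.0, 9.2, 9.5], "T_e": 30.0})
        out = tr.aggregate_te(df)
        assert out["mean"].iloc[0] == 30.0
        assert out["sem"].iloc[0] == 0.0

    def test_singleton_hour_sem_missing(self):
        df = pd.DataFrame({"habitat": ["sun"], "time": [9.0], "T_e": [30.0]})
        assert np.isnan(tr.aggregate_te(df)["sem"].iloc[0])


class TestThermalQualitySeries:
    TSET = tr.TsetSummary("pop", 37.38, 36.57, 38.40)

    def test_all_within_band_zero(self):
        df = pd.DataFrame({"habitat": "shade", "time": np.linspace(8, 18, 20),
                           "T_e": 37.0})
        out = tr.thermal_quality_series(df, self.TSET)
        np.testing.assert_allclose(out["d_e"], 0.0)

    def test_constant_exceedance(self):
        df = pd.DataFrame({"habitat": "sun", "time": np.linspace(8, 18, 20),
                           "T_e": self.TSET.t_set_upper + 2.0})
        out = tr.thermal_quality_series(df, self.TSET)
        np.testing.assert_allclose(out["d_e"], 2.0)

    def test_matches_brute_force(self, rng):
        df = pd.DataFrame({
            "habitat": rng.choice(["sun", "shade"], 80),
            "time": rng.uniform(8, 19, 80),
            "T_e": rng.normal(36, 5, 80),
        })
        out = tr.thermal_quality_series(df, self.TSET).set_index(["hour", "habitat"])
        for (hour, habitat), row in out.iterrows():
            sel = df[(np.floor(df["time"]).astype(int) == hour)
                     & (df["habitat"] == habitat)]["T_e"]
            devs = [max(self.TSET.t_set_lower - t, t - self.TSET.t_set_upper, 0.0)
                    for t in sel]
            assert row["d_e"] == pytest.approx(np.mean(devs))


class TestCalibrateTeModel:
    def test_exact_line(self):
        x = np.linspace(20, 45, 30)
        slope, intercept, adj_r2, _ = tr.calibrate_te_model(np.c_[x, 1.09 * x])
        assert slope == pytest.approx(1.09)
        assert intercept == pytest.approx(0.0, abs=1e-10)
        assert adj_r2 == pytest.approx(1.0)

    def test_noise_only_ci_covers_zero(self, rng):
        x = rng.uniform(20, 45, 500)
        y = rng.normal(30, 2, 500)
        slope, _, _, (lo, hi) = tr.calibrate_te_model(np.c_[x, y])
        assert lo <= 0.0 <= hi

    def test_duplication_narrows_ci(self, rng):
        x = rng.uniform(20, 45, 50)
        y = 1.1 * x + rng.normal(0, 1, 50)
        pairs = np.c_[x, y]
        s1, _, _, (lo1, hi1) = tr.calibrate_te_model(pairs)
        s2, _, _, (lo2, hi2) = tr.calibrate_te_model(np.vstack([pairs, pairs]))
        assert s2 == pytest.approx(s1)
        assert (hi2 - lo2) < (hi1 - lo1)


class TestPipeline:
    def test_tb_inside_setpoints_gives_db_zero_E_one(self):
        """Synthetic captures with T_b pinned inside the band: d_b = 0, E = 1."""
        ids = [f"L{i:03d}" for i in range(1, 6)]
        captures = pd.DataFrame({
            "id": ids, "sex_age": "male", "time": 10.5, "T_b": 37.0,
            "T_a": 30.0, "T_s": 32.0, "RH": 20.0, "wind": 1.0,
            "microhabitat": "BS-shade", "SVL": 60.0, "BW": 7.0,
        })
        te = pd.DataFrame({"model_id": "M01", "habitat": "sun",
                           "time": np.repeat(np.arange(8.0, 19.0), 3),
                           "T_e": 45.0})  # hot habitat: d_e > 0
        traces = pd.concat([
            pd.DataFrame({"id": i, "reading": range(8),
                          "T_pref": [36.5, 36.8, 37.0, 37.2, 37.4, 37.6, 37.8, 38.0]})
            for i in ids])
        tolerance = pd.DataFrame({"id": ids, "ct_min": 11.76, "vt_max": 38.99,
                                  "ct_max": 43.44})
        out = tr.compute_indices(captures, te, traces, tolerance)
        assert out["overall"].d_b == pytest.approx(0.0)
        assert out["overall"].E == pytest.approx(1.0)
        assert out["overall"].breadth == pytest.approx(31.68)

    def test_groups_partition_overall(self, campaign, te_series, lab_thermal):
        traces, tolerance = lab_thermal
        out = tr.compute_indices(campaign, te_series, traces, tolerance)
        group_n = sum(v.n for k, v in out.items() if k != "overall")
        assert group_n == out["overall"].n
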