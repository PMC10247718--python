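"""Gap-filling and the three-step ratio allocation."""

import numpy as np
import pandas as pd
import pytest

import cnp
from cnp.harmonize import GapFillPolicy, gap_fill_series


def natural_spline_eval(x, y, xq):
    """Independent natural cubic spline: first-principles tridiagonal solve.

    Second derivatives M solve the classic system with M_0 = M_n = 0;
    evaluation by the standard piecewise-cubic formula.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x) - 1
    h = np.diff(x)
    # tridiagonal system for interior second derivatives
    a = np.zeros((n - 1, n - 1))
    rhs = np.zeros(n - 1)
    for i in range(1, n):
        if i > 1:
            a[i - 1, i - 2] = h[i - 1]
        a[i - 1, i - 1] = 2 * (h[i - 1] + h[i])
        if i < n - 1:
            a[i - 1, i] = h[i]
        rhs[i - 1] = 6 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    m = np.zeros(n + 1)
    m[1:n] = np.linalg.solve(a, rhs)
    out = []
    for q in np.atleast_1d(xq):
        i = min(max(np.searchsorted(x, q) - 1, 0), n - 1)
        t = q - x[i]
        c0 = y[i]
        c1 = (y[i + 1] - y[i]) / h[i] - h[i] * (2 * m[i] + m[i + 1]) / 6
        c2 = m[i] / 2
        c3 = (m[i + 1] - m[i]) / (6 * h[i])
        out.append(c0 + c1 * t + c2 * t**2 + c3 * t**3)
    return np.array(out)


class TestGapFill:
    def test_linear_series_fills_the_line(self):
        years = np.arange(2004, 2009)
        vals = np.array([10.0, 20.0, np.nan, 40.0, 50.0])
        filled, status = gap_fill_series(years, vals)
        assert filled[2] == pytest.approx(30.0, abs=1e-9)
        assert status[2] == "gap_filled"
        assert list(status[[0, 1, 3, 4]]) == ["observed"] * 4

    def test_run_of_three_left_missing(self):
        years = np.arange(2004, 2014)
        vals = np.arange(10.0, 20.0)
        vals[3:6] = np.nan
        filled, status = gap_fill_series(years, vals, GapFillPolicy(max_run=2))
        assert np.isnan(filled[3:6]).all()
        assert list(status[3:6]) == ["missing"] * 3

    def test_boundary_gaps_not_filled(self):
        years = np.arange(2004, 2010)
        vals = np.array([np.nan, 20.0, 30.0, 40.0, 50.0, np.nan])
        filled, status = gap_fill_series(years, vals)
        assert np.isnan(filled[0]) and np.isnan(filled[-1])
        assert status[0] == "missing" and status[-1] == "missing"

    def test_cubic_series_matches_tridiagonal_oracle(self):
        years = np.arange(0, 13)
        truth = years.astype(float) ** 3 - 2 * years
        vals = truth.astype(float)
        vals[[5, 6]] = np.nan
        filled, status = gap_fill_series(years, vals)
        obs = ~np.isnan(vals)
        expect = natural_spline_eval(years[obs], vals[obs], [5, 6])
        assert np.allclose(filled[[5, 6]], expect, rtol=1e-9, atol=1e-9)
        assert list(status[[5, 6]]) == ["gap_filled"] * 2

    def test_negative_fills_floored_at_zero(self):
        years = np.arange(2004, 2011)
        vals = np.array([5.0, 1.0, np.nan, 0.0, 1.0, 5.0, 10.0])
        filled, _ = gap_fill_series(years, vals, GapFillPolicy(floor_at_zero=True))
        assert filled[2] >= 0.0

    def test_too_few_observed_points_raise(self):
        years = np.arange(2004, 2008)
        vals = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(cnp.MissingDataError, match="observed points"):
            gap_fill_series(years, vals)

    def test_long_gap_world_drops_the_gap_years(self, uniform_world):
        w = cnp.perturb_world(uniform_world, "long_gap")
        filled = cnp.gap_fill_county_stats(w.county)
        still = filled.consumption[filled.consumption["status"] == "missing"]
        assert len(still) == (w.config.max_gap_run + 2) * 2  # both kinds

    def test_short_gaps_filled_close_to_truth(self, het_world):
        w = het_world
        filled = cnp.gap_fill_county_stats(w.county)
        merged = filled.consumption[filled.consumption["status"] == "gap_filled"]
        truth = w.truth.consumption.set_index(["county", "year", "kind"])
        if len(merged):
            got = merged.set_index(["county", "year", "kind"])["consumption"]
            t = truth.loc[got.index, "consumption"]
            # smooth-series fills land within a few percent of truth
            assert np.median(np.abs(got / t - 1)) < 0.05


def _one_county_world(rates, areas):
    """1 county, 1 year, 1 kind; rates/areas keyed by the 4 categories."""
    prov = cnp.ProvincialRates(pd.DataFrame(
        [(1, 2004, c, "phosphorus", r) for c, r in rates.items()])
        .set_axis(["province", "year", "crop", "kind", "rate"], axis=1))
    named = {c: a for c, a in areas.items() if c != "other"}
    total = sum(areas.values())
    county = cnp.CountyStats(
        provinces=pd.DataFrame({"county": [1], "province": [1]}),
        consumption=pd.DataFrame(
            [(1, 2004, "phosphorus", 1000.0, "observed"),
             (1, 2004, "component", 0.0, "observed")],
            columns=["county", "year", "kind", "consumption", "status"]),
        areas=pd.DataFrame(
            [(1, 2004, c, a, "observed") for c, a in named.items()]
            + [(1, 2004, "total", total, "observed")],
            columns=["county", "year", "crop", "area", "status"]),
    ).validate()
    # the component kind needs rates too; make them zero
    comp = prov.df.assign(kind="component", rate=0.0)
    prov = cnp.ProvincialRates(pd.concat([prov.df, comp], ignore_index=True))
    return prov, county


class TestAllocationRatios:
    def test_hand_evaluated_ratios(self):
        rates = {"rice": 6.5, "wheat": 8.7, "maize": 6.4, "other": 3.0}
        areas = {"rice": 2e6, "wheat": 1e6, "maize": 1e6, "other": 4e6}
        prov, county = _one_county_world(rates, areas)
        out = cnp.allocation_ratios(prov, county)
        out = out[out["kind"] == "phosphorus"].set_index("crop")["ratio"]
        denom = 6.5 * 2e6 + 8.7 * 1e6 + 6.4 * 1e6 + 3.0 * 4e6  # 40.1e6 g
        assert denom == pytest.approx(40.1e6)
        for crop in rates:
            expect = rates[crop] * areas[crop] / denom
            assert out[crop] == pytest.approx(expect, rel=1e-12)

    def test_single_crop_county_ratio_one(self):
        rates = {"rice": 6.5, "wheat": 8.7, "maize": 6.4, "other": 3.0}
        areas = {"rice": 1e6, "wheat": 0.0, "maize": 0.0, "other": 0.0}
        prov, county = _one_county_world(rates, areas)
        out = cnp.allocation_ratios(prov, county)
        out = out[out["kind"] == "phosphorus"].set_index("crop")["ratio"]
        assert out["rice"] == pytest.approx(1.0, rel=1e-15)
        assert out["wheat"] == 0.0 and out["maize"] == 0.0 and out["other"] == 0.0

    def test_equal_rates_and_areas_give_quarter_each(self):
        rates = {c: 5.0 for c in cnp.ALL_CROPS}
        areas = {c: 1e6 for c in cnp.ALL_CROPS}
        prov, county = _one_county_world(rates, areas)
        out = cnp.allocation_ratios(prov, county)
        out = out[out["kind"] == "phosphorus"]
        assert np.allclose(out["ratio"], 0.25, rtol=1e-15)

    def test_ratios_sum_to_one_everywhere(self, het_result):
        r = het_result.ratios.dropna(subset=["ratio"])
        sums = r.groupby(["county", "year", "kind"])["ratio"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_area_unit_invariance(self, uniform_world):
        w = uniform_world
        filled = cnp.gap_fill_county_stats(w.county)
        stage1 = cnp.other_crops_rate(w.prov_rates, w.prov_totals)
        base = cnp.allocation_ratios(stage1.rates, filled)
        # express all county areas in hectares instead of m2
        scaled_areas = filled.areas.assign(area=filled.areas["area"] / 1e4)
        scaled = cnp.CountyStats(filled.provinces, filled.consumption, scaled_areas)
        out = cnp.allocation_ratios(stage1.rates, scaled)
        key = ["county", "year", "crop", "kind"]
        a = base.set_index(key)["ratio"].sort_index()
        b = out.set_index(key)["ratio"].sort_index()
        assert np.allclose(a.fillna(-1), b.fillna(-1), rtol=1e-12)


class TestAllocateAndRates:
    def test_allocation_splits_total_by_ratio(self):
        ratios = pd.DataFrame({
            "county": 1, "year": 2004,
            "crop": list(cnp.ALL_CROPS), "kind": "phosphorus",
            "ratio": [0.5, 0.3, 0.1, 0.1], "status": "observed"})
        county = cnp.CountyStats(
            provinces=pd.DataFrame({"county": [1], "province": [1]}),
            consumption=pd.DataFrame(
                [(1, 2004, "phosphorus", 1000.0, "observed")],
                columns=["county", "year", "kind", "consumption", "status"]),
            areas=pd.DataFrame(
                [(1, 2004, c, 1.0, "observed") for c in cnp.NAMED_CROPS]
                + [(1, 2004, "total", 4.0, "observed")],
                columns=["county", "year", "crop", "area", "status"]))
        out = cnp.allocate_consumption(ratios, county)
        got = out.set_index("crop")["consumption"]
        assert got["rice"] == 500.0 and got["wheat"] == 300.0
        assert got["maize"] == 100.0 and got["other"] == 100.0

    def test_conservation_through_allocation(self, het_result, het_world):
        cons = cnp.allocate_consumption(het_result.ratios,
                                        het_result.filled_county)
        live = cons[cons["status"] != "dropped"]
        per = live.groupby(["county", "year", "kind"])["consumption"].sum()
        tot = het_result.filled_county.consumption.set_index(
            ["county", "year", "kind"])["consumption"]
        aligned = tot.reindex(per.index)
        assert np.allclose(per, aligned, rtol=1e-9)

    def test_rate_is_consumption_over_area(self):
        cons = pd.DataFrame({
            "county": [1], "year": [2004], "crop": ["rice"],
            "kind": ["phosphorus"], "consumption": [650.0],
            "status": ["observed"], "reason": [""]})
        county = cnp.CountyStats(
            provinces=pd.DataFrame({"county": [1], "province": [1]}),
            consumption=pd.DataFrame(
                [(1, 2004, "phosphorus", 650.0, "observed")],
                columns=["county", "year", "kind", "consumption", "status"]),
            areas=pd.DataFrame(
                [(1, 2004, "rice", 100.0, "observed"),
                 (1, 2004, "total", 100.0, "observed")],
                columns=["county", "year", "crop", "area", "status"]))
        out = cnp.county_rates(cons, county)
        rice = out.df[out.df["crop"] == "rice"]
        assert rice["rate"].iloc[0] == pytest.approx(6.5, rel=1e-15)

    def test_zero_area_zero_consumption_flagged_not_nan(self, uniform_result):
        df = uniform_result.rates.df
        dropped = df[df["reason"] == "zero_area"]
        assert len(dropped) > 0
        assert dropped["rate"].isna().all()
        live = df[df["status"] != "dropped"]
        assert live["rate"].notna().all()

    def test_exact_recovery_in_uniform_regime(self, uniform_world):
        w = uniform_world
        stage1 = cnp.other_crops_rate(w.prov_rates, w.prov_totals)
        got = cnp.harmonize(stage1.rates, w.county)
        live = got.df[got.df["status"] != "dropped"]
        truth = w.truth.rates.set_index(["county", "year", "crop", "kind"])["rate"]
        g = live.set_index(["county", "year", "crop", "kind"])["rate"]
        common = g.index.intersection(truth.index)
        assert len(common) == len(truth)
        assert np.allclose(g.loc[common], truth.loc[common], rtol=1e-9)

    def test_scale_equivariance_of_rates(self, uniform_world):
        w = uniform_world
        stage1 = cnp.other_crops_rate(w.prov_rates, w.prov_totals)
        base = cnp.harmonize(stage1.rates, w.county)
        c = 2.5
        scaled_cons = w.county.consumption.assign(
            consumption=w.county.consumption["consumption"] * c)
        scaled = cnp.CountyStats(w.county.provinces, scaled_cons, w.county.areas)
        out = cnp.harmonize(stage1.rates, scaled)
        key = ["county", "year", "crop", "kind"]
        a = base.df.set_index(key)["rate"].sort_index()
        b = out.df.set_index(key)["rate"].sort_index()
        mask = a.notna()
        assert np.allclose(b[mask], a[mask] * c, rtol=1e-12)
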