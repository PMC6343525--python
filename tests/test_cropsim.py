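"""Daily crop model: limits, balances, orderings, stress indicators."""

import numpy as np
import pytest
from dataclasses import replace

from heliastress.cropsim import (
    GenotypeParameters,
    Management,
    TABLE_GENOTYPES,
    nni,
    simulate,
    stress_indicators,
    temperature_factor,
    thermal_time,
)
from heliastress.synth import ClimateSeries, SoilProfile, gen_climate


def const_climate(n=200, tmean=24.0, rad=20.0, pet=5.0, precip=6.0):
    return ClimateSeries(
        "CONST", 2000,
        tmean=np.full(n, tmean), radiation=np.full(n, rad),
        pet=np.full(n, pet), precip=np.full(n, precip),
    )


class TestThermalTime:
    def test_at_base_zero(self):
        assert np.all(thermal_time(np.full(5, 4.8)) == 0.0)

    def test_hand_value(self):
        assert thermal_time(np.full(5, 14.8))[-1] == pytest.approx(50.0)

    def test_non_decreasing_with_subzero_days(self):
        rng = np.random.default_rng(0)
        tt = thermal_time(rng.uniform(-5, 30, 100))
        assert np.all(np.diff(tt) >= 0)


class TestTemperatureFactor:
    def test_plateau_and_edges(self):
        assert temperature_factor(20.0) == 1.0
        assert temperature_factor(28.0) == 1.0
        assert temperature_factor(4.8) == 0.0
        assert temperature_factor(37.0) == 0.0

    def test_linear_limbs(self):
        assert temperature_factor((4.8 + 20.0) / 2) == pytest.approx(0.5)
        assert temperature_factor(32.5) == pytest.approx(0.5)

    def test_invalid_cardinals_rejected(self):
        with pytest.raises(ValueError, match="cardinal"):
            temperature_factor(20.0, cardinals=(10, 5, 28, 37))


class TestNni:
    def test_critical_uptake_gives_one(self):
        b = 5.0  # t/ha
        crit = 4.53 * b ** (1 - 0.42) * 10.0
        assert nni(b, crit) == pytest.approx(1.0)

    def test_half_critical(self):
        b = 5.0
        crit = 4.53 * b ** (1 - 0.42) * 10.0
        assert nni(b, crit / 2) == pytest.approx(0.5)

    def test_floor_makes_index_continuous(self):
        uptake = 30.0
        assert nni(0.5, uptake) == pytest.approx(nni(1.0, uptake))


class TestSimulateLimits:
    def test_no_stress_yield_equals_closed_form(self):
        g = TABLE_GENOTYPES[0]
        out = simulate(g, const_climate(), SoilProfile(),
                       Management(sowing_doy=1, irrigation="auto"))
        potential = g.harvest_index * g.rue * (out.series["interception"] * 20.0).sum()
        assert abs(out.yield_g_m2 - potential) / potential <= 1e-6
        ind = stress_indicators(out)
        assert all(v <= 1e-9 for v in ind.values())

    def test_all_stress_factors_one_without_stress(self):
        out = simulate(TABLE_GENOTYPES[0], const_climate(),
                       SoilProfile(), Management(sowing_doy=1, irrigation="auto"))
        s = out.series
        for col in ("f_water", "f_nlow", "f_tlow", "f_thigh"):
            assert np.allclose(s[col], 1.0)

    def test_water_depletes_without_rain(self):
        clim = const_climate(precip=0.0)
        out = simulate(TABLE_GENOTYPES[0], clim, SoilProfile(), Management(sowing_doy=1))
        f = out.series["ftsw"].to_numpy()
        grown = out.series["lai"].to_numpy() > 0.05
        assert np.all(np.diff(f[grown]) <= 1e-12)
        assert f[-1] < f[0]

    def test_water_balance_closure(self):
        series, soils, _ = gen_climate("drought", 1, 1, seed=2)
        c = series[0]
        out = simulate(TABLE_GENOTYPES[1], c, soils[c.location_id], Management())
        b = out.water_balance
        lhs = b["atsw_end"] - b["atsw_start"]
        rhs = (b["precip_in"] + b["irrigation_in"] - b["transpiration_out"]
               - b["evaporation_out"] - b["clamp_loss"])
        assert abs(lhs - rhs) <= 1e-9 * max(1.0, b["precip_in"])

    def test_maturity_not_reached_errors(self):
        clim = const_climate(n=95, tmean=6.0)
        with pytest.raises(RuntimeError, match="maturity not reached"):
            simulate(TABLE_GENOTYPES[0], clim, SoilProfile(), Management(sowing_doy=1))

    def test_nan_weather_rejected_with_day(self):
        clim = const_climate()
        clim.tmean[10] = np.nan
        with pytest.raises(ValueError, match="tmean at day index 10"):
            simulate(TABLE_GENOTYPES[0], clim, SoilProfile(), Management(sowing_doy=1))


class TestMonotonicity:
    def test_yield_non_increasing_with_less_rain(self):
        yields = []
        for scale in (1.0, 0.6, 0.3, 0.1, 0.0):
            clim = const_climate(precip=6.0 * scale)
            out = simulate(TABLE_GENOTYPES[0], clim, SoilProfile(),
                           Management(sowing_doy=1))
            yields.append(out.yield_g_m2)
        assert np.all(np.diff(yields) <= 1e-9)

    def test_yield_non_increasing_with_warming(self):
        yields = []
        for dt in (0.0, 2.0, 4.0, 6.0, 8.0):
            clim = const_climate(tmean=24.0 + dt)
            out = simulate(TABLE_GENOTYPES[0], clim, SoilProfile(),
                           Management(sowing_doy=1, irrigation="auto"))
            yields.append(out.yield_g_m2)
        assert np.all(np.diff(yields) <= 1e-9)

    def test_drought_worse_than_optimal(self):
        g = TABLE_GENOTYPES[0]
        outs = {}
        for arch in ("optimal", "drought"):
            series, soils, _ = gen_climate(arch, 1, 1, seed=5)
            c = series[0]
            outs[arch] = simulate(g, c, soils[c.location_id], Management())
        assert outs["drought"].yield_g_m2 < outs["optimal"].yield_g_m2
        assert (stress_indicators(outs["drought"])["SFTSW"]
                > stress_indicators(outs["optimal"])["SFTSW"])

    def test_late_regulating_genotype_transpires_more_under_drought(self):
        """A genotype with a_TR = -13.98 keeps transpiring at mid FTSW
        where a -7.64 genotype has already down-regulated: the ordering
        follows the response curve, and in a shared dry-down the late
        regulator draws the bucket down further."""
        from heliastress.traits import eval_ftsw_response

        assert eval_ftsw_response(-13.98, 0.5) > eval_ftsw_response(-7.64, 0.5)
        slow = replace(TABLE_GENOTYPES[2], a_le=-4.94)  # a_tr = -13.98
        fast = replace(TABLE_GENOTYPES[1], a_le=-4.94)  # a_tr = -7.64
        clim = const_climate(precip=0.0)
        soil = SoilProfile(depth=600.0)
        outs = {
            g.a_tr: simulate(g, clim, soil, Management(sowing_doy=1))
            for g in (slow, fast)
        }
        assert (outs[-13.98].water_balance["transpiration_out"]
                > outs[-7.64].water_balance["transpiration_out"])


class TestStressIndicators:
    def test_constant_deficit_closed_form(self):
        """FTSW held at 0.4 integrates to 0.6 per day of the cycle; a
        40-day window at that level gives SFTSW = 24."""
        g = TABLE_GENOTYPES[0]
        out = simulate(g, const_climate(), SoilProfile(),
                       Management(sowing_doy=1, irrigation="auto"))
        s = out.series.copy()
        s["ftsw"] = 0.4
        out2 = replace_series(out, s)
        span = s["doy"].iloc[-1] - s["doy"].iloc[0]
        assert stress_indicators(out2)["SFTSW"] == pytest.approx(0.6 * span)
        assert 0.6 * 40 == pytest.approx(24.0)

    def test_low_and_high_never_both_positive(self):
        series, soils, _ = gen_climate("heat", 1, 1, seed=1)
        c = series[0]
        out = simulate(TABLE_GENOTYPES[0], c, soils[c.location_id], Management())
        s = out.series
        both = (s["f_tlow"] < 1.0) & (s["f_thigh"] < 1.0)
        assert not both.any()

    def test_additive_over_subwindows(self):
        series, soils, _ = gen_climate("drought", 1, 1, seed=3)
        c = series[0]
        out = simulate(TABLE_GENOTYPES[0], c, soils[c.location_id], Management())
        s = out.series
        doy = s["doy"].to_numpy(dtype=float)
        deficit = 1.0 - s["ftsw"].to_numpy()
        mid = len(doy) // 2
        total = np.trapezoid(deficit, doy)
        parts = np.trapezoid(deficit[: mid + 1], doy[: mid + 1]) + np.trapezoid(
            deficit[mid:], doy[mid:]
        )
        assert parts == pytest.approx(total, rel=1e-12)


def replace_series(out, series):
    from dataclasses import replace as dc_replace
    return dc_replace(out, series=series)
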