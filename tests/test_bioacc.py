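"""Thermal performance, growth, kinetic rates and the warming ratio scan."""

import numpy as np
import pytest

import climfate as cf
from climfate.bioacc import (DEFAULT_CYCLE, closed_form_steady_state,
                             temperature_series)
from climfate.constants import DAYS_PER_YEAR


class TestAnnualTemperature:
    def test_zero_amplitude_is_constant(self):
        days = np.arange(365)
        T = cf.annual_temperature(days, mean=10.0, amplitude=0.0, offset=2.0)
        assert np.all(T == 12.0)

    def test_offset_shifts_everything(self):
        days = np.arange(365)
        base = cf.annual_temperature(days)
        warm = cf.annual_temperature(days, offset=3.0)
        assert np.allclose(warm, base + 3.0)

    def test_annual_mean_is_mean_plus_offset(self):
        days = np.arange(365)
        T = cf.annual_temperature(days, mean=13.5, amplitude=10.5, offset=2.0)
        assert T.mean() == pytest.approx(15.5, abs=1e-9)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            cf.annual_temperature(0.0, amplitude=-1.0)

    def test_peak_in_early_august(self):
        days = np.arange(365)
        T = cf.annual_temperature(days)
        assert 200 <= days[np.argmax(T)] <= 230


class TestThermalPerformance:
    def test_consumption_landmarks(self, traits):
        assert cf.thermal_performance(traits.T_opt, traits) == 1.0
        assert cf.thermal_performance(traits.CT_max, traits) == 0.0
        assert cf.thermal_performance(traits.CT_max + 4.0, traits) == 0.0
        assert cf.thermal_performance(traits.CT_min, traits) == 0.0
        assert cf.thermal_performance(traits.CT_min - 4.0, traits) == 0.0

    def test_consumption_rises_below_optimum(self, traits):
        T = np.linspace(traits.CT_min, traits.T_opt, 30)
        vals = cf.thermal_performance(T, traits)
        assert np.all(np.diff(vals) >= 0.0)
        assert np.all((0.0 <= vals) & (vals <= 1.0))

    def test_q10_doubling(self, traits):
        got = cf.thermal_performance(traits.T_ref_b + 10.0, traits,
                                     "respiration")
        assert got == pytest.approx(traits.Q10)
        # respiration keeps rising beyond CT_max (no cap)
        assert cf.thermal_performance(traits.CT_max + 5.0, traits,
                                      "respiration") > \
            cf.thermal_performance(traits.CT_max, traits, "respiration")

    def test_invalid_traits_rejected(self):
        with pytest.raises(ValueError):
            cf.ThermalTraits(CT_min=20.0, T_opt=10.0, CT_max=30.0)


class TestGrowth:
    def test_starvation_below_ctmin_never_grows(self, traits, bioparams):
        T = np.full(400, traits.CT_min - 3.0)
        W = cf.simulate_growth(traits, bioparams, T)
        assert np.all(np.diff(W) <= 1e-12)
        assert np.all(W >= bioparams.starvation_floor)

    def test_warmer_constant_temperature_grows_faster(self, traits,
                                                      bioparams):
        days = 365
        w_opt = cf.simulate_growth(traits, bioparams,
                                   np.full(days, traits.T_opt))
        # the net-growth optimum sits below T_opt (respiration rises with
        # temperature), so compare against a clearly colder regime
        w_cool = cf.simulate_growth(traits, bioparams,
                                    np.full(days, traits.T_opt - 10.0))
        assert w_opt[-1] > w_cool[-1]

    def test_moderate_warming_helps_excess_warming_hurts(self, traits,
                                                         bioparams):
        # year-3 weights: +1 and +2 degC beat baseline, +3 drops back
        final = {}
        for offset in (0.0, 1.0, 2.0, 3.0):
            W = cf.simulate_growth(traits, bioparams,
                                   temperature_series(3, offset=offset))
            final[offset] = W[-1]
        assert final[1.0] > final[0.0]
        assert final[2.0] > final[1.0]
        assert final[3.0] < final[2.0]

    def test_weight_positive_throughout(self, traits, bioparams):
        W = cf.simulate_growth(traits, bioparams, temperature_series(5))
        assert np.all(W > 0.0)
        assert len(W) == 5 * DAYS_PER_YEAR + 1


class TestRateConstants:
    def test_biotransformation_rate_definition(self, traits, bioparams):
        chem = cf.FishChemical(logKOW=6.0, HL_B=0.1)
        k = cf.rate_constants(10.0, traits.T_ref_b, chem, bioparams, traits)
        assert k["kM"] == pytest.approx(np.log(2) / 0.1)   # 6.93 per day

    def test_no_feeding_below_ctmin(self, traits, bioparams):
        chem = cf.FishChemical(logKOW=6.0, HL_B=10.0)
        k = cf.rate_constants(10.0, traits.CT_min - 1.0, chem, bioparams,
                              traits)
        assert k["kD"] == 0.0
        assert k["kE"] == 0.0

    def test_elimination_falls_with_hydrophobicity(self, traits, bioparams):
        k2 = [cf.rate_constants(10.0, 15.0,
                                cf.FishChemical(logKOW=kow, HL_B=10.0),
                                bioparams, traits)["k2"]
              for kow in (4.0, 5.0, 6.0, 7.0, 8.0)]
        assert np.all(np.diff(k2) < 0.0)

    def test_all_rates_nonnegative(self, traits, bioparams):
        chem = cf.FishChemical(logKOW=5.0, HL_B=1.0)
        k = cf.rate_constants(25.0, 18.0, chem, bioparams, traits)
        for name in ("k1", "k2", "kD", "kE", "kM"):
            assert k[name] >= 0.0


class TestBioaccumulation:
    def test_zero_exposure_stays_clean(self, traits, bioparams):
        chem = cf.FishChemical(logKOW=6.0, HL_B=10.0, C_wd=0.0, C_diet=0.0)
        traj = cf.simulate_bioaccumulation(chem, traits, bioparams)
        assert np.all(traj.concentration == 0.0)

    def test_trajectory_shape(self, traits, bioparams):
        chem = cf.FishChemical(logKOW=6.0, HL_B=10.0)
        traj = cf.simulate_bioaccumulation(chem, traits, bioparams, years=5)
        assert len(traj.day) == 5 * DAYS_PER_YEAR + 1
        assert np.all(traj.weight > 0.0)
        assert np.all(traj.concentration >= 0.0)

    def test_fast_biotransformation_suppresses_burden(self, traits,
                                                      bioparams):
        fast = cf.simulate_bioaccumulation(
            cf.FishChemical(logKOW=7.0, HL_B=0.001), traits, bioparams)
        slow = cf.simulate_bioaccumulation(
            cf.FishChemical(logKOW=7.0, HL_B=1000.0), traits, bioparams)
        y3 = slice(2 * DAYS_PER_YEAR, 3 * DAYS_PER_YEAR)
        # suppression equals the loss-rate ratio, several orders of magnitude
        assert fast.concentration[y3].mean() < \
            1e-4 * slow.concentration[y3].mean()

    def test_burden_monotone_in_halflife(self, traits, bioparams):
        y3 = slice(2 * DAYS_PER_YEAR, 3 * DAYS_PER_YEAR)
        means = [cf.simulate_bioaccumulation(
            cf.FishChemical(logKOW=6.0, HL_B=h), traits,
            bioparams).concentration[y3].mean()
            for h in (0.1, 1.0, 10.0, 100.0, 1000.0)]
        assert np.all(np.diff(means) > 0.0)

    def test_constant_environment_matches_closed_form(self, traits,
                                                      bioparams):
        # below CT_min the fish sits at the starvation floor: constant
        # weight, zero feeding -- the kinetics admit an algebraic solution
        T_cold = traits.CT_min - 5.0
        chem = cf.FishChemical(logKOW=5.0, HL_B=50.0)
        temps = np.full(6 * DAYS_PER_YEAR + 1, T_cold)
        traj = cf.simulate_bioaccumulation(chem, traits, bioparams,
                                           temperatures=temps)
        expected = closed_form_steady_state(
            chem, bioparams.starvation_floor, T_cold, bioparams, traits)
        assert traj.concentration[-1] == pytest.approx(expected, rel=1e-3)


class TestRatioScan:
    @pytest.fixture(scope="class")
    def scan(self):
        return cf.ratio_scan()

    def test_zero_offset_identity(self):
        scan = cf.ratio_scan(logKOW_grid=(2.0, 7.0), HLB_grid=(1.0, 100.0),
                             offsets=(0.0,))
        for col in ("max_ratio_spring_autumn", "min_ratio_summer",
                    "max_ratio_annual", "min_ratio_annual"):
            assert np.allclose(scan[col], 1.0, atol=1e-12)

    def test_no_failed_cells(self, scan):
        assert not scan["failed"].any()
        assert len(scan) == 9 * 5 * 2      # grid cells x offsets

    def test_seasonal_sign_structure(self, scan):
        # fast-metabolizing hydrophobics: warming raises spring/autumn
        # bioaccumulation and lowers it in summer
        fast = scan[(scan["HL_B_d"] <= 1.0) & (scan["logKOW"] > 6.0)]
        for offset in (2.0, 3.0):
            sub = fast[fast["offset_C"] == offset]
            assert sub["max_ratio_spring_autumn"].max() > 1.0
            assert sub["min_ratio_summer"].min() < 1.0

    def test_extremes_live_at_fast_halflife_high_kow(self, scan):
        t3 = scan[scan["offset_C"] == 3.0].copy()
        dev = np.maximum(t3["max_ratio_annual"] - 1.0,
                         1.0 - t3["min_ratio_annual"])
        worst = t3.loc[dev.idxmax()]
        assert worst["HL_B_d"] <= 1.0
        assert worst["logKOW"] > 6.0

    def test_pop_like_chemicals_are_damped(self, scan):
        # persistent hydrophobics respond far less than fast metabolizers
        for offset in (2.0, 3.0):
            sub = scan[scan["offset_C"] == offset]
            fast = sub[(sub["HL_B_d"] <= 1.0) & (sub["logKOW"] > 6.0)]
            pop = sub[(sub["logKOW"] >= 6.0) & (sub["HL_B_d"] >= 100.0)]

            def max_dev(df):
                return max((df["max_ratio_annual"] - 1.0).max(),
                           (1.0 - df["min_ratio_annual"]).max())

            assert max_dev(pop) < max_dev(fast)

    def test_summary_consistent_with_scan(self, scan):
        s = cf.scan_summary(scan)
        t3 = scan[scan["offset_C"] == 3.0]
        assert s["max_spring_autumn_increase_pct"] == pytest.approx(
            100.0 * (t3["max_ratio_spring_autumn"].max() - 1.0))
        assert s["max_summer_fold_decrease"] >= 1.0
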