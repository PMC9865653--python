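"""Sodium scenarios, trajectories and the sodium-to-SBP link."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from saltckd.bundle import EffectParams
from saltckd.exposure import (
    BPDistribution,
    Scenario,
    build_trajectory,
    builtin_scenarios,
    hypertensive_fraction,
    round_sodium_mg,
    salt_to_sodium_mg,
    sbp_mean_shift,
    shifted_bp,
    stratum_targets,
)
from saltckd.strata import stratum_index


class TestSaltSodiumConversion:
    def test_one_gram_of_salt(self):
        assert salt_to_sodium_mg(1.0) == pytest.approx(393.4)
        assert round_sodium_mg(salt_to_sodium_mg(1.0)) == 390.0

    def test_zero(self):
        assert salt_to_sodium_mg(0.0) == 0.0

    def test_five_grams_molar_masses(self):
        # 5000 mg NaCl * 22.99 / 58.44, computed independently
        assert salt_to_sodium_mg(5.0) == pytest.approx(5000 * 22.99 / 58.44, abs=0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            salt_to_sodium_mg(-1.0)


def _flat_baseline(value: float) -> pd.Series:
    return pd.Series(value, index=stratum_index(), dtype=float)


class TestTrajectory:
    def test_sdt_ramp_in_salt_units(self):
        # working in salt grams: 9.6 g/day down to the 5 g/day target over
        # ten equal decrements
        base = _flat_baseline(9.6)
        traj = build_trajectory(base, Scenario("sdt-salt", "absolute_sodium_target_mg", 5.0))
        decrement = traj.iloc[0, 0] - traj.iloc[1, 0]
        assert decrement == pytest.approx(0.46, abs=1e-12)
        assert round_sodium_mg(salt_to_sodium_mg(decrement)) == 180.0

    def test_nphs_ramp_in_salt_units(self):
        base = _flat_baseline(9.6)
        traj = build_trajectory(base, Scenario("nphs-salt", "relative_reduction_fraction", 0.30))
        decrement = traj.iloc[0, 0] - traj.iloc[1, 0]
        assert round(decrement, 2) == 0.29
        assert round_sodium_mg(salt_to_sodium_mg(decrement)) == 110.0

    def test_endpoint_hits_target(self, bundle):
        for scenario in builtin_scenarios():
            traj = build_trajectory(bundle, scenario)
            target = stratum_targets(bundle.sodium_mg, scenario, bundle.population)
            np.testing.assert_allclose(traj.iloc[-1].to_numpy(), target.to_numpy(), atol=1e-9)

    def test_population_mean_target_scaling(self, bundle):
        traj = build_trajectory(bundle, Scenario("SDT", "absolute_sodium_target_mg", 2000.0))
        final_mean = np.average(traj.iloc[-1], weights=bundle.population)
        assert final_mean == pytest.approx(2000.0, abs=1e-9)
        # equal relative reduction in every stratum
        ratios = traj.iloc[-1].to_numpy() / bundle.sodium_mg.to_numpy()
        assert np.ptp(ratios) < 1e-12

    def test_null_target_gives_constant_trajectory(self, bundle):
        mean = float(np.average(bundle.sodium_mg, weights=bundle.population))
        traj = build_trajectory(bundle, Scenario("null", "absolute_sodium_target_mg", mean))
        assert (traj.to_numpy() == traj.to_numpy()[0]).all()

    def test_monotone_then_flat(self, bundle):
        for scenario in builtin_scenarios():
            arr = build_trajectory(bundle, scenario).to_numpy()
            assert (np.diff(arr, axis=0) <= 1e-12).all()
            assert (arr[scenario.ramp_years :] == arr[scenario.ramp_years]).all()
            assert (arr >= 0).all()

    def test_increase_scenario_rejected(self, bundle):
        with pytest.raises(ValueError):
            build_trajectory(bundle, Scenario("up", "absolute_sodium_target_mg", 10000.0))


class TestHypertensiveFraction:
    def test_mean_at_threshold(self):
        assert hypertensive_fraction(BPDistribution(140.0, 18.0)) == pytest.approx(0.5)

    def test_against_normal_cdf(self):
        # independent oracle: scipy's normal survival function
        got = hypertensive_fraction(BPDistribution(120.3, 13.5))
        assert got == pytest.approx(norm.sf(140, 120.3, 13.5), abs=1e-12)
        assert got == pytest.approx(0.0723, abs=5e-4)

    def test_tiny_sd_limit(self):
        assert hypertensive_fraction(BPDistribution(120.0, 1e-9)) < 1e-12


class TestSBPShift:
    def test_full_reference_reduction_in_hypertensives(self):
        eff = EffectParams()
        shift = sbp_mean_shift(1720.0, BPDistribution(200.0, 0.1), eff)
        assert shift == pytest.approx(5.39, abs=1e-9)

    def test_zero_delta(self):
        assert sbp_mean_shift(0.0, BPDistribution(130.0, 10.0), EffectParams()) == 0.0

    def test_mixed_population_weighting(self):
        # 0.5 * (P(>140)*5.39 + P(<=140)*2.42) with the normal tail from scipy
        p = norm.sf(140, 130, 10)
        expected = 0.5 * (p * 5.39 + (1 - p) * 2.42)
        got = sbp_mean_shift(860.0, BPDistribution(130.0, 10.0), EffectParams())
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.446, abs=1e-3)

    @settings(deadline=None, max_examples=50)
    @given(
        d1=st.floats(0, 3000),
        d2=st.floats(0, 3000),
        mean=st.floats(100, 180),
    )
    def test_monotone_in_delta_and_mean(self, d1, d2, mean):
        eff = EffectParams()
        lo, hi = sorted((d1, d2))
        bp = BPDistribution(mean, 15.0)
        assert sbp_mean_shift(lo, bp, eff) <= sbp_mean_shift(hi, bp, eff) + 1e-12
        # higher mean -> larger hypertensive mass -> larger shift
        assert sbp_mean_shift(hi, bp, eff) <= sbp_mean_shift(
            hi, BPDistribution(mean + 5, 15.0), eff
        ) + 1e-12

    def test_sdt_shifts_every_stratum_down_sd_fixed(self, bundle):
        traj = build_trajectory(bundle, Scenario("SDT", "absolute_sodium_target_mg", 2000.0))
        deltas = bundle.sodium_mg.to_numpy() - traj.iloc[-1].to_numpy()
        for j, d in enumerate(deltas):
            bp0 = BPDistribution(bundle.sbp_mean.iloc[j], bundle.sbp_sd.iloc[j])
            bp1 = shifted_bp(bp0, d, bundle.effects)
            assert bp1.mean < bp0.mean
            assert bp1.sd == bp0.sd


def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario("bad", "relative_reduction_fraction", 1.5)
    with pytest.raises(ValueError):
        Scenario("bad", "absolute_salt_reduction_g", -1.0)
    with pytest.raises(ValueError):
        Scenario("bad", "unknown_kind", 1.0)
    with pytest.raises(ValueError):
        Scenario("bad", "relative_reduction_fraction", 0.3, ramp_years=0)
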