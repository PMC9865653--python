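"""Illness-death submodels: cycle arithmetic, case-fatality derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltckd.disease import (
    DiseaseState,
    derive_case_fatality,
    disease_cycle,
    run_disease,
)
from saltckd.strata import AGE_LOWER_BOUNDS, SEXES
from saltckd.synthetic import _disease_march


def rk4_cycle(s0, c0, i, f, dt=1e-4):
    """Independent numerical oracle for one annual cycle of
    dS/dt = -iS, dC/dt = iS - fC."""
    s, c = s0, c0

    def ds(s):
        return -i * s

    def dc(s, c):
        return i * s - f * c

    n = int(round(1.0 / dt))
    for _ in range(n):
        k1s, k1c = ds(s), dc(s, c)
        k2s, k2c = ds(s + dt / 2 * k1s), dc(s + dt / 2 * k1s, c + dt / 2 * k1c)
        k3s, k3c = ds(s + dt / 2 * k2s), dc(s + dt / 2 * k2s, c + dt / 2 * k2c)
        k4s, k4c = ds(s + dt * k3s), dc(s + dt * k3s, c + dt * k3c)
        s += dt / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
        c += dt / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)
    return s, c


class TestDiseaseCycle:
    def test_no_hazards_no_change(self):
        state = DiseaseState(0.9, 0.08, 0.02)
        new = disease_cycle(state, 0.0, 0.0)
        assert new.s == state.s and new.c == state.c
        assert new.dc == pytest.approx(state.dc, abs=1e-12)

    def test_hand_example_against_rk4(self):
        got = disease_cycle(DiseaseState(1.0, 0.0, 0.0), 0.02, 0.1)
        s_ref, c_ref = rk4_cycle(1.0, 0.0, 0.02, 0.1)
        assert got.s == pytest.approx(0.98020, abs=5e-6)
        assert got.c == pytest.approx(0.01884, abs=5e-6)
        assert got.s == pytest.approx(s_ref, abs=1e-10)
        assert got.c == pytest.approx(c_ref, abs=1e-10)

    def test_equal_hazards_limit(self):
        got = disease_cycle(DiseaseState(1.0, 0.0, 0.0), 0.05, 0.05)
        s_ref, c_ref = rk4_cycle(1.0, 0.0, 0.05, 0.05 + 1e-13)
        assert got.c == pytest.approx(c_ref, abs=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(
        i=st.floats(0, 2),
        f=st.floats(0, 2),
        c=st.floats(0, 1),
        d=st.floats(0, 1),
    )
    def test_conservation_and_zero_remission(self, i, f, c, d):
        total = 1.0 + c + d
        state = DiseaseState(1.0 / total, c / total, d / total)
        new = disease_cycle(state, i, f)
        assert new.s + new.c + new.dc == pytest.approx(1.0, abs=1e-12)
        assert min(new) >= -1e-15
        assert new.s <= state.s + 1e-15  # nobody returns to healthy
        assert new.dc >= state.dc - 1e-15  # death is absorbing

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            disease_cycle(DiseaseState(0.7, 0.1, 0.1), 0.1, 0.1)  # sums to 0.9
        with pytest.raises(ValueError):
            disease_cycle(DiseaseState(1.0, 0.0, 0.0), -0.1, 0.1)


class TestCaseFatality:
    def test_ratio_arithmetic(self, bundle):
        f = derive_case_fatality(bundle, "ratio")
        expected = bundle.cause_mortality / bundle.prevalence
        np.testing.assert_allclose(f.to_numpy(), expected.to_numpy())

    def test_zero_mortality_gives_zero(self, bundle):
        b = bundle.copy()
        b.cause_mortality["htn"] = 0.0
        f = derive_case_fatality(b, "ratio")
        assert (f["htn"] == 0.0).all()

    def test_zero_prevalence_with_deaths_names_stratum(self, bundle):
        b = bundle.copy()
        b.prevalence.loc[(45, "male"), "dm"] = 0.0
        with pytest.raises(ValueError, match=r"45.*male|\(45, 'male'\)"):
            derive_case_fatality(b, "ratio")

    def test_ode_consistent_roundtrip(self, bundle):
        # forward-simulate one cause with known constant case fatality,
        # feed the resulting prevalence/mortality back, recover f
        b = bundle.copy()
        f_true = 0.05
        for sex in SEXES:
            inc = b.incidence["gmn"].xs(sex, level="sex").to_numpy()
            prev = _disease_march(inc, np.full_like(inc, f_true), 0.004)
            for k, age in enumerate(AGE_LOWER_BOUNDS):
                b.prevalence.loc[(age, sex), "gmn"] = prev[k]
                b.cause_mortality.loc[(age, sex), "gmn"] = f_true * prev[k]
        derived = derive_case_fatality(b, "ode_consistent")["gmn"]
        assert np.allclose(derived.to_numpy(), f_true, rtol=0.05)

    def test_ode_consistent_tracks_input_prevalence(self, bundle, case_fatality):
        # with the derived f and no intervention, the submodel's prevalence
        # stays near the input prevalence through midlife and old age
        n_bands = len(AGE_LOWER_BOUNDS)
        for sex in SEXES:
            inc = bundle.incidence["htn"].xs(sex, level="sex").to_numpy()
            cf = case_fatality["htn"].xs(sex, level="sex").to_numpy()
            prev_in = bundle.prevalence["htn"].xs(sex, level="sex").to_numpy()
            s, c = 1.0 - prev_in[0], prev_in[0]
            for band in range(n_bands - 1):
                for _ in range(5):
                    from saltckd.disease import cycle_arrays

                    s, c = cycle_arrays(s, c, inc[band], cf[band])
                age = AGE_LOWER_BOUNDS[band + 1]
                if 30 <= age <= 90:
                    modelled = float(c / (s + c))
                    assert modelled == pytest.approx(prev_in[band + 1], rel=0.10)


class TestRunDisease:
    @staticmethod
    def _inputs(t=20):
        n = 3
        i = np.full((n, t), 0.01)
        f = np.full((n, t), 0.04)
        c0 = np.array([0.02, 0.05, 0.1])
        active = np.ones((n, t), dtype=bool)
        return i, f, c0, active

    def test_null_pif_arms_identical(self):
        i, f, c0, active = self._inputs()
        res = run_disease(i, f, np.zeros_like(i), c0, active)
        np.testing.assert_array_equal(res["c_bau"], res["c_int"])
        np.testing.assert_array_equal(res["death_flow_bau"], res["death_flow_int"])

    def test_constant_pif_first_cycle(self):
        i, f, c0, active = self._inputs()
        pif = np.full_like(i, 0.1)
        res = run_disease(i, f, pif, c0, active)
        # hazard reduction is exactly 10%; the one-cycle case count follows
        # the closed form (1 - exp(-0.9 i)) / (1 - exp(-i)) of the hazards
        s0 = 1.0 - c0
        expect_bau = s0 * (1 - np.exp(-0.01))
        expect_int = s0 * (1 - np.exp(-0.009))
        np.testing.assert_allclose(res["incident_flow_bau"][:, 0], expect_bau, rtol=1e-12)
        np.testing.assert_allclose(res["incident_flow_int"][:, 0], expect_int, rtol=1e-12)

    def test_positive_pif_reduces_deaths_every_year(self):
        i, f, c0, active = self._inputs()
        res = run_disease(i, f, np.full_like(i, 0.2), c0, active)
        diff = res["death_flow_bau"] - res["death_flow_int"]
        assert (diff[:, 1:] > 0).all()
        assert (res["c_int"] <= res["c_bau"] + 1e-15).all()

    def test_conservation_both_arms(self):
        i, f, c0, active = self._inputs()
        res = run_disease(i, f, np.full_like(i, 0.3), c0, active)
        for arm in ("bau", "int"):
            total = res[f"s_{arm}"] + res[f"c_{arm}"] + res[f"dc_{arm}"]
            np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_pif_at_or_above_one_rejected(self):
        i, f, c0, active = self._inputs()
        with pytest.raises(ValueError):
            run_disease(i, f, np.full_like(i, 1.5), c0, active)
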