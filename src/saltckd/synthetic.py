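"""Synthetic input-bundle generator.

Real runs of this model require nationally stratified inputs (population,
mortality, CKD epidemiology by cause, sodium intake, measured SBP, CKD
expenditure).  This module fabricates an internally consistent stand-in
population so the whole pipeline is testable offline:

* an adult population pyramid of roughly 19 million people aged 25+;
* Gompertz all-cause mortality, steeper for men, with the terminal band
  inflated so survivorship effectively closes by age 100;
* four CKD cause submodels (hypertensive, diabetic, glomerulonephritic,
  other/unspecified) whose prevalence is obtained by forward integration of
  the zero-remission illness-death equations from age-increasing incidence
  and a known case-fatality schedule -- so case fatality derived downstream
  can be checked against the truth used here;
* a midlife-peaked, male-dominant sodium pattern rescaled so the
  population-weighted mean is exactly 3700 mg/day;
* measured baseline SBP distributions taken verbatim from the embedded
  survey fixture (10-year bands duplicated onto the 5-year grid);
* per-cause annual CKD expenditure consistent with roughly A$500-1200 per
  prevalent case per year (about A$1.9 billion in total).

The ``noisy`` realism setting perturbs the underlying hazards before
integration, so invariants and internal consistency survive the noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import EffectParams, InputBundle
from .strata import AGE_LOWER_BOUNDS, CAUSES, SEXES, stratum_index

TARGET_MEAN_SODIUM_MG = 3700.0

# Baseline measured systolic BP, mean (sd) mmHg, by published 10-year band.
_SBP_SURVEY_ROWS = [
    # band_lower, band_upper, sex, mean, sd
    (25, 34, "male", 120.3, 13.5),
    (35, 44, "male", 121.3, 11.6),
    (45, 54, "male", 126.5, 17.9),
    (55, 64, "male", 132.4, 14.7),
    (65, 74, "male", 134.9, 21.3),
    (75, 84, "male", 136.5, 20.9),
    (85, 120, "male", 140.2, 33.3),
    (25, 34, "female", 108.5, 15.8),
    (35, 44, "female", 112.5, 15.7),
    (45, 54, "female", 119.6, 17.0),
    (55, 64, "female", 126.8, 20.6),
    (65, 74, "female", 133.6, 17.7),
    (75, 84, "female", 137.9, 17.0),
    (85, 120, "female", 140.8, 28.0),
]


def sbp_survey_fixture() -> pd.DataFrame:
    """Published baseline SBP mean/sd by 10-year age band and sex."""
    return pd.DataFrame(
        _SBP_SURVEY_ROWS, columns=["band_lower", "band_upper", "sex", "sbp_mean", "sbp_sd"]
    )


def sbp_baseline_on_grid() -> tuple[pd.Series, pd.Series]:
    """Map the 10-year SBP fixture onto the 15-band model grid.

    Bands above 85 reuse the 85+ values."""
    t1 = sbp_survey_fixture()
    idx = stratum_index()
    means, sds = [], []
    for age, sex in idx:
        row = t1[(t1.sex == sex) & (t1.band_lower <= age) & (age <= t1.band_upper)].iloc[0]
        means.append(row.sbp_mean)
        sds.append(row.sbp_sd)
    return (
        pd.Series(means, index=idx, name="sbp_mean"),
        pd.Series(sds, index=idx, name="sbp_sd"),
    )


# Cause-specific generator parameters: incidence intercept (per person-year
# at age 25), incidence log-slope per year of age, case-fatality intercept
# and slope, prevalence at the first band, true disability weight.
_CAUSE_PARAMS = {
    "htn": dict(i0=4.0e-4, gi=0.045, f0=4.0e-3, gf=1.6e-4, p0=0.004, dw=0.10),
    "dm": dict(i0=3.2e-4, gi=0.042, f0=3.5e-3, gf=1.4e-4, p0=0.003, dw=0.15),
    "gmn": dict(i0=2.6e-4, gi=0.030, f0=5.0e-3, gf=1.8e-4, p0=0.003, dw=0.12),
    "other": dict(i0=6.5e-4, gi=0.040, f0=2.5e-3, gf=1.2e-4, p0=0.006, dw=0.08),
}

_GOMPERTZ = {"male": (6.0e-4, 0.088), "female": (3.5e-4, 0.092)}


def _disease_march(i_bands: np.ndarray, f_bands: np.ndarray, p0: float) -> np.ndarray:
    """Prevalence at each band lower bound from band-constant hazards.

    Integrates dS/da = -iS, dC/da = iS - fC (zero remission, other-cause
    death conditioned out) in annual steps across the 5-year bands and
    records C/(S+C) at each band entry.
    """
    s = 1.0 - p0
    c = p0
    prev = [p0]
    for b in range(len(i_bands) - 1):
        i, f = i_bands[b], f_bands[b]
        for _ in range(5):
            s_new = s * np.exp(-i)
            if abs(i - f) < 1e-12:
                c_new = c * np.exp(-f) + i * s * np.exp(-i)
            else:
                c_new = c * np.exp(-f) + i * s * (np.exp(-f) - np.exp(-i)) / (i - f)
            s, c = s_new, c_new
        prev.append(c / (s + c))
    return np.asarray(prev)


def generate_bundle(
    seed: int,
    realism: str = "smooth",
    effects: EffectParams | None = None,
) -> InputBundle:
    """Generate a complete synthetic :class:`InputBundle`.

    Parameters
    ----------
    seed
        Seeds every random choice; identical seeds give identical bundles.
    realism
        ``"smooth"`` for noiseless schedules, ``"noisy"`` to jitter the
        underlying hazards (multiplicative lognormal, sigma ~ 5-8%).
    """
    if realism not in ("smooth", "noisy"):
        raise ValueError(f"unknown realism {realism!r}")
    rng = np.random.default_rng(seed)
    noisy = realism == "noisy"
    ages = np.asarray(AGE_LOWER_BOUNDS, dtype=float)
    nb = len(ages)
    idx = stratum_index()

    def jitter(shape, sigma):
        # draw in both modes so smooth/noisy share downstream rng state
        z = rng.normal(0.0, sigma, size=shape)
        return np.exp(z) if noisy else np.ones(shape)

    data: dict[str, dict] = {k: {} for k in ("population", "acm_rate", "sodium_mg")}
    per_cause: dict[str, dict] = {
        k: {} for k in ("incidence", "prevalence", "cause_mortality", "yld", "cost_total")
    }

    for sex in SEXES:
        # population pyramid: flat through midlife then Gaussian roll-off
        base = 9.3e5 if sex == "female" else 9.5e5
        rolloff = np.where(ages > 57, np.exp(-(((ages - 57) / 20.0) ** 2)), 1.0)
        old_age_sex = 1.0 if sex == "female" else np.interp(ages, [57, 95], [1.0, 0.7]).clip(max=1.0)
        pop = base * rolloff * old_age_sex * jitter(nb, 0.03)
        data["population"][sex] = np.maximum(pop, 5e3)

        a0, b0 = _GOMPERTZ[sex]
        acm = a0 * np.exp(b0 * (ages - 25.0)) * jitter(nb, 0.05)
        acm[-1] *= 2.2  # close survivorship by age 100
        acm = np.maximum.accumulate(acm)
        data["acm_rate"][sex] = acm

        # sodium: midlife peak, men above women; rescaled to 3700 below
        if sex == "male":
            sod = 4150.0 + 500.0 * np.exp(-(((ages - 45.0) / 18.0) ** 2))
        else:
            sod = 2980.0 + 380.0 * np.exp(-(((ages - 47.0) / 18.0) ** 2))
        data["sodium_mg"][sex] = sod * jitter(nb, 0.02)

        sex_mult = 1.15 if sex == "male" else 0.9
        for cause in CAUSES:
            p = _CAUSE_PARAMS[cause]
            inc = p["i0"] * sex_mult * np.exp(p["gi"] * (ages - 25.0)) * jitter(nb, 0.08)
            cf = (p["f0"] + p["gf"] * (ages - 25.0)) * jitter(nb, 0.08)
            prev = _disease_march(inc, cf, p["p0"] * sex_mult)
            prev = np.maximum.accumulate(prev)  # monotone up to 95 even when noisy
            per_cause["incidence"][(cause, sex)] = inc
            per_cause["prevalence"][(cause, sex)] = prev
            per_cause["cause_mortality"][(cause, sex)] = cf * prev
            per_cause["yld"][(cause, sex)] = p["dw"] * prev

    # rescale sodium so the population-weighted mean is exactly on target
    w = np.concatenate([data["population"][s] for s in SEXES])
    s_all = np.concatenate([data["sodium_mg"][s] for s in SEXES])
    scale = TARGET_MEAN_SODIUM_MG / (np.sum(w * s_all) / np.sum(w))
    for sex in SEXES:
        data["sodium_mg"][sex] = data["sodium_mg"][sex] * scale

    def to_series(d: dict, name: str) -> pd.Series:
        vals = [d[sex][i] for i, age in enumerate(AGE_LOWER_BOUNDS) for sex in SEXES]
        return pd.Series(vals, index=idx, name=name, dtype=float)

    population = to_series(data["population"], "population")
    acm_rate = to_series(data["acm_rate"], "acm_rate")
    sodium_mg = to_series(data["sodium_mg"], "sodium_mg")
    sbp_mean, sbp_sd = sbp_baseline_on_grid()

    frames = {}
    for name in ("incidence", "prevalence", "cause_mortality", "yld"):
        frames[name] = pd.DataFrame(
            {
                cause: to_series(
                    {s: per_cause[name][(cause, s)] for s in SEXES}, cause
                )
                for cause in CAUSES
            }
        )[list(CAUSES)]

    # background all-cause YLD comfortably above the CKD-attributable share
    base_yld = 0.085 + 0.0022 * (np.repeat(ages, 2) - 25.0)
    all_yld = pd.Series(base_yld, index=idx, name="all_yld_rate")
    all_yld = all_yld * (1.0 + rng.normal(0, 0.03, size=len(all_yld)) * noisy)
    all_yld = pd.concat(
        [all_yld, frames["yld"].sum(axis=1) * 1.5], axis=1
    ).max(axis=1)

    # expenditure: per-case cost by cause with a mild age gradient
    per_case = {"htn": 900.0, "dm": 1000.0, "gmn": 1150.0, "other": 540.0}
    age_mult = 1.0 + 0.01 * (np.repeat(ages, 2) - 25.0)
    cost = pd.DataFrame(
        {
            cause: per_case[cause]
            * age_mult
            * frames["prevalence"][cause]
            * population
            * jitter(len(idx), 0.05)
            for cause in CAUSES
        }
    )[list(CAUSES)]
    cost.index = idx

    bundle = InputBundle(
        population=population,
        acm_rate=acm_rate,
        all_yld_rate=all_yld.rename("all_yld_rate"),
        sodium_mg=sodium_mg,
        sbp_mean=sbp_mean,
        sbp_sd=sbp_sd,
        incidence=frames["incidence"],
        prevalence=frames["prevalence"],
        cause_mortality=frames["cause_mortality"],
        yld=frames["yld"],
        cost_total=cost,
        effects=effects or EffectParams(),
        seed=seed,
    )
    bundle.validate()
    return bundle
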