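"""Sodium scenarios, intake trajectories and sodium-to-SBP translation.

Policy scenarios reduce mean daily sodium intake linearly over a ramp
(default ten equal annual decrements, 2020-2029, so the target holds from
the 2029 cycle onward).  Sodium changes translate into a downward shift of
the cohort's systolic BP distribution, with a larger per-mg effect in the
hypertensive fraction of the cohort (mean SBP above 140 mmHg) than in the
normotensive remainder; the SBP standard deviation is held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .bundle import EffectParams, InputBundle
from .strata import BASE_YEAR, MAX_AGE, AGE_LOWER_BOUNDS

# Sodium mass fraction of NaCl from molar masses (22.99 / 58.44).
SODIUM_FRACTION_OF_SALT = 0.3934

#: Survey pairing used when quoting salt-equivalents of the national mean
#: intake: a weighted mean of ~3700 mg sodium is conventionally quoted as
#: 9.6 g salt/day.
BASELINE_SODIUM_MG = 3700.0
BASELINE_SALT_G = 9.6


class BPDistribution(NamedTuple):
    """Normal systolic BP distribution (mmHg)."""

    mean: float
    sd: float


def salt_to_sodium_mg(salt_g: float) -> float:
    """Convert grams of salt (NaCl) to mg of sodium."""
    if salt_g < 0:
        raise ValueError("salt mass must be non-negative")
    return salt_g * 1000.0 * SODIUM_FRACTION_OF_SALT


def round_sodium_mg(sodium_mg: float, nearest: int = 10) -> float:
    """Round a sodium amount to the nearest ``nearest`` mg (reporting helper)."""
    return float(nearest * round(sodium_mg / nearest))


SCENARIO_KINDS = (
    "absolute_sodium_target_mg",
    "relative_reduction_fraction",
    "absolute_salt_reduction_g",
)


@dataclass(frozen=True)
class Scenario:
    """A sodium-reduction policy with a linear ramp.

    ``magnitude`` is interpreted by ``kind``: a population-mean sodium
    target in mg/day, a relative reduction fraction in (0, 1), or an
    absolute salt reduction in g/day applied uniformly per stratum.
    """

    name: str
    kind: str
    magnitude: float
    ramp_years: int = 10
    start_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.magnitude <= 0 and self.kind != "absolute_sodium_target_mg":
            raise ValueError("reduction magnitude must be positive")
        if self.kind == "relative_reduction_fraction" and not (0 < self.magnitude < 1):
            raise ValueError("relative reduction must lie in (0, 1)")
        if self.ramp_years < 1:
            raise ValueError("ramp must span at least one year")


def builtin_scenarios() -> list[Scenario]:
    """The six modelled policy scenarios."""
    return [
        Scenario("SDT", "absolute_sodium_target_mg", 2000.0),
        Scenario("NPHS-30pct", "relative_reduction_fraction", 0.30),
        Scenario("20pct", "relative_reduction_fraction", 0.20),
        Scenario("15pct", "relative_reduction_fraction", 0.15),
        Scenario("salt-1g", "absolute_salt_reduction_g", 1.0),
        Scenario("salt-2g", "absolute_salt_reduction_g", 2.0),
    ]


def scenario_by_name(name: str) -> Scenario:
    for s in builtin_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"no builtin scenario named {name!r}")


def stratum_targets(
    baseline: pd.Series, scenario: Scenario, population: pd.Series | None = None
) -> pd.Series:
    """Post-ramp sodium level per stratum.

    For a population-mean target, every stratum is reduced by the same
    relative factor so the population-weighted mean lands on the target.
    """
    if scenario.kind == "absolute_sodium_target_mg":
        if population is None:
            mean = baseline.mean()
        else:
            mean = float(np.average(baseline, weights=population))
        if scenario.magnitude > mean:
            raise ValueError(
                f"target {scenario.magnitude} exceeds baseline mean {mean:.1f}; "
                "intake increases are not modelled"
            )
        return baseline * (scenario.magnitude / mean)
    if scenario.kind == "relative_reduction_fraction":
        return baseline * (1.0 - scenario.magnitude)
    # absolute_salt_reduction_g
    delta = salt_to_sodium_mg(scenario.magnitude)
    return (baseline - delta).clip(lower=0.0)


def build_trajectory(
    bundle_or_baseline: InputBundle | pd.Series,
    scenario: Scenario,
    end_year: int | None = None,
) -> pd.DataFrame:
    """Annual mean-sodium trajectory, rows = calendar years, cols = strata.

    Baseline holds in ``start_year``; ``ramp_years`` equal decrements are
    applied at the following cycle starts; the target holds thereafter to
    ``end_year`` (default: the year the youngest cohort reaches 100).
    """
    if isinstance(bundle_or_baseline, InputBundle):
        baseline = bundle_or_baseline.sodium_mg
        population = bundle_or_baseline.population
    else:
        baseline = bundle_or_baseline
        population = None
    if end_year is None:
        end_year = scenario.start_year + (MAX_AGE - AGE_LOWER_BOUNDS[0])
    target = stratum_targets(baseline, scenario, population)
    years = np.arange(scenario.start_year, end_year + 1)
    frac = np.minimum(years - scenario.start_year, scenario.ramp_years) / scenario.ramp_years
    values = baseline.to_numpy()[None, :] - frac[:, None] * (baseline - target).to_numpy()[None, :]
    return pd.DataFrame(np.maximum(values, 0.0), index=years, columns=baseline.index)


def hypertensive_fraction(bp: BPDistribution, threshold: float = 140.0) -> float:
    """P(SBP > threshold) under the cohort's normal SBP distribution."""
    if bp.sd <= 0:
        raise ValueError("SBP standard deviation must be positive")
    return 0.5 * math.erfc((threshold - bp.mean) / (bp.sd * math.sqrt(2.0)))


def sbp_mean_shift(
    delta_sodium_mg: float, bp: BPDistribution, eff: EffectParams
) -> float:
    """mmHg reduction in mean SBP for a daily sodium reduction.

    Linear in the sodium change, scaled to the trial reference reduction
    (4.4 g salt ~ 1720 mg sodium), with the hypertensive / normotensive
    effects weighted by the mass of the BP distribution either side of
    140 mmHg.
    """
    if delta_sodium_mg < 0:
        raise ValueError("sodium reduction must be non-negative")
    p_hyp = hypertensive_fraction(bp, eff.hyp_threshold)
    per_ref = p_hyp * eff.effect_hyp.central + (1.0 - p_hyp) * eff.effect_norm.central
    return (delta_sodium_mg / eff.reference_sodium_mg) * per_ref


def shifted_bp(bp: BPDistribution, delta_sodium_mg: float, eff: EffectParams) -> BPDistribution:
    """BP distribution after a sodium reduction: mean lowered, sd unchanged."""
    return BPDistribution(bp.mean - sbp_mean_shift(delta_sodium_mg, bp, eff), bp.sd)
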