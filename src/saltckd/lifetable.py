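"""Proportional multistate lifetable: survivorship, HALYs, decomposition.

Changes in per-cause CKD death flows feed back additively into all-cause
mortality; survivorship declines exponentially within each annual cycle and
person-years use the trapezoid rule.  Life years are weighted for health:
the business-as-usual weight is one minus the all-cause YLD rate, and the
intervention arm earns back the disability of the CKD prevalence it
prevents, valued at background-corrected per-case disability weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import InputBundle
from .strata import CAUSES


@dataclass
class DisabilityWeights:
    """Per-stratum, per-cause disability weights.

    ``crude`` = cause YLD rate / cause prevalence (disability per prevalent
    case).  ``adjusted`` corrects multiplicatively for background
    comorbidity: a prevented case averts its CKD disability only insofar as
    the person is not already disabled by unrelated conditions.
    """

    crude: pd.DataFrame
    adjusted: pd.DataFrame
    background_yld: pd.Series


def disability_weights(bundle: InputBundle, background: str = "multiplicative") -> DisabilityWeights:
    """Derive disability weights from YLD rates and prevalence.

    ``background`` selects the comorbidity correction: ``multiplicative``
    (default) scales by 1 - YLD from non-CKD conditions; ``subtractive``
    applies no scaling (crude weights used as-is against the all-cause
    YLD background).
    """
    if background not in ("multiplicative", "subtractive"):
        raise ValueError(f"unknown background correction {background!r}")
    p = bundle.prevalence
    y = bundle.yld
    bad = (p.to_numpy() <= 0) & (y.to_numpy() > 0)
    if bad.any():
        loc = np.argwhere(bad)[0]
        raise ValueError(
            f"YLD without prevalence at stratum {p.index[loc[0]]}, cause {p.columns[loc[1]]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        crude_arr = np.where(p.to_numpy() > 0, y.to_numpy() / p.to_numpy(), 0.0)
    crude = pd.DataFrame(crude_arr, index=p.index, columns=p.columns)
    if (crude.to_numpy() > 1.0).any():
        raise ValueError("crude disability weight above 1: inconsistent YLD/prevalence inputs")
    byld_other = (bundle.all_yld_rate - y.sum(axis=1)).clip(lower=0.0)
    if background == "multiplicative":
        adjusted = crude.mul(1.0 - byld_other, axis=0)
    else:
        adjusted = crude.copy()
    return DisabilityWeights(crude, adjusted, bundle.all_yld_rate)


def survivorship(mortality: np.ndarray, active: np.ndarray) -> np.ndarray:
    """l(t) paths from per-cycle mortality rates; l(0) = 1.

    ``mortality`` and ``active`` have shape (n_cohorts, n_cycles); the
    returned array has one more column.  Inactive cycles hold l constant.
    """
    if (mortality[active] < 0).any():
        raise ValueError("negative all-cause mortality after disease feedback")
    n, t = mortality.shape
    l = np.empty((n, t + 1))
    l[:, 0] = 1.0
    for k in range(t):
        step = np.where(active[:, k], np.exp(-mortality[:, k]), 1.0)
        l[:, k + 1] = l[:, k] * step
    return l


def person_years(l: np.ndarray) -> np.ndarray:
    """Trapezoid person-years per cycle: (l(t) + l(t+1)) / 2."""
    return 0.5 * (l[:, :-1] + l[:, 1:])


def decompose_haly_by_cause(
    total_gain: float,
    morbidity_by_cause: dict[str, float],
    deathflow_reduction_by_cause: dict[str, float],
) -> dict[str, float]:
    """Split a total HALY gain into per-cause contributions.

    Morbidity gains (averted prevalent disability) are attributed directly;
    the remaining mortality-driven life-year gains are allocated in
    proportion to each cause's cumulative death-flow reduction.  Components
    sum to the total by construction.
    """
    morbidity_total = sum(morbidity_by_cause.values())
    mortality_total = total_gain - morbidity_total
    red_total = sum(deathflow_reduction_by_cause.values())
    out = {}
    for cause in CAUSES:
        share = (
            deathflow_reduction_by_cause.get(cause, 0.0) / red_total if red_total != 0 else 0.0
        )
        out[cause] = morbidity_by_cause.get(cause, 0.0) + mortality_total * share
    return out
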