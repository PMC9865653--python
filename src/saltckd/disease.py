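"""Illness-death Markov submodels for the four CKD causes.

Each cause is a three-live-state process (healthy S, prevalent C, dead from
the cause Dc), conditional on surviving all other causes, advanced in
annual cycles with the exact constant-hazard solution of

    dS/dt = -i S        dC/dt = i S - f C        (zero remission)

Case fatality f (mortality hazard among prevalent cases) is rarely
published, so it is derived internally from observed incidence, prevalence
and cause-specific mortality: either crudely (mortality / prevalence) or
by solving the illness-death equations band-by-band up the age range for
the f that reproduces the observed prevalence gradient.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bundle import InputBundle
from .strata import AGE_LOWER_BOUNDS, CAUSES, SEXES


class DiseaseState(NamedTuple):
    """Proportions (healthy, prevalent, dead-from-cause); sums to 1."""

    s: float
    c: float
    dc: float


def _validate_state(state: DiseaseState) -> None:
    if min(state) < -1e-12 or abs(sum(state) - 1.0) > 1e-9:
        raise ValueError(f"invalid disease state {state}")


def cycle_arrays(s, c, i, f):
    """One annual cycle of the closed-form solution, elementwise on arrays.

    Returns (s', c').  Near i == f the removable singularity is replaced by
    its limit i*s*exp(-i).
    """
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    i = np.asarray(i, dtype=float)
    f = np.asarray(f, dtype=float)
    ei, ef = np.exp(-i), np.exp(-f)
    diff = i - f
    safe = np.where(np.abs(diff) < 1e-12, 1.0, diff)
    inflow = np.where(np.abs(diff) < 1e-12, i * s * ei, i * s * (ef - ei) / safe)
    return s * ei, c * ef + inflow


def disease_cycle(state: DiseaseState, i: float, f: float) -> DiseaseState:
    """Advance one annual cycle with incidence ``i`` and case fatality ``f``."""
    if i < 0 or f < 0:
        raise ValueError("hazards must be non-negative")
    _validate_state(state)
    s1, c1 = cycle_arrays(state.s, state.c, i, f)
    return DiseaseState(float(s1), float(c1), 1.0 - float(s1) - float(c1))


def _march_band(s: float, c: float, i: float, f: float, n_years: int = 5):
    for _ in range(n_years):
        s, c = cycle_arrays(s, c, i, f)
    return float(s), float(c)


def derive_case_fatality(bundle: InputBundle, method: str = "ode_consistent") -> pd.DataFrame:
    """Case-fatality rates per stratum and cause.

    ``ratio``: f = cause mortality / prevalence (zero where both are zero).
    ``ode_consistent``: marches the illness-death equations up the age
    bands, choosing per band the f that reproduces the observed prevalence
    at the next band entry (bisection to 1e-8); the terminal band falls
    back to the ratio estimate.
    """
    if method not in ("ratio", "ode_consistent"):
        raise ValueError(f"unknown method {method!r}")
    m = bundle.cause_mortality
    p = bundle.prevalence
    bad = (p.to_numpy() <= 0) & (m.to_numpy() > 0)
    if bad.any():
        loc = np.argwhere(bad)[0]
        stratum = m.index[loc[0]]
        raise ValueError(
            f"zero prevalence with nonzero cause mortality at stratum {stratum}, "
            f"cause {m.columns[loc[1]]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p.to_numpy() > 0, m.to_numpy() / p.to_numpy(), 0.0)
    f_ratio = pd.DataFrame(ratio, index=m.index, columns=m.columns)
    if method == "ratio":
        return f_ratio

    out = f_ratio.copy()
    f_max = 10.0
    for sex in SEXES:
        for cause in CAUSES:
            inc = bundle.incidence[cause].xs(sex, level="sex").to_numpy()
            prev = p[cause].xs(sex, level="sex").to_numpy()
            c = prev[0]
            s = 1.0 - c
            for b in range(len(AGE_LOWER_BOUNDS) - 1):
                target = prev[b + 1]

                def prev_after(f: float) -> float:
                    s1, c1 = _march_band(s, c, inc[b], f)
                    return c1 / (s1 + c1)

                # prevalence after the band is decreasing in f
                if target >= prev_after(0.0):
                    f_b = 0.0
                elif target <= prev_after(f_max):
                    f_b = f_max
                else:
                    f_b = brentq(lambda f: prev_after(f) - target, 0.0, f_max, xtol=1e-8)
                out.loc[(AGE_LOWER_BOUNDS[b], sex), cause] = f_b
                s, c = _march_band(s, c, inc[b], f_b)
    return out


def run_disease(
    i_base: np.ndarray,
    f: np.ndarray,
    pif: np.ndarray,
    c0: np.ndarray,
    active: np.ndarray,
) -> dict[str, np.ndarray]:
    """Run BAU and intervention arms of one cause across cohorts.

    All inputs are arrays of shape (n_cohorts, n_cycles) except ``c0``
    (initial prevalence per cohort) and ``active`` (bool mask of live
    cohort-cycles).  Intervention incidence is ``i_base * (1 - pif)``; the
    BAU arm uses PIF = 0.  Returns state paths (n_cohorts, n_cycles + 1)
    and per-cycle incident and cause-death flows for both arms.
    """
    n, t = i_base.shape
    if np.any(pif >= 1.0 + 1e-12):
        raise ValueError("PIF must be below 1")
    out: dict[str, np.ndarray] = {}
    for arm, i_arr in (("bau", i_base), ("int", i_base * (1.0 - pif))):
        i_arr = np.where(active, np.maximum(i_arr, 0.0), 0.0)
        f_arr = np.where(active, f, 0.0)
        s = np.empty((n, t + 1))
        c = np.empty((n, t + 1))
        s[:, 0] = 1.0 - c0
        c[:, 0] = c0
        for k in range(t):
            s[:, k + 1], c[:, k + 1] = cycle_arrays(s[:, k], c[:, k], i_arr[:, k], f_arr[:, k])
        dc = 1.0 - s - c
        out[f"s_{arm}"] = s
        out[f"c_{arm}"] = c
        out[f"dc_{arm}"] = dc
        out[f"incident_flow_{arm}"] = s[:, :-1] - s[:, 1:]
        out[f"death_flow_{arm}"] = dc[:, 1:] - dc[:, :-1]
    return out
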