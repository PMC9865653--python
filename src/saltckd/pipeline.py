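"""End-to-end scenario runner.

Simulates two identical closed cohorts of adults alive in 2019 -- one under
business as usual, one under a sodium-reduction scenario -- in annual
cycles until death or age 100 (calendar year 2094 for the youngest band).
The per-cycle chain is: sodium trajectory -> SBP distribution shift ->
per-cause potential impact fraction -> illness-death submodels -> lifetable
with mortality feedback -> HALYs, averted events and discounted cost
offsets.  The difference between the arms is the scenario's impact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import InputBundle
from .disease import derive_case_fatality, run_disease
from .economics import discount_factors, per_capita_costs
from .exposure import (
    BPDistribution,
    Scenario,
    build_trajectory,
    sbp_mean_shift,
    builtin_scenarios,
    scenario_by_name,
)
from .lifetable import (
    decompose_haly_by_cause,
    disability_weights,
    person_years,
    survivorship,
)
from .pif import RRFunction, mean_rr
from .strata import AGE_LOWER_BOUNDS, BASE_YEAR, CAUSES, MAX_AGE, SEXES, stratum_index

HORIZON_2030_END = 2030  # cycles starting 2019..2029: "between 2019 and 2030"

MEASURES = (
    "incident_cases_averted",
    "incident_relative_pct",
    "ckd_deaths_averted",
    "deaths_relative_pct",
    "haly_gain",
    "savings_aud",
)


def _grid(series: pd.Series) -> np.ndarray:
    """Reshape a stratum Series to (n_bands, n_sexes)."""
    return series.to_numpy().reshape(len(AGE_LOWER_BOUNDS), len(SEXES))


@dataclass
class ScenarioResult:
    """Aggregated outcomes of one scenario run (intervention minus BAU)."""

    scenario: Scenario
    table: pd.DataFrame  # columns: sex, horizon, measure, value
    haly_by_cause: pd.DataFrame  # columns: sex, horizon, cause, value
    mean_sbp_drop: dict[str, float]  # population-weighted mmHg at end of ramp
    detail: pd.DataFrame | None = None

    def value(self, measure: str, sex: str = "total", horizon: str = "lifetime") -> float:
        t = self.table
        row = t[(t.measure == measure) & (t.sex == sex) & (t.horizon == horizon)]
        if len(row) != 1:
            raise KeyError((measure, sex, horizon))
        return float(row.value.iloc[0])

    def summary(self) -> dict[str, float]:
        out = {
            f"{r.measure}|{r.sex}|{r.horizon}": r.value for r in self.table.itertuples()
        }
        for r in self.haly_by_cause.itertuples():
            out[f"haly_{r.cause}|{r.sex}|{r.horizon}"] = r.value
        for sex, v in self.mean_sbp_drop.items():
            out[f"sbp_drop|{sex}|2030"] = v
        return out


def _pif_matrix(
    bundle: InputBundle, traj: pd.DataFrame, scenario: Scenario
) -> dict[str, np.ndarray]:
    """PIF per cause on (stratum, ramp-distinct year) with post-ramp reuse.

    Sodium deltas change only during the ramp, so only ramp_years + 1
    distinct PIF values exist per stratum and cause.
    """
    eff = bundle.effects
    baseline = bundle.sodium_mg.to_numpy()
    n_strata = len(baseline)
    n_distinct = scenario.ramp_years + 1
    deltas = baseline[None, :] - traj.to_numpy()[:n_distinct, :]  # (year, stratum)
    means = bundle.sbp_mean.to_numpy()
    sds = bundle.sbp_sd.to_numpy()
    out = {}
    for cause in CAUSES:
        rr = RRFunction(eff.rr[cause].central, eff.tmrel, eff.rr_unit_mmhg)
        mat = np.zeros((n_strata, n_distinct))
        for j in range(n_strata):
            bp0 = BPDistribution(means[j], sds[j])
            a0 = mean_rr(bp0, rr)  # baseline integral shared by all ramp years
            for y in range(n_distinct):
                d = deltas[y, j]
                if d <= 0:
                    continue
                bp1 = BPDistribution(bp0.mean - sbp_mean_shift(d, bp0, eff), bp0.sd)
                mat[j, y] = (a0 - mean_rr(bp1, rr)) / a0
        out[cause] = mat
    return out


def run_scenario(
    bundle: InputBundle,
    scenario: Scenario,
    *,
    cf_method: str = "ode_consistent",
    case_fatality: pd.DataFrame | None = None,
    discount_rate_haly: float = 0.0,
    discount_rate_cost: float = 0.03,
    background: str = "multiplicative",
    keep_detail: bool = False,
) -> ScenarioResult:
    """Run BAU and intervention arms for one scenario and aggregate."""
    idx = stratum_index()
    n_bands = len(AGE_LOWER_BOUNDS)
    cohorts = list(idx)  # (age0, sex)
    n = len(cohorts)
    t_max = MAX_AGE - AGE_LOWER_BOUNDS[0]
    years = BASE_YEAR + np.arange(t_max)

    age0 = np.array([a for a, _ in cohorts])
    sex_idx = np.array([SEXES.index(s) for _, s in cohorts])
    # band index of each cohort at each cycle, capped at the terminal band
    band_idx = np.minimum((age0[:, None] + np.arange(t_max)[None, :] - 25) // 5, n_bands - 1)
    active = (age0[:, None] + np.arange(t_max)[None, :]) < MAX_AGE

    def at(series: pd.Series) -> np.ndarray:
        return _grid(series)[band_idx, sex_idx[:, None]]

    if case_fatality is None:
        case_fatality = derive_case_fatality(bundle, cf_method)
    dw = disability_weights(bundle, background)
    costs = per_capita_costs(bundle, discount_rate_cost, discount_rate_haly)

    traj = build_trajectory(bundle, scenario, end_year=int(years[-1]) + 1)
    pif_mats = _pif_matrix(bundle, traj, scenario)
    year_slot = np.minimum(np.arange(t_max), scenario.ramp_years)
    flat_stratum = band_idx * len(SEXES) + sex_idx[:, None]  # index into stratum order

    n0 = bundle.population.to_numpy()  # cohort sizes, stratum order == cohort order
    m_bau = at(bundle.acm_rate)
    byld = at(bundle.all_yld_rate)

    disease = {}
    df_diff_total = np.zeros((n, t_max))
    for cause in CAUSES:
        pif = pif_mats[cause][flat_stratum, year_slot[None, :]]
        res = run_disease(
            i_base=at(bundle.incidence[cause]),
            f=at(case_fatality[cause]),
            pif=pif,
            c0=_grid(bundle.prevalence[cause])[band_idx[:, 0], sex_idx],
            active=active,
        )
        disease[cause] = res
        df_diff_total += res["death_flow_bau"] - res["death_flow_int"]

    m_int = m_bau - df_diff_total
    if (m_int[active] < 0).any():
        raise ValueError("disease feedback drove all-cause mortality negative")

    l_bau = survivorship(np.where(active, m_bau, 0.0), active)
    l_int = survivorship(np.where(active, m_int, 0.0), active)
    ly_bau = person_years(l_bau) * active
    ly_int = person_years(l_int) * active

    dfac_h = discount_factors(years, discount_rate_haly)
    dfac_c = discount_factors(years, discount_rate_cost)

    w_bau = 1.0 - byld
    dc_morb = {}  # per-cause morbidity HALY term, (n, t)
    savings = np.zeros((n, t_max))
    for cause in CAUSES:
        res = disease[cause]
        c_b, s_b = res["c_bau"][:, :-1], res["s_bau"][:, :-1]
        c_i, s_i = res["c_int"][:, :-1], res["s_int"][:, :-1]
        dw_adj = at(dw.adjusted[cause])
        dc_morb[cause] = n0[:, None] * ly_int * dw_adj * (c_b - c_i) * dfac_h[None, :]
        cpc = at(costs.per_capita_cost[cause])
        prev_b = n0[:, None] * l_bau[:, :-1] * np.divide(
            c_b, c_b + s_b, out=np.zeros_like(c_b), where=(c_b + s_b) > 0
        )
        prev_i = n0[:, None] * l_int[:, :-1] * np.divide(
            c_i, c_i + s_i, out=np.zeros_like(c_i), where=(c_i + s_i) > 0
        )
        savings += (prev_b - prev_i) * cpc * dfac_c[None, :] * active

    w_int = w_bau + sum(
        at(dw.adjusted[c]) * (disease[c]["c_bau"][:, :-1] - disease[c]["c_int"][:, :-1])
        for c in CAUSES
    )
    haly_bau = n0[:, None] * ly_bau * w_bau * dfac_h[None, :]
    haly_int = n0[:, None] * ly_int * w_int * dfac_h[None, :]

    horizons = {"2030": years < HORIZON_2030_END, "lifetime": np.ones_like(years, dtype=bool)}
    sex_groups = {
        "male": sex_idx == 0,
        "female": sex_idx == 1,
        "total": np.ones(n, dtype=bool),
    }

    rows, haly_rows = [], []
    for sex, smask in sex_groups.items():
        for horizon, hmask in horizons.items():
            mask = smask[:, None] & hmask[None, :] & active
            inc_b = inc_av = dth_b = dth_av = 0.0
            morb = {}
            dfred = {}
            for cause in CAUSES:
                res = disease[cause]
                ib = (n0[:, None] * l_bau[:, :-1] * res["incident_flow_bau"])[mask].sum()
                ii = (n0[:, None] * l_int[:, :-1] * res["incident_flow_int"])[mask].sum()
                db = (n0[:, None] * l_bau[:, :-1] * res["death_flow_bau"])[mask].sum()
                di = (n0[:, None] * l_int[:, :-1] * res["death_flow_int"])[mask].sum()
                inc_b += ib
                inc_av += ib - ii
                dth_b += db
                dth_av += db - di
                morb[cause] = dc_morb[cause][mask].sum()
                dfred[cause] = (
                    n0[:, None] * (res["death_flow_bau"] - res["death_flow_int"])
                )[mask].sum()
            haly_gain = (haly_int - haly_bau)[mask].sum()
            per_cause = decompose_haly_by_cause(haly_gain, morb, dfred)
            for cause, v in per_cause.items():
                haly_rows.append((sex, horizon, cause, v))
            vals = {
                "incident_cases_averted": inc_av,
                "incident_relative_pct": 100.0 * inc_av / inc_b if inc_b else 0.0,
                "ckd_deaths_averted": dth_av,
                "deaths_relative_pct": 100.0 * dth_av / dth_b if dth_b else 0.0,
                "haly_gain": haly_gain,
                "savings_aud": savings[mask].sum(),
            }
            for m, v in vals.items():
                rows.append((sex, horizon, m, v))

    # population-weighted mean SBP drop once the ramp is complete
    deltas_end = bundle.sodium_mg.to_numpy() - traj.to_numpy()[scenario.ramp_years, :]
    shift = np.array(
        [
            sbp_mean_shift(
                max(d, 0.0),
                BPDistribution(bundle.sbp_mean.iloc[j], bundle.sbp_sd.iloc[j]),
                bundle.effects,
            )
            for j, d in enumerate(deltas_end)
        ]
    )
    pop = bundle.population.to_numpy()
    mean_sbp_drop = {}
    for sex, smask in sex_groups.items():
        mean_sbp_drop[sex] = float(np.average(shift[smask], weights=pop[smask]))

    detail = None
    if keep_detail:
        recs = []
        for cause in CAUSES:
            res = disease[cause]
            for arm in ("bau", "int"):
                for j, (a0, sex) in enumerate(cohorts):
                    tj = MAX_AGE - a0
                    for k in range(tj):
                        recs.append(
                            (
                                int(years[k]),
                                f"{a0}-{a0 + 4}",
                                sex,
                                cause,
                                arm,
                                res[f"s_{arm}"][j, k],
                                res[f"c_{arm}"][j, k],
                                res[f"dc_{arm}"][j, k],
                                res[f"incident_flow_{arm}"][j, k],
                                res[f"death_flow_{arm}"][j, k],
                            )
                        )
        detail = pd.DataFrame(
            recs,
            columns=[
                "year",
                "cohort",
                "sex",
                "cause",
                "arm",
                "S",
                "C",
                "Dc",
                "incident_flow",
                "death_flow",
            ],
        )

    return ScenarioResult(
        scenario=scenario,
        table=pd.DataFrame(rows, columns=["sex", "horizon", "measure", "value"]),
        haly_by_cause=pd.DataFrame(haly_rows, columns=["sex", "horizon", "cause", "value"]),
        mean_sbp_drop=mean_sbp_drop,
        detail=detail,
    )


@dataclass
class RunConfig:
    """Declarative description of a full multi-scenario run."""

    bundle_dir: str | None = None
    generate_seed: int | None = 1
    realism: str = "smooth"
    scenarios: list[str] = field(default_factory=lambda: [s.name for s in builtin_scenarios()])
    horizons: list[str] = field(default_factory=lambda: ["2030", "lifetime"])
    discount_rate_haly: float = 0.0
    discount_rate_cost: float = 0.03
    cf_method: str = "ode_consistent"
    draws: int = 0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not set(self.horizons) <= {"2030", "lifetime"}:
            raise ValueError("horizons must be a subset of {2030, lifetime}")
        if len(set(self.scenarios)) != len(self.scenarios):
            raise ValueError("scenario names must be unique")


def run_all(config: RunConfig, bundle: InputBundle | None = None) -> pd.DataFrame:
    """Run every configured scenario; optionally write artifacts.

    Returns the tidy results table (scenario x sex x horizon x measure).
    Writing is triggered by ``config.out_dir``; a JSON log records the
    config hash so reruns are auditable.
    """
    from .synthetic import generate_bundle
    from .bundle import read_bundle
    from .uncertainty import PSAConfig, run_psa

    if bundle is None:
        if config.bundle_dir is not None:
            bundle = read_bundle(config.bundle_dir)
        elif config.generate_seed is not None:
            bundle = generate_bundle(config.generate_seed, config.realism)
        else:
            raise ValueError("config names neither a bundle directory nor a generator seed")
    bundle.validate()

    case_fatality = derive_case_fatality(bundle, config.cf_method)
    frames = []
    psa_frames = []
    for name in config.scenarios:
        scenario = scenario_by_name(name)
        res = run_scenario(
            bundle,
            scenario,
            case_fatality=case_fatality,
            discount_rate_haly=config.discount_rate_haly,
            discount_rate_cost=config.discount_rate_cost,
        )
        tab = pd.concat(
            [
                res.table,
                res.haly_by_cause.assign(
                    measure=lambda d: "haly_" + d.cause, value=res.haly_by_cause.value
                )[["sex", "horizon", "measure", "value"]],
            ]
        )
        tab.insert(0, "scenario", name)
        frames.append(tab[tab.horizon.isin(config.horizons)])
        if config.draws:
            psa = run_psa(
                bundle,
                scenario,
                PSAConfig(n_draws=config.draws, seed=config.seed),
                discount_rate_haly=config.discount_rate_haly,
                discount_rate_cost=config.discount_rate_cost,
            )
            psa.insert(0, "scenario", name)
            psa_frames.append(psa)

    results = pd.concat(frames, ignore_index=True)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        pivot = {
            name: {
                f"{r.measure}|{r.sex}|{r.horizon}": r.value
                for r in results[results.scenario == name].itertuples()
            }
            for name in config.scenarios
        }
        (out / "results.json").write_text(json.dumps(pivot, indent=1))
        if psa_frames:
            pd.concat(psa_frames, ignore_index=True).to_csv(out / "psa.csv", index=False)
        cfg = json.dumps(config.__dict__, sort_keys=True, default=str)
        log = {
            "config": json.loads(cfg),
            "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
            "bundle_seed": bundle.seed,
        }
        (out / "run.log").write_text(json.dumps(log, indent=1))
    return results
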