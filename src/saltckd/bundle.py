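"""Input containers: stratified epidemiology, exposure, costs and effect sizes.

An :class:`InputBundle` carries everything one model run needs, stratified by
the 15 x 2 age-sex grid: population counts, all-cause mortality, all-cause
YLD rates, per-cause CKD incidence / prevalence / mortality / YLD, mean daily
sodium, systolic BP distribution parameters and annual CKD expenditure.
Bundles serialize to a directory of tidy CSV files plus a JSON metadata file
holding the :class:`EffectParams` and generator seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .strata import AGE_LOWER_BOUNDS, CAUSES, SEXES, stratum_index


@dataclass(frozen=True)
class CIParam:
    """A parameter with a central estimate and a 95% confidence interval."""

    central: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.central <= self.hi):
            raise ValueError(
                f"CI bounds inverted or central outside CI: {self.central} ({self.lo}, {self.hi})"
            )


@dataclass(frozen=True)
class EffectParams:
    """Sodium-to-SBP effect sizes and SBP-to-CKD relative risks.

    ``effect_hyp`` / ``effect_norm`` are the mmHg SBP drops per
    ``reference_sodium_mg`` daily sodium reduction in people with mean SBP
    above / below ``hyp_threshold``.  ``rr`` maps each CKD cause to the
    relative risk per ``rr_unit_mmhg`` of SBP above the theoretical minimum
    risk exposure level ``tmrel``.
    """

    effect_hyp: CIParam = CIParam(5.39, 4.15, 6.62)
    effect_norm: CIParam = CIParam(2.42, 1.29, 3.56)
    reference_sodium_mg: float = 1720.0
    reference_salt_g: float = 4.4
    hyp_threshold: float = 140.0
    tmrel: float = 115.0
    rr_unit_mmhg: float = 10.0
    rr: dict[str, CIParam] = field(
        default_factory=lambda: {
            "htn": CIParam(1.42, 1.28, 1.58),
            "dm": CIParam(1.31, 1.19, 1.44),
            "gmn": CIParam(1.18, 1.08, 1.29),
            "other": CIParam(1.26, 1.15, 1.38),
        }
    )

    def __post_init__(self) -> None:
        if not (self.effect_hyp.central > self.effect_norm.central > 0):
            raise ValueError("expected effect_hyp > effect_norm > 0")
        if not self.tmrel < self.hyp_threshold:
            raise ValueError("TMREL must lie below the hypertension threshold")
        for cause, p in self.rr.items():
            if p.central <= 1:
                raise ValueError(f"relative risk for {cause} must exceed 1")


# Scalar per-stratum quantities (pandas Series on the stratum index).
SCALAR_FIELDS = ("population", "acm_rate", "all_yld_rate", "sodium_mg", "sbp_mean", "sbp_sd")
# Per-cause quantities (DataFrames: stratum index x cause columns).
CAUSE_FIELDS = ("incidence", "prevalence", "cause_mortality", "yld", "cost_total")


@dataclass
class InputBundle:
    population: pd.Series
    acm_rate: pd.Series
    all_yld_rate: pd.Series
    sodium_mg: pd.Series
    sbp_mean: pd.Series
    sbp_sd: pd.Series
    incidence: pd.DataFrame
    prevalence: pd.DataFrame
    cause_mortality: pd.DataFrame
    yld: pd.DataFrame
    cost_total: pd.DataFrame
    effects: EffectParams = field(default_factory=EffectParams)
    seed: int | None = None
    # relative standard errors used by the probabilistic sensitivity analysis
    sodium_rse: float = 0.02
    sbp_mean_se: float = 0.5
    cost_rse: float = 0.10

    def validate(self) -> None:
        """Raise ValueError on the first violated invariant."""
        idx = stratum_index()
        for name in SCALAR_FIELDS:
            s = getattr(self, name)
            if not s.index.equals(idx):
                raise ValueError(f"{name}: wrong stratum index")
            if not np.isfinite(s.to_numpy()).all():
                raise ValueError(f"{name}: non-finite values")
        for name in CAUSE_FIELDS:
            df = getattr(self, name)
            if not df.index.equals(idx) or tuple(df.columns) != CAUSES:
                raise ValueError(f"{name}: wrong index or cause columns")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"{name}: negative values")
        if (self.population <= 0).any():
            raise ValueError("population must be positive")
        if (self.acm_rate < 0).any():
            raise ValueError("all-cause mortality must be non-negative")
        if (self.sodium_mg <= 0).any():
            raise ValueError("sodium intake must be positive")
        if (self.sbp_sd <= 0).any():
            raise ValueError("SBP standard deviation must be positive")
        if ((self.prevalence < 0) | (self.prevalence > 1)).any().any():
            raise ValueError("prevalence proportions must lie in [0, 1]")
        if (self.prevalence.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("summed cause prevalence exceeds 1")
        if (self.cause_mortality.sum(axis=1) > self.acm_rate + 1e-12).any():
            raise ValueError("cause mortality exceeds all-cause mortality")
        if (self.yld.sum(axis=1) > self.all_yld_rate + 1e-12).any():
            raise ValueError("cause YLD exceeds all-cause YLD")

    def copy(self) -> "InputBundle":
        return InputBundle(
            **{n: getattr(self, n).copy() for n in SCALAR_FIELDS},
            **{n: getattr(self, n).copy() for n in CAUSE_FIELDS},
            effects=self.effects,
            seed=self.seed,
            sodium_rse=self.sodium_rse,
            sbp_mean_se=self.sbp_mean_se,
            cost_rse=self.cost_rse,
        )


def _series_to_frame(s: pd.Series) -> pd.DataFrame:
    out = s.rename("value").reset_index()
    out["age_group"] = out["age"].map(lambda a: f"{a}-{a + 4}")
    return out[["age_group", "sex", "value"]]


def _frame_from_csv(path: Path) -> pd.Series:
    df = pd.read_csv(path, float_precision="round_trip")
    df["age"] = df["age_group"].str.split("-").str[0].astype(int)
    s = df.set_index(["age", "sex"])["value"]
    return s.reindex(stratum_index())


def write_bundle(bundle: InputBundle, directory: str | Path) -> None:
    """Serialize a bundle to ``directory`` as CSV files + metadata.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in SCALAR_FIELDS:
        _series_to_frame(getattr(bundle, name)).to_csv(d / f"{name}.csv", index=False)
    for name in CAUSE_FIELDS:
        df = getattr(bundle, name)
        for cause in CAUSES:
            _series_to_frame(df[cause]).to_csv(d / f"{name}_{cause}.csv", index=False)
    eff = bundle.effects
    meta = {
        "seed": bundle.seed,
        "sodium_rse": bundle.sodium_rse,
        "sbp_mean_se": bundle.sbp_mean_se,
        "cost_rse": bundle.cost_rse,
        "effects": {
            "effect_hyp": asdict(eff.effect_hyp),
            "effect_norm": asdict(eff.effect_norm),
            "reference_sodium_mg": eff.reference_sodium_mg,
            "reference_salt_g": eff.reference_salt_g,
            "hyp_threshold": eff.hyp_threshold,
            "tmrel": eff.tmrel,
            "rr_unit_mmhg": eff.rr_unit_mmhg,
            "rr": {c: asdict(p) for c, p in eff.rr.items()},
        },
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))


def read_bundle(directory: str | Path) -> InputBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    em = meta["effects"]
    effects = EffectParams(
        effect_hyp=CIParam(**em["effect_hyp"]),
        effect_norm=CIParam(**em["effect_norm"]),
        reference_sodium_mg=em["reference_sodium_mg"],
        reference_salt_g=em["reference_salt_g"],
        hyp_threshold=em["hyp_threshold"],
        tmrel=em["tmrel"],
        rr_unit_mmhg=em["rr_unit_mmhg"],
        rr={c: CIParam(**p) for c, p in em["rr"].items()},
    )
    scalars = {n: _frame_from_csv(d / f"{n}.csv").rename(n) for n in SCALAR_FIELDS}
    frames = {}
    for name in CAUSE_FIELDS:
        cols = {c: _frame_from_csv(d / f"{name}_{c}.csv") for c in CAUSES}
        frames[name] = pd.DataFrame(cols)[list(CAUSES)]
    b = InputBundle(
        **scalars,
        **frames,
        effects=effects,
        seed=meta["seed"],
        sodium_rse=meta["sodium_rse"],
        sbp_mean_se=meta["sbp_mean_se"],
        cost_rse=meta["cost_rse"],
    )
    b.validate()
    return b
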