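"""Age-sex stratification grid shared by every model stage.

The simulation grid is fifteen 5-year age bands (25-29 ... 95-99) crossed
with sex.  Cohorts alive in 2019 are tracked on this grid until they die or
reach age 100.
"""

from __future__ import annotations

import pandas as pd

AGE_LOWER_BOUNDS: tuple[int, ...] = tuple(range(25, 100, 5))
SEXES: tuple[str, str] = ("male", "female")
CAUSES: tuple[str, ...] = ("htn", "dm", "gmn", "other")

CAUSE_LABELS = {
    "htn": "CKD due to hypertension",
    "dm": "CKD due to diabetes mellitus",
    "gmn": "CKD due to glomerulonephritis",
    "other": "CKD due to other and unspecified causes",
}

BASE_YEAR = 2019
MAX_AGE = 100


def age_band_label(lower: int) -> str:
    return f"{lower}-{lower + 4}"


AGE_BAND_LABELS: tuple[str, ...] = tuple(age_band_label(a) for a in AGE_LOWER_BOUNDS)


def stratum_index() -> pd.MultiIndex:
    """MultiIndex of (age, sex) covering the full 15 x 2 grid."""
    return pd.MultiIndex.from_product(
        [list(AGE_LOWER_BOUNDS), list(SEXES)], names=["age", "sex"]
    )


def band_of_age(age: float) -> int:
    """Lower bound of the 5-year band containing ``age`` (clamped to grid)."""
    if age < AGE_LOWER_BOUNDS[0]:
        return AGE_LOWER_BOUNDS[0]
    if age >= AGE_LOWER_BOUNDS[-1]:
        return AGE_LOWER_BOUNDS[-1]
    return int(age) - (int(age) - 25) % 5
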