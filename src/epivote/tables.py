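"""Bundled reference tables: age bands, a synthetic IFR table, and a synthetic
all-cause mortality schedule.

Both tables are *synthetic illustrative values*, not published estimates: they
are shaped like the age/sex gradients reported in the epidemiological
literature (infection fatality ratios rising steeply with age and higher for
men; all-cause mortality following a Gompertz-like curve) but are bundled only
so the package runs self-contained. Analyses of real data should supply their
own IFR table via CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Default 10-year age bands (open-ended final band), 9 bands x 2 sexes = 18 strata.
AGE_BANDS = [
    "0-9",
    "10-19",
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    "80+",
]

SEXES = ["F", "M"]

# Synthetic IFR by age band (probability of death given infection).
_IFR_F = [1e-5, 1e-5, 5e-5, 1.5e-4, 5e-4, 1.6e-3, 6e-3, 2e-2, 6e-2]
_IFR_M = [1e-5, 1.5e-5, 8e-5, 3e-4, 1e-3, 3e-3, 1.2e-2, 4e-2, 1e-1]

# Synthetic annual all-cause death probability by age band (sex-neutral base;
# the male rates are scaled up by _MALE_MORTALITY_FACTOR).
_ANNUAL_MORTALITY = [3e-4, 2e-4, 5e-4, 8e-4, 2e-3, 5e-3, 1.1e-2, 3e-2, 1.1e-1]
_MALE_MORTALITY_FACTOR = 1.25

# Resident age-structure shares used by the simulator (sums to 1).
_AGE_SHARES = [0.11, 0.12, 0.11, 0.12, 0.13, 0.13, 0.11, 0.08, 0.055]


def default_ifr_table(age_bands: list[str] | None = None) -> pd.DataFrame:
    """Return the bundled synthetic IFR table.

    Columns ``age_band``, ``sex``, ``ifr``; one row per stratum; values in
    [0, 1] and non-decreasing in age within each sex.
    """
    bands = age_bands if age_bands is not None else AGE_BANDS
    if len(bands) != len(_IFR_F):
        raise ValueError(
            f"bundled IFR table defines {len(_IFR_F)} age bands, got {len(bands)}"
        )
    rows = []
    for sex, vals in (("F", _IFR_F), ("M", _IFR_M)):
        for band, v in zip(bands, vals):
            rows.append({"age_band": band, "sex": sex, "ifr": v})
    return pd.DataFrame(rows)


def annual_mortality_schedule(age_bands: list[str] | None = None) -> pd.DataFrame:
    """Synthetic annual all-cause death probabilities per stratum.

    Used by the simulator to set baseline hazards; the estimation code never
    sees this table.
    """
    bands = age_bands if age_bands is not None else AGE_BANDS
    if len(bands) != len(_ANNUAL_MORTALITY):
        raise ValueError("mortality schedule and age-band list length mismatch")
    rows = []
    for band, q in zip(bands, _ANNUAL_MORTALITY):
        rows.append({"age_band": band, "sex": "F", "annual_mortality": q})
        rows.append(
            {"age_band": band, "sex": "M", "annual_mortality": q * _MALE_MORTALITY_FACTOR}
        )
    return pd.DataFrame(rows)


def default_age_shares() -> np.ndarray:
    """Population age-structure shares matching :data:`AGE_BANDS` (normalised)."""
    s = np.asarray(_AGE_SHARES, dtype=float)
    return s / s.sum()
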