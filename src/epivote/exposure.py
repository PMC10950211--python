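"""Probability that a voter knows at least one infected person.

Under voter homogeneity, a voter with a social circle of ``k`` acquaintances,
each infected independently with probability ``pi`` (the municipal
prevalence), knows at least one infected person with probability
``1 - (1 - pi)^k`` — the birthday-paradox effect that makes this large even
at low prevalence.  ``k = 15`` is the conservative default (close circle,
discounting asymptomatic cases); ``k = 150`` is the Dunbar-number variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: named network sizes: a conservative inner circle and the Dunbar number
NETWORK_SIZES = {"inner_circle": 15, "dunbar": 150}

DEFAULT_THRESHOLDS = (0.30, 0.50)


def prob_know_infected(pi, k: int = 15, symptomatic_fraction: float = 1.0):
    """``1 - (1 - pi * symptomatic_fraction)^k`` for scalar or array ``pi``.

    ``symptomatic_fraction`` optionally thins prevalence to the share of
    infections a contact would notice; the default folds that into ``k``.
    """
    arr = np.asarray(pi, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ConfigurationError("prevalence values must lie in [0, 1]")
    if k < 1 or int(k) != k:
        raise ConfigurationError("network size k must be a positive integer")
    if not 0.0 < symptomatic_fraction <= 1.0:
        raise ConfigurationError("symptomatic_fraction must lie in (0, 1]")
    p = 1.0 - (1.0 - arr * symptomatic_fraction) ** int(k)
    return float(p) if np.isscalar(pi) else p


def exposure_table(
    estimates: pd.DataFrame,
    k: int = 15,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    symptomatic_fraction: float = 1.0,
) -> pd.DataFrame:
    """Per-municipality knowing-probability with boolean threshold flags."""
    out = estimates[["municipality_id"]].copy()
    out["network_size"] = int(k)
    out["p_know"] = prob_know_infected(
        estimates["pi_hat"].to_numpy(), k, symptomatic_fraction
    )
    for t in thresholds:
        out[f"exceeds_{t:g}"] = out["p_know"] >= t
    return out


def count_exceeding(
    estimates: pd.DataFrame,
    k: int = 15,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    symptomatic_fraction: float = 1.0,
) -> pd.DataFrame:
    """Counts and sample shares of municipalities whose knowing-probability
    meets each threshold."""
    tab = exposure_table(estimates, k, thresholds, symptomatic_fraction)
    n = len(tab)
    rows = []
    for t in thresholds:
        cnt = int(tab[f"exceeds_{t:g}"].sum())
        rows.append(
            {"threshold": t, "count": cnt, "share": cnt / n if n else np.nan}
        )
    return pd.DataFrame(rows)
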