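"""Small shared primitives."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError


def stable_rank_bins(values: pd.Series, n_bins: int) -> pd.Series:
    """1-based rank bins of near-equal size with ties broken by index order.

    Values are sorted stably by value (ties keep the incoming order, i.e.
    municipality-id order when the series is id-sorted); the sorted sequence
    is cut into ``n_bins`` contiguous chunks whose sizes differ by at most
    one.  Raises when there are fewer observations than bins or all values
    are identical (ranks undefined).
    """
    n = len(values)
    if n < n_bins:
        raise ConfigurationError(
            f"need at least {n_bins} observations for {n_bins} bins"
        )
    if values.nunique() == 1:
        raise ConfigurationError("rank bins undefined: all values identical")
    order = values.reset_index(drop=True).sort_values(kind="stable").index.to_numpy()
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bins = np.repeat(np.arange(1, n_bins + 1), sizes)
    out = np.empty(n, dtype=int)
    out[order] = bins
    return pd.Series(out, index=values.index, name=f"bin{n_bins}")
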