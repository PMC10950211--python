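"""Basic plots for predicted margins and group trend means.

Matplotlib is an optional dependency; these helpers import it lazily so the
estimation library stays usable without a plotting stack.
"""

from __future__ import annotations

import pandas as pd


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install epivote[plot])") from exc
    return plt


def plot_margins(predictions: pd.DataFrame, ax=None, **kwargs):
    """Predicted vote share with confidence band across spread levels.

    Expects the frame returned by :func:`epivote.predict_at_levels`.
    """
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(predictions["level"], predictions["predicted"], marker="o", **kwargs)
    ax.fill_between(
        predictions["level"], predictions["ci_low"], predictions["ci_high"], alpha=0.2
    )
    ax.set_xlabel("spread level")
    ax.set_ylabel("predicted incumbent share (pp)")
    return ax


def plot_group_trends(means: pd.DataFrame, ax=None):
    """Mean incumbent share by election year for treated vs control groups.

    Expects the frame returned by :func:`epivote.parallel_trends`.
    """
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    for grp, sub in means.groupby("group"):
        ax.plot(sub["year"], sub["mean_share"], marker="o", label=grp)
    ax.set_xlabel("election year")
    ax.set_ylabel("mean incumbent share (pp)")
    ax.legend()
    return ax
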