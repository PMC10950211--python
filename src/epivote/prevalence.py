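"""Municipality-level prevalence from stratified excess mortality.

The model: within a fixed observation window, deaths in stratum *s* (age band
x sex) of a municipality are Poisson.  In baseline years the rate is
``N_st * h_s`` with a stratum hazard ``h_s`` constant across baseline years;
in the epidemic year it is ``N_s * (h_s + pi * IFR_s)``, so the excess hazard
is prevalence modulated by the stratum's infection fatality ratio.  The
estimator maximises the joint likelihood over ``(h_1..h_S, pi)`` with
``pi`` constrained to [0, 1] and reports a profile-likelihood interval.

For a fixed ``pi`` the partially-maximised hazards have a closed form (the
stationarity condition is a quadratic in ``h_s``), so profiling reduces to a
one-dimensional concave search — no general-purpose optimiser over S+1
parameters is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .exceptions import ConfigurationError, EstimationError

logger = logging.getLogger(__name__)

_STRATUM = ["municipality_id", "age_band", "sex"]


class ExtrapolationResult(NamedTuple):
    panel: pd.DataFrame  # observed + extrapolated rows
    methods: pd.DataFrame  # per-stratum method actually used


def extrapolate_population(
    population: pd.DataFrame,
    method: str = "auto",
    through: int | None = None,
) -> ExtrapolationResult:
    """Extend per-stratum population series beyond the observed years.

    One trend is fitted per municipality x age band x sex on the observed
    years and evaluated at the missing years up to ``through`` (default: three
    years past the last observed year, the census-to-election gap).

    ``linear`` fits counts, ``log_linear`` fits log counts (exact for
    geometric growth), ``auto`` picks log-linear when all observed counts are
    positive and linear otherwise.  Strata with a single observed year carry
    the last value forward (logged as a warning); predictions are floored at
    zero.
    """
    if method not in ("linear", "log_linear", "auto"):
        raise ConfigurationError(f"unknown extrapolation method '{method}'")
    if population.empty:
        return ExtrapolationResult(population.copy(), pd.DataFrame(columns=_STRATUM + ["method"]))
    last = int(population["year"].max())
    through = last + 3 if through is None else int(through)
    new_years = np.arange(last + 1, through + 1)
    if len(new_years) == 0:
        return ExtrapolationResult(population.copy(), pd.DataFrame(columns=_STRATUM + ["method"]))

    wide = (
        population.pivot_table(
            index=_STRATUM, columns="year", values="population", aggfunc="sum"
        )
        .sort_index(axis=1)
    )
    years = wide.columns.to_numpy(dtype=float)
    Y = wide.to_numpy(dtype=float)
    observed = ~np.isnan(Y)
    n_obs = observed.sum(axis=1)

    few = n_obs < 2
    if few.any():
        warnings.warn(
            f"{int(few.sum())} strata have < 2 observed years; carrying last value forward",
            stacklevel=2,
        )

    pos = np.where(observed, Y > 0, True).all(axis=1)
    if method == "linear":
        use_log = np.zeros(len(wide), dtype=bool)
    elif method == "log_linear":
        use_log = pos.copy()
        if (~pos).any():
            warnings.warn(
                f"log-linear undefined for {int((~pos).sum())} strata containing zeros; "
                "fell back to linear for those",
                stacklevel=2,
            )
    else:
        use_log = pos.copy()

    t_mean = np.where(observed, years, 0.0).sum(axis=1) / np.maximum(n_obs, 1)
    preds = np.empty((len(wide), len(new_years)))
    for space, mask in (("lin", ~use_log), ("log", use_log)):
        if not mask.any():
            continue
        Z = Y[mask]
        if space == "log":
            with np.errstate(divide="ignore"):
                Z = np.log(Z)
        obs = observed[mask]
        Zf = np.where(obs, Z, 0.0)
        tm = t_mean[mask][:, None]
        tc = np.where(obs, years[None, :] - tm, 0.0)
        denom = (tc**2).sum(axis=1)
        z_mean = Zf.sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
        slope = np.where(denom > 0, (tc * (Zf - z_mean[:, None] * obs)).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
        pred = z_mean[:, None] + slope[:, None] * (new_years[None, :] - tm)
        if space == "log":
            pred = np.exp(pred)
        preds[mask] = pred
    preds = np.maximum(preds, 0.0)

    idx = wide.index.to_frame(index=False)
    methods = idx.copy()
    methods["method"] = np.where(few, "carry_forward", np.where(use_log, "log_linear", "linear"))

    new_rows = idx.loc[idx.index.repeat(len(new_years))].reset_index(drop=True)
    new_rows["year"] = np.tile(new_years, len(wide))
    new_rows["population"] = preds.reshape(-1)
    out = pd.concat([population, new_rows[population.columns.tolist()]], ignore_index=True)
    return ExtrapolationResult(out, methods)


def fit_baseline_hazard(
    population: pd.DataFrame,
    deaths: pd.DataFrame,
    pooling: str = "none",
    baseline_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-stratum baseline window hazards from the pre-epidemic years.

    With ``pooling='none'`` the estimate is the Poisson MLE
    ``sum_t D_t / sum_t N_t``.  With ``pooling='shrink'`` each municipality's
    stratum hazard is the posterior mean of a Gamma-Poisson empirical-Bayes
    model whose prior is moment-matched to the national spread of stratum
    hazards, pulling small-exposure municipalities toward the national value.

    Strata with zero total exposure are excluded (logged).
    """
    if pooling not in ("none", "shrink"):
        raise ConfigurationError(f"unknown pooling '{pooling}'")
    if baseline_years is None:
        y_max = int(deaths["year"].max())
        baseline_years = (int(deaths["year"].min()), y_max - 1)
    lo, hi = baseline_years
    d = deaths[(deaths["year"] >= lo) & (deaths["year"] <= hi)]
    p = population[(population["year"] >= lo) & (population["year"] <= hi)]
    agg = (
        d.groupby(_STRATUM, observed=True)["deaths"].sum().to_frame("D")
        .join(p.groupby(_STRATUM, observed=True)["population"].sum().to_frame("N"), how="outer")
        .fillna(0.0)
        .reset_index()
    )
    empty = agg["N"] <= 0
    if empty.any():
        logger.warning("excluding %d strata with zero exposure", int(empty.sum()))
        agg = agg[~empty].copy()
    agg["hazard"] = agg["D"] / agg["N"]

    if pooling == "shrink":
        out = []
        for (band, sex), grp in agg.groupby(["age_band", "sex"], observed=True):
            D, N = grp["D"].to_numpy(float), grp["N"].to_numpy(float)
            h0 = D.sum() / N.sum()
            w = N / N.sum()
            # moment-match a Gamma(shape, rate) prior: across-municipality
            # variance of the raw MLEs minus the average sampling variance
            samp_var = (w * (h0 / np.maximum(N, 1.0))).sum()
            total_var = (w * (grp["hazard"].to_numpy() - h0) ** 2).sum()
            prior_var = max(total_var - samp_var, 1e-4 * h0**2 + 1e-300)
            shape = h0**2 / prior_var
            rate = shape / max(h0, 1e-300)
            g = grp.copy()
            g["hazard"] = (shape + D) / (rate + N)
            out.append(g)
        agg = pd.concat(out, ignore_index=True)
    return agg[_STRATUM + ["hazard"]]


# ---------------------------------------------------------------------------
# joint excess-hazard MLE
# ---------------------------------------------------------------------------

def _profile_hazards(pi, A, B, D20, N20, ifr):
    """Closed-form maximisers h_s(pi) of the per-stratum joint likelihood."""
    c = pi * ifr
    a = B + N20
    b = a * c - A - D20
    disc = b * b + 4.0 * a * (A * c)
    h = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
    return np.maximum(h, 0.0)


def _profile_loglik(pi, A, B, D20, N20, ifr):
    h = _profile_hazards(pi, A, B, D20, N20, ifr)
    lam = h + pi * ifr
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(A > 0, A * np.log(h), 0.0)
        t2 = np.where(D20 > 0, D20 * np.log(lam), 0.0)
    # A>0 with h==0 (or D20>0 with lam==0) has likelihood zero
    t1 = np.where((A > 0) & (h <= 0), -np.inf, t1)
    t2 = np.where((D20 > 0) & (lam <= 0), -np.inf, t2)
    return float((t1 - B * h + t2 - N20 * lam).sum())


@dataclass
class PrevalenceFit:
    """Joint-MLE output: per-municipality estimates plus fitted hazards."""

    estimates: pd.DataFrame  # municipality_id, pi_hat, ci_low, ci_high, ...
    hazards: pd.DataFrame  # municipality_id, age_band, sex, hazard (at pi_hat)


def estimate_prevalence(
    population: pd.DataFrame,
    deaths: pd.DataFrame,
    ifr: pd.DataFrame,
    ci_level: float = 0.95,
    xatol: float = 1e-10,
) -> PrevalenceFit:
    """Maximise the joint Poisson excess-hazard likelihood per municipality.

    The final death year is the epidemic year; earlier years are baseline.
    Returns point estimates constrained to [0, 1], profile-likelihood
    intervals at ``ci_level`` (chi-square cutoff with 1 df), the expected
    baseline deaths for the epidemic year, a boundary flag, and the fitted
    stratum hazards.  Municipalities with zero epidemic-year population are
    excluded (logged); strata missing from the IFR table raise.
    """
    y20 = int(deaths["year"].max())
    d20 = deaths[deaths["year"] == y20].set_index(_STRATUM)["deaths"]
    dbase = (
        deaths[deaths["year"] < y20].groupby(_STRATUM, observed=True)["deaths"].sum()
    )
    n20 = population[population["year"] == y20].set_index(_STRATUM)["population"]
    nbase = (
        population[(population["year"] >= int(deaths["year"].min())) & (population["year"] < y20)]
        .groupby(_STRATUM, observed=True)["population"]
        .sum()
    )
    df = pd.concat(
        {"A": dbase, "B": nbase, "D20": d20, "N20": n20}, axis=1
    ).fillna(0.0).reset_index()
    ifr_idx = ifr.set_index(["age_band", "sex"])["ifr"]
    key = pd.MultiIndex.from_frame(df[["age_band", "sex"]])
    if not key.isin(ifr_idx.index).all():
        missing = sorted(set(map(tuple, df.loc[~key.isin(ifr_idx.index), ["age_band", "sex"]].values)))
        raise ConfigurationError(f"IFR table missing strata: {missing}")
    df["ifr"] = ifr_idx.reindex(key).to_numpy()

    cutoff = chi2.ppf(ci_level, df=1) / 2.0
    est_rows, hz_frames = [], []
    for mid, grp in df.groupby("municipality_id", sort=True):
        live = grp["N20"] > 0
        if not live.any():
            logger.warning("municipality %s has zero epidemic-year population; excluded", mid)
            continue
        g = grp[live]
        A = g["A"].to_numpy(float)
        B = g["B"].to_numpy(float)
        D20 = g["D20"].to_numpy(float)
        N20 = g["N20"].to_numpy(float)
        fr = g["ifr"].to_numpy(float)

        ll = lambda p: _profile_loglik(p, A, B, D20, N20, fr)
        res = minimize_scalar(
            lambda p: -ll(p), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": xatol},
        )
        pi_hat = float(res.x)
        ll_max = -float(res.fun)
        # the bounded search never evaluates the exact boundary; snap to it
        for bound in (0.0, 1.0):
            if ll(bound) >= ll_max:
                pi_hat, ll_max = bound, ll(bound)
        converged = bool(res.success) and np.isfinite(ll_max)

        f = lambda p: ll(p) - (ll_max - cutoff)
        try:
            lo = 0.0 if f(0.0) >= 0 else brentq(f, 0.0, max(pi_hat, 1e-12))
            hi = 1.0 if f(1.0) >= 0 else brentq(f, min(pi_hat, 1.0 - 1e-12), 1.0)
        except ValueError:
            lo, hi, converged = 0.0, 1.0, False

        h_hat = _profile_hazards(pi_hat, A, B, D20, N20, fr)
        hz = g[["municipality_id", "age_band", "sex"]].copy()
        hz["hazard"] = h_hat
        hz_frames.append(hz)
        est_rows.append(
            {
                "municipality_id": mid,
                "pi_hat": pi_hat,
                "ci_low": min(lo, pi_hat),
                "ci_high": max(hi, pi_hat),
                "expected_baseline_deaths_2020": float((N20 * h_hat).sum()),
                "boundary": pi_hat in (0.0, 1.0),
                "converged": converged,
            }
        )
    estimates = pd.DataFrame(
        est_rows,
        columns=[
            "municipality_id", "pi_hat", "ci_low", "ci_high",
            "expected_baseline_deaths_2020", "boundary", "converged",
        ],
    )
    hazards = (
        pd.concat(hz_frames, ignore_index=True)
        if hz_frames
        else pd.DataFrame(columns=_STRATUM + ["hazard"])
    )
    return PrevalenceFit(estimates=estimates, hazards=hazards)


def compute_baseline_mortality(
    hazards: pd.DataFrame, population: pd.DataFrame, year: int | None = None
) -> pd.Series:
    """Population-weighted mean stratum hazard per municipality.

    Equals expected window deaths divided by total population in ``year``
    (default: the last population year) — the pre-epidemic probability of
    dying within the observation window.
    """
    if year is None:
        year = int(population["year"].max())
    p = population[population["year"] == year]
    m = p.merge(hazards, on=_STRATUM, how="inner")
    g = m.groupby("municipality_id")
    out = g.apply(
        lambda x: (x["population"] * x["hazard"]).sum() / x["population"].sum(),
        include_groups=False,
    )
    return out.rename("baseline_mortality")


@dataclass
class PrevalenceTransform:
    """Outlier-robust recoding of the prevalence measure for regression use."""

    scheme: str  # decile | quintile | quartile | log
    values: pd.Series  # indexed by municipality_id
    log_offset: float | None = None


def transform_prevalence(estimates: pd.DataFrame, scheme: str) -> PrevalenceTransform:
    """Rank bins (decile/quintile continuous, quartile categorical) or a
    logged version of the prevalence point estimates.

    Bins are computed on the estimation sample with ties broken by stable
    municipality-id order; the log offset is half the smallest positive
    estimate.
    """
    from .utils import stable_rank_bins

    vals = (
        estimates.set_index("municipality_id")["pi_hat"].sort_index()
        if "pi_hat" in estimates
        else estimates.set_index("municipality_id").iloc[:, 0].sort_index()
    )
    if scheme in ("decile", "quintile", "quartile"):
        n_bins = {"decile": 10, "quintile": 5, "quartile": 4}[scheme]
        if len(vals) < n_bins:
            raise ConfigurationError(
                f"{scheme} transform needs >= {n_bins} municipalities, got {len(vals)}"
            )
        if vals.nunique() == 1:
            raise ConfigurationError(f"{scheme} transform undefined: all values identical")
        bins = stable_rank_bins(vals, n_bins)
        if scheme == "quartile":
            cat = pd.Categorical(bins, categories=[1, 2, 3, 4], ordered=True)
            return PrevalenceTransform(scheme, pd.Series(cat, index=vals.index, name="quartile"))
        return PrevalenceTransform(scheme, bins.astype(float).rename(scheme))
    if scheme == "log":
        pos = vals[vals > 0]
        if pos.empty:
            raise ConfigurationError("log transform undefined: no positive estimates")
        delta = float(pos.min()) / 2.0
        return PrevalenceTransform(
            "log", np.log(vals + delta).rename("log_prevalence"), log_offset=delta
        )
    raise ConfigurationError(f"unknown transform scheme '{scheme}'")
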