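"""Effect of epidemic spread on incumbent vote shares: the design suite.

The workhorse specification is a lagged-dependent-variable OLS with county
fixed effects,

    share_2020 = a + b * spread + g'X + e * share_2014 + county + error,

where ``spread`` is an outlier-robust transform of estimated prevalence
(decile/quintile rank treated as continuous, or quartile categories) and X
holds logged census covariates, 2014 turnout, the number of candidates, and
baseline mortality.  Around it sit the robustness designs: first differences,
difference-in-differences (naive four-cell and two-way fixed effects),
1:1 caliper propensity-score matching, a placebo on the previous election,
a parallel-trends contrast, and moderator interactions with cluster-robust
standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigurationError, EstimationError, MatchingError
from .utils import stable_rank_bins

logger = logging.getLogger(__name__)

#: census covariates entering every design; all but median income are logged
LOGGED_COVARIATES = [
    "pop_density",
    "male_female_ratio",
    "share_65plus",
    "share_immigrants",
    "share_blue_collar",
    "share_unemployed",
    "share_junior_hs",
    "share_bachelor",
]
RAW_COVARIATES = ["median_income"]

CONTROL_COLUMNS = [f"log_{c}" for c in LOGGED_COVARIATES] + RAW_COVARIATES + [
    "turnout_2014",
    "n_candidates_2020",
    "baseline_mortality",
]


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Model-form census covariates: logs everywhere except median income.

    Non-positive values entering a log are lifted by half the smallest
    positive value in their column (with a warning) so the row survives.
    """
    df = covariates.set_index("municipality_id")
    out = pd.DataFrame(index=df.index)
    for col in LOGGED_COVARIATES:
        x = df[col].to_numpy(dtype=float)
        bad = x <= 0
        if bad.any():
            pos = x[x > 0]
            if pos.size == 0:
                raise ConfigurationError(f"covariate '{col}' has no positive values")
            offset = pos.min() / 2.0
            warnings.warn(
                f"{int(bad.sum())} non-positive values in '{col}'; "
                f"log computed with offset {offset:g}",
                stacklevel=2,
            )
            x = x + offset
        out[f"log_{col}"] = np.log(x)
    for col in RAW_COVARIATES:
        out[col] = df[col].to_numpy(dtype=float)
    return out


@dataclass
class EffectEstimate:
    """A coefficient with inference metadata from one design."""

    design: str
    transform: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    r_squared: float | None = None
    notes: str = ""
    table: pd.DataFrame | None = None  # all reported terms
    model: object = field(default=None, repr=False)  # statsmodels results
    cov_cols: list[str] = field(default_factory=list, repr=False)
    design_means: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self):
        if np.isfinite(self.se) and self.se >= 0 and not (
            self.ci_low <= self.coefficient <= self.ci_high
        ):
            raise EstimationError("confidence interval does not bracket the estimate")


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    transform,
    baseline_mortality: pd.Series | None = None,
    outcome: str = "share_2020",
    lag: str | None = "share_2014",
    restrict_incumbents: bool = True,
) -> pd.DataFrame:
    """Assemble the model-ready table for the vote-share regressions.

    Returns a municipality-indexed frame with ``y``, the spread regressor
    (``cov`` for continuous transforms; ``cov_2..cov_4`` dummies for the
    quartile transform), the lagged share, all control columns, and
    ``county_id``.  Incomplete rows are dropped with a logged count; the
    spread columns used are recorded in ``df.attrs``.
    """
    p = panel.set_index("municipality_id")
    if restrict_incumbents and "incumbent_running" in p:
        p = p[p["incumbent_running"].astype(bool)]
    X = encode_covariates(covariates)

    values = transform.values if hasattr(transform, "values") else pd.Series(transform)
    scheme = getattr(transform, "scheme", "custom")

    df = pd.DataFrame(index=p.index)
    df["y"] = p[outcome]
    if isinstance(values.dtype, pd.CategoricalDtype):
        codes = values.reindex(df.index)
        levels = list(values.cat.categories)
        cov_cols = []
        for lvl in levels[1:]:
            col = f"cov_{lvl}"
            df[col] = (codes == lvl).astype(float)
            cov_cols.append(col)
        df.loc[codes.isna(), cov_cols] = np.nan
    else:
        df["cov"] = pd.to_numeric(values, errors="coerce").reindex(df.index)
        cov_cols = ["cov"]
    if lag is not None:
        df["lag"] = p[lag]
    for col in X.columns:
        df[col] = X[col].reindex(df.index)
    df["turnout_2014"] = p["turnout_2014"]
    df["n_candidates_2020"] = p["n_candidates_2020"].astype(float)
    if baseline_mortality is not None:
        df["baseline_mortality"] = baseline_mortality.reindex(df.index)
    df["county_id"] = p["county_id"]

    before = len(df)
    df = df.dropna()
    dropped = before - len(df)
    if dropped:
        logger.info("design matrix: dropped %d incomplete rows of %d", dropped, before)
    df.attrs["cov_cols"] = cov_cols
    df.attrs["transform"] = scheme
    return df


def _regressor_columns(dm: pd.DataFrame) -> list[str]:
    return [c for c in dm.columns if c not in ("y", "county_id")]


def _fit_fe_ols(
    dm: pd.DataFrame,
    fe: str = "dummies",
    cov_type: str = "HC1",
    cluster: pd.Series | None = None,
):
    """OLS of ``y`` on everything else with county fixed effects.

    ``fe='dummies'`` appends explicit county indicators; ``fe='demean'``
    absorbs them by within-county centring (coefficients identical by
    Frisch-Waugh; use the dummy path for inference).
    """
    cols = _regressor_columns(dm)
    y = dm["y"].to_numpy(dtype=float)
    if fe == "dummies":
        X = dm[cols].astype(float)
        dums = pd.get_dummies(dm["county_id"], prefix="county", drop_first=True)
        X = pd.concat([X, dums.astype(float)], axis=1)
        X = sm.add_constant(X, has_constant="add")
    elif fe == "demean":
        X = dm[cols].astype(float)
        g = dm.groupby("county_id")
        X = X - g[cols].transform("mean")
        y = y - g["y"].transform("mean").to_numpy()
    else:
        raise ConfigurationError(f"unknown fe scheme '{fe}'")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        keep, bad = [], []
        basis = np.empty((X.shape[0], 0))
        for c in X.columns:
            cand = np.column_stack([basis, X[c].to_numpy()])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                basis = cand
                keep.append(c)
            else:
                bad.append(c)
        raise EstimationError(f"singular design matrix; collinear columns: {bad}")

    kwargs = {}
    if cov_type == "cluster":
        if cluster is None:
            raise ConfigurationError("cluster covariance requested without groups")
        kwargs = {"cov_type": "cluster", "cov_kwds": {"groups": cluster.loc[dm.index]}}
    else:
        kwargs = {"cov_type": cov_type}
    res = sm.OLS(y, X).fit(**kwargs)
    return res, X


def _estimate_from(res, X, dm, design, notes=""):
    cov_cols = dm.attrs.get("cov_cols", ["cov"])
    params = pd.Series(np.asarray(res.params), index=X.columns)
    bse = pd.Series(np.asarray(res.bse), index=X.columns)
    pvals = pd.Series(np.asarray(res.pvalues), index=X.columns)
    ci = pd.DataFrame(np.asarray(res.conf_int()), index=X.columns, columns=["lo", "hi"])
    main = cov_cols[0]
    table = pd.DataFrame(
        {
            "term": cov_cols,
            "coefficient": params[cov_cols].to_numpy(),
            "se": bse[cov_cols].to_numpy(),
            "ci_low": ci.loc[cov_cols, "lo"].to_numpy(),
            "ci_high": ci.loc[cov_cols, "hi"].to_numpy(),
            "p_value": pvals[cov_cols].to_numpy(),
        }
    )
    return EffectEstimate(
        design=design,
        transform=dm.attrs.get("transform", "custom"),
        coefficient=float(params[main]),
        se=float(bse[main]),
        ci_low=float(ci.loc[main, "lo"]),
        ci_high=float(ci.loc[main, "hi"]),
        p_value=float(pvals[main]),
        n_obs=int(res.nobs),
        r_squared=float(res.rsquared),
        notes=notes,
        table=table,
        model=res,
        cov_cols=cov_cols,
        design_means=X.mean(axis=0),
    )


def fit_lagged_dv(
    dm: pd.DataFrame, fe: str = "dummies", cov_type: str = "HC1"
) -> EffectEstimate:
    """The workhorse lagged-dependent-variable OLS with county fixed effects.

    The spread coefficient is per transform unit (per decile step for the
    continuous decile transform; per category versus the bottom quartile for
    the categorical one).  Heteroskedasticity-robust (HC1) errors by default.
    """
    res, X = _fit_fe_ols(dm, fe=fe, cov_type=cov_type)
    return _estimate_from(res, X, dm, design="lagged_dv")


def predict_at_levels(estimate: EffectEstimate, levels) -> pd.DataFrame:
    """Predicted outcome at given spread levels, other regressors at means.

    Adds a final row contrasting the top and bottom requested level.  Levels
    outside the observed support trigger a warning.
    """
    if estimate.model is None or estimate.design_means is None:
        raise EstimationError("estimate carries no fitted model")
    means = estimate.design_means
    cov_cols = estimate.cov_cols
    rows = []
    for lvl in levels:
        x = means.copy()
        if len(cov_cols) == 1 and cov_cols[0] == "cov":
            x["cov"] = float(lvl)
        else:
            for c in cov_cols:
                x[c] = 0.0
            col = f"cov_{lvl}"
            if col in cov_cols:
                x[col] = 1.0
            elif lvl not in (1, "1"):
                warnings.warn(f"level {lvl!r} not among fitted categories", stacklevel=2)
        rows.append(x)
    Xp = pd.DataFrame(rows)
    pred = estimate.model.get_prediction(Xp).summary_frame(alpha=0.05)
    out = pd.DataFrame(
        {
            "level": list(levels),
            "predicted": pred["mean"].to_numpy(),
            "ci_low": pred["mean_ci_lower"].to_numpy(),
            "ci_high": pred["mean_ci_upper"].to_numpy(),
        }
    )
    contrast = Xp.iloc[-1] - Xp.iloc[0]
    diff = float(contrast @ estimate.model.params)
    var = float(contrast @ estimate.model.cov_params() @ contrast)
    out.attrs["top_bottom_difference"] = diff
    out.attrs["top_bottom_se"] = np.sqrt(max(var, 0.0))
    return out


def fit_first_difference(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    transform,
    baseline_mortality: pd.Series | None = None,
    fe: str = "dummies",
    cov_type: str = "HC1",
) -> EffectEstimate:
    """OLS of the 2020-2014 change in incumbent share on spread + controls."""
    dm = build_design_matrix(panel, covariates, transform, baseline_mortality)
    dm = dm.copy()
    dm["y"] = dm["y"] - dm["lag"]
    dm = dm.drop(columns="lag")
    res, X = _fit_fe_ols(dm, fe=fe, cov_type=cov_type)
    est = _estimate_from(res, X, dm, design="first_diff")
    est.design = "first_diff"
    return est


# ---------------------------------------------------------------------------
# difference-in-differences
# ---------------------------------------------------------------------------

def define_treatment(transform_or_values) -> pd.Series:
    """Treated = top two quartiles of the spread measure.

    Accepts a quartile :class:`~epivote.prevalence.PrevalenceTransform` or a
    raw value series (quartiles are then computed here, ties broken by
    municipality-id order).  Degenerate all-equal inputs raise.
    """
    values = (
        transform_or_values.values
        if hasattr(transform_or_values, "values") and hasattr(transform_or_values, "scheme")
        else pd.Series(transform_or_values)
    )
    if isinstance(values.dtype, pd.CategoricalDtype):
        q = values.astype(int)
    else:
        q = stable_rank_bins(values.sort_index(), 4)
    return (q >= 3).rename("treated")


def did_naive(panel: pd.DataFrame, treated: pd.Series) -> float:
    """Four-cell difference-in-differences on incumbent shares."""
    p = panel.set_index("municipality_id")
    t = treated.reindex(p.index).astype(bool)
    d20, d14 = p["share_2020"], p["share_2014"]
    return float(
        (d20[t].mean() - d14[t].mean()) - (d20[~t].mean() - d14[~t].mean())
    )


def fit_did(
    panel: pd.DataFrame,
    treated: pd.Series,
    with_fe: bool = True,
    covariate_changes: pd.DataFrame | None = None,
    restrict_incumbents: bool = True,
) -> EffectEstimate:
    """Difference-in-differences across the 2014 and 2020 elections.

    ``with_fe`` runs the two-way (municipality + period) fixed-effects
    regression on the long panel; without covariates it coincides exactly
    with the naive four-cell contrast.  ``covariate_changes`` (a
    municipality-indexed frame of 2014->2017 control changes) enters
    interacted with the post period.  Municipalities missing a period are
    dropped (logged).
    """
    p = panel.set_index("municipality_id")
    if restrict_incumbents and "incumbent_running" in p:
        p = p[p["incumbent_running"].astype(bool)]
    t = treated.reindex(p.index)
    keep = p[["share_2014", "share_2020"]].notna().all(axis=1) & t.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("DiD: dropped %d municipalities lacking a period or flag", dropped)
    p, t = p[keep], t[keep].astype(bool)
    if p.empty or t.nunique() < 2:
        raise EstimationError("DiD needs both treated and control municipalities")

    sub = p.reset_index()[["municipality_id", "share_2014", "share_2020"]]
    naive = did_naive(sub, t)

    if not with_fe and covariate_changes is None:
        # inference from the equivalent change regression
        dy = (p["share_2020"] - p["share_2014"]).to_numpy()
        X = sm.add_constant(t.astype(float).to_numpy())
        res = sm.OLS(dy, X).fit(cov_type="HC1")
        ci = res.conf_int()[1]
        return EffectEstimate(
            design="did_naive",
            transform="quartile_top2",
            coefficient=naive,
            se=float(res.bse[1]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            p_value=float(res.pvalues[1]),
            n_obs=int(len(p)) * 2,
            notes="four-cell contrast; SE from the change regression",
            model=res,
        )

    # long two-way FE regression, municipality effects absorbed by centring
    long = pd.DataFrame(
        {
            "municipality_id": np.repeat(p.index.to_numpy(), 2),
            "post": np.tile([0.0, 1.0], len(p)),
            "y": np.column_stack([p["share_2014"], p["share_2020"]]).reshape(-1),
            "treated_post": np.column_stack(
                [np.zeros(len(p)), t.astype(float)]
            ).reshape(-1),
        }
    )
    cols = ["post", "treated_post"]
    if covariate_changes is not None:
        cc = covariate_changes.reindex(p.index)
        for c in cc.columns:
            long[f"d_{c}_post"] = np.column_stack(
                [np.zeros(len(p)), cc[c].to_numpy(dtype=float)]
            ).reshape(-1)
            cols.append(f"d_{c}_post")
        long = long.dropna()
    g = long.groupby("municipality_id")
    Xw = long[cols] - g[cols].transform("mean")
    yw = long["y"] - g["y"].transform("mean")
    res = sm.OLS(yw.to_numpy(), Xw.to_numpy()).fit(
        cov_type="cluster", cov_kwds={"groups": long["municipality_id"]}
    )
    i = cols.index("treated_post")
    ci = res.conf_int()[i]
    return EffectEstimate(
        design="did_fe",
        transform="quartile_top2",
        coefficient=float(res.params[i]),
        se=float(res.bse[i]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues[i]),
        n_obs=int(len(long)),
        notes=f"naive four-cell contrast = {naive:.10g}",
        model=res,
    )


# ---------------------------------------------------------------------------
# propensity-score matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedSample:
    """1:1 caliper-matched municipalities with their propensity scores."""

    pairs: pd.DataFrame  # treated_id, control_id, ps_treated, ps_control
    caliper: float
    propensity: pd.Series  # full-sample scores
    n_discarded: int

    @property
    def matched_ids(self) -> pd.Index:
        return pd.Index(
            np.concatenate([self.pairs["treated_id"], self.pairs["control_id"]])
        )


def propensity_match(
    dm: pd.DataFrame,
    treated: pd.Series,
    caliper: float = 0.025,
    seed: int = 0,
) -> MatchedSample:
    """Greedy 1:1 nearest-neighbour matching on the propensity score.

    The score is a logistic regression of treatment on the full control set
    (covariates, turnout, candidates, baseline mortality, lagged share).
    Treated units are processed in descending score order; each takes the
    nearest unused control, pairs beyond the caliper are discarded, and exact
    ties are broken by a seeded draw.  Raises when no admissible pair exists.
    """
    t = treated.reindex(dm.index).astype(bool)
    if t.sum() == 0 or (~t).sum() == 0:
        raise MatchingError("both treated and control units are required")
    controls = [c for c in _regressor_columns(dm) if c not in dm.attrs.get("cov_cols", ["cov"])]
    controls = [c for c in controls if dm[c].nunique() > 1]  # constants carry no signal
    if controls:
        X = sm.add_constant(dm[controls].astype(float), has_constant="add")
        try:
            logit = sm.Logit(t.astype(float), X).fit(disp=0, maxiter=200)
            ps = pd.Series(np.asarray(logit.predict(X)), index=dm.index, name="propensity")
        except Exception as exc:  # perfect separation, singular design
            raise MatchingError(f"propensity model failed: {exc}") from exc
    else:
        # covariates identical across units: everyone shares the base rate
        ps = pd.Series(float(t.mean()), index=dm.index, name="propensity")

    pairs_df, discarded = _greedy_caliper_match(
        ps, t, caliper, np.random.default_rng(seed)
    )
    if pairs_df.empty:
        raise MatchingError(f"no matches within caliper {caliper}")
    return MatchedSample(
        pairs=pairs_df, caliper=caliper, propensity=ps, n_discarded=discarded
    )


def _greedy_caliper_match(
    ps: pd.Series, treated: pd.Series, caliper: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, int]:
    """Greedy 1:1 nearest-neighbour matching on given scores, without
    replacement, treated processed in descending score order, seeded
    tie-breaks; pairs beyond the caliper are discarded."""
    t = treated.reindex(ps.index).astype(bool)
    t_ids = ps.index[t].to_numpy()
    c_ids = ps.index[~t].to_numpy()
    ps_t = ps.loc[t_ids].to_numpy()
    ps_c = ps.loc[c_ids].to_numpy()
    order = np.lexsort((rng.random(len(t_ids)), -ps_t))

    available = np.ones(len(c_ids), dtype=bool)
    pairs, discarded = [], 0
    for i in order:
        if not available.any():
            discarded += 1
            continue
        gaps = np.abs(ps_c - ps_t[i])
        gaps[~available] = np.inf
        best = np.min(gaps)
        if best > caliper:
            discarded += 1
            continue
        cand = np.flatnonzero(gaps == best)
        j = cand[0] if len(cand) == 1 else rng.choice(cand)
        available[j] = False
        pairs.append((t_ids[i], c_ids[j], ps_t[i], ps_c[j]))
    pairs_df = pd.DataFrame(
        pairs, columns=["treated_id", "control_id", "ps_treated", "ps_control"]
    )
    return pairs_df, discarded


def matched_estimate(dm: pd.DataFrame, matched: MatchedSample) -> EffectEstimate:
    """Refit the workhorse specification on the matched municipalities."""
    sub = dm.loc[dm.index.intersection(matched.matched_ids)]
    sub.attrs.update(dm.attrs)
    est = fit_lagged_dv(sub)
    est.design = "psm"
    est.notes = (
        f"{len(matched.pairs)} pairs, caliper {matched.caliper}, "
        f"{matched.n_discarded} treated discarded"
    )
    return est


def standardized_mean_differences(
    dm: pd.DataFrame, treated: pd.Series, columns: list[str] | None = None
) -> pd.Series:
    """|mean_T - mean_C| / pooled SD per covariate (balance diagnostic)."""
    t = treated.reindex(dm.index).astype(bool)
    cols = columns or [
        c for c in _regressor_columns(dm) if c not in dm.attrs.get("cov_cols", ["cov"])
    ]
    out = {}
    for c in cols:
        a, b = dm.loc[t, c].astype(float), dm.loc[~t, c].astype(float)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        out[c] = np.abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return pd.Series(out, name="smd")


# ---------------------------------------------------------------------------
# placebo and pre-trends
# ---------------------------------------------------------------------------

def placebo_test(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    transform,
    baseline_mortality: pd.Series | None = None,
    min_n: int = 100,
) -> EffectEstimate:
    """Refit the workhorse design on the pre-epidemic election.

    Outcome is the 2014 share, the lag is the 2008 share, and the spread
    measure stays the 2020-based one; under a well-specified design the
    coefficient is null.  Runs on the subsample carrying a 2008 share
    (a warning flags subsamples below ``min_n``).
    """
    if "share_2008" not in panel or panel["share_2008"].notna().sum() == 0:
        raise EstimationError("placebo test requires 2008 vote shares")
    dm = build_design_matrix(
        panel, covariates, transform, baseline_mortality,
        outcome="share_2014", lag="share_2008",
    )
    if len(dm) < min_n:
        warnings.warn(
            f"placebo subsample has only {len(dm)} municipalities", stacklevel=2
        )
    res, X = _fit_fe_ols(dm)
    est = _estimate_from(res, X, dm, design="placebo")
    return est


def parallel_trends(
    panel: pd.DataFrame, treated: pd.Series, restrict_incumbents: bool = True
) -> tuple[EffectEstimate, pd.DataFrame]:
    """Contrast of pre-epidemic share changes (2008->2014) by treatment group.

    Returns the difference-in-trends estimate (HC1) and the group-by-year
    mean shares for plotting.
    """
    p = panel.set_index("municipality_id")
    if restrict_incumbents and "incumbent_running" in p:
        p = p[p["incumbent_running"].astype(bool)]
    t = treated.reindex(p.index)
    keep = p[["share_2008", "share_2014"]].notna().all(axis=1) & t.notna()
    p, t = p[keep], t[keep].astype(bool)
    if p.empty or t.nunique() < 2:
        raise EstimationError("parallel-trends check needs both groups with 2008 shares")
    dpre = (p["share_2014"] - p["share_2008"]).to_numpy()
    X = sm.add_constant(t.astype(float).to_numpy())
    res = sm.OLS(dpre, X).fit(cov_type="HC1")
    ci = res.conf_int()[1]
    est = EffectEstimate(
        design="parallel_trends",
        transform="quartile_top2",
        coefficient=float(res.params[1]),
        se=float(res.bse[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues[1]),
        n_obs=int(len(p)),
        notes="difference in 2008->2014 share changes, treated minus control",
        model=res,
    )
    rows = []
    for grp, mask in (("treated", t), ("control", ~t)):
        for year, col in ((2008, "share_2008"), (2014, "share_2014"), (2020, "share_2020")):
            if col in p:
                rows.append({"group": grp, "year": year, "mean_share": p.loc[mask, col].mean()})
    return est, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# anxiety index and interactions
# ---------------------------------------------------------------------------

#: mapping of the two survey items' response categories to scores
ANXIETY_SCALE = {
    "never": 0.0,
    "several days": 1.0 / 3.0,
    "more than half of the time": 2.0 / 3.0,
    "almost every day": 1.0,
}


def aggregate_anxiety(responses: pd.DataFrame) -> pd.DataFrame:
    """Additive two-item anxiety index averaged into county x size cells.

    Each respondent's index is the mean of the two items mapped onto
    {0, 1/3, 2/3, 1}; cells report the respondent mean and count.  Unknown
    response labels raise a schema error.
    """
    from .exceptions import SchemaError

    items = ["item_nervous", "item_worry"]
    for col in items:
        bad = ~responses[col].isin(ANXIETY_SCALE)
        if bad.any():
            raise SchemaError(
                f"unknown response label(s) in '{col}': "
                f"{sorted(responses.loc[bad, col].unique())}"
            )
    idx = responses[items].apply(lambda s: s.map(ANXIETY_SCALE)).mean(axis=1)
    df = responses[["county_id", "size_category"]].copy()
    df["anxiety"] = idx
    cells = (
        df.groupby(["county_id", "size_category"], observed=True)["anxiety"]
        .agg(anxiety_mean="mean", n_respondents="size")
        .reset_index()
    )
    return cells


@dataclass
class InteractionResult:
    estimate: EffectEstimate  # interaction term (continuous) or joint summary
    marginal_effects: pd.DataFrame  # spread effect across moderator values


def fit_interaction(
    dm: pd.DataFrame,
    moderator: pd.Series,
    moderator_name: str = "moderator",
    cluster: pd.Series | None = None,
    n_points: int = 20,
) -> InteractionResult:
    """Workhorse design plus spread x moderator terms.

    Continuous moderators yield the interaction coefficient and the marginal
    effect of one spread unit over ``n_points`` evenly spaced moderator
    values; categorical moderators yield group-specific spread slopes.
    Cluster-robust errors when ``cluster`` is given (the anxiety design),
    HC1 otherwise.  A constant moderator is unidentified and raises.
    """
    cov_cols = dm.attrs.get("cov_cols", ["cov"])
    if len(cov_cols) != 1:
        raise ConfigurationError("interactions require a continuous spread transform")
    cov = cov_cols[0]
    m = moderator.reindex(dm.index)
    dmx = dm.loc[m.notna()].copy()
    m = m[m.notna()]
    cov_type = "cluster" if cluster is not None else "HC1"

    if isinstance(m.dtype, pd.CategoricalDtype) or m.dtype == object:
        m = m.astype("category")
        if len(m.cat.categories) < 2 or m.nunique() < 2:
            raise EstimationError("moderator is constant; interaction unidentified")
        base = m.cat.categories[0]
        inter_cols = []
        for lvl in m.cat.categories[1:]:
            dmx[f"mod_{lvl}"] = (m == lvl).astype(float)
            dmx[f"{cov}_x_{lvl}"] = dmx[cov] * (m == lvl).astype(float)
            inter_cols.append(f"{cov}_x_{lvl}")
        dmx.attrs.update(dm.attrs)
        res, X = _fit_fe_ols(dmx, cov_type=cov_type, cluster=cluster)
        params = pd.Series(np.asarray(res.params), index=X.columns)
        V = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        rows = []
        for lvl in m.cat.categories:
            vec = pd.Series(0.0, index=X.columns)
            vec[cov] = 1.0
            if lvl != base:
                vec[f"{cov}_x_{lvl}"] = 1.0
            eff = float(vec @ params)
            se = float(np.sqrt(max(vec @ V @ vec, 0.0)))
            rows.append(
                {
                    "moderator_value": lvl,
                    "effect": eff,
                    "se": se,
                    "ci_low": eff - 1.96 * se,
                    "ci_high": eff + 1.96 * se,
                }
            )
        me = pd.DataFrame(rows)
        first = inter_cols[0]
        ci = pd.DataFrame(np.asarray(res.conf_int()), index=X.columns, columns=["lo", "hi"])
        est = EffectEstimate(
            design="interaction",
            transform=dm.attrs.get("transform", "custom"),
            coefficient=float(params[first]),
            se=float(pd.Series(np.asarray(res.bse), index=X.columns)[first]),
            ci_low=float(ci.loc[first, "lo"]),
            ci_high=float(ci.loc[first, "hi"]),
            p_value=float(pd.Series(np.asarray(res.pvalues), index=X.columns)[first]),
            n_obs=int(res.nobs),
            r_squared=float(res.rsquared),
            notes=f"categorical moderator '{moderator_name}', base level {base!r}",
            model=res,
            cov_cols=[cov] + inter_cols,
        )
        return InteractionResult(est, me)

    m = m.astype(float)
    if np.isclose(m.std(ddof=0), 0.0):
        raise EstimationError("moderator is constant; interaction unidentified")
    dmx["mod"] = m
    dmx[f"{cov}_x_mod"] = dmx[cov] * m
    dmx.attrs.update(dm.attrs)
    res, X = _fit_fe_ols(dmx, cov_type=cov_type, cluster=cluster)
    params = pd.Series(np.asarray(res.params), index=X.columns)
    V = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    grid = np.linspace(m.min(), m.max(), n_points)
    rows = []
    for val in grid:
        vec = pd.Series(0.0, index=X.columns)
        vec[cov] = 1.0
        vec[f"{cov}_x_mod"] = val
        eff = float(vec @ params)
        se = float(np.sqrt(max(vec @ V @ vec, 0.0)))
        rows.append(
            {
                "moderator_value": val,
                "effect": eff,
                "se": se,
                "ci_low": eff - 1.96 * se,
                "ci_high": eff + 1.96 * se,
            }
        )
    inter = f"{cov}_x_mod"
    ci = pd.DataFrame(np.asarray(res.conf_int()), index=X.columns, columns=["lo", "hi"])
    est = EffectEstimate(
        design="interaction",
        transform=dm.attrs.get("transform", "custom"),
        coefficient=float(params[inter]),
        se=float(pd.Series(np.asarray(res.bse), index=X.columns)[inter]),
        ci_low=float(ci.loc[inter, "lo"]),
        ci_high=float(ci.loc[inter, "hi"]),
        p_value=float(pd.Series(np.asarray(res.pvalues), index=X.columns)[inter]),
        n_obs=int(res.nobs),
        r_squared=float(res.rsquared),
        notes=f"continuous moderator '{moderator_name}'",
        model=res,
        cov_cols=[cov, inter],
    )
    return InteractionResult(est, pd.DataFrame(rows))
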