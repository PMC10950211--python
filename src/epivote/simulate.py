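"""Synthetic municipality panels with known ground truth.

The generator emulates the data environment of an early-epidemic municipal
election: stratified population counts, Poisson death counts whose 2020 rate
carries an excess hazard equal to prevalence x IFR, a right-skewed prevalence
field with many untouched municipalities, census covariates driven by a latent
urbanicity factor, an election panel with a planted per-decile incumbency
effect, and survey cells for an anxiety index.  Everything is reproducible
byte-for-byte from ``(config, seed)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError
from .utils import stable_rank_bins
from .tables import (
    AGE_BANDS,
    annual_mortality_schedule,
    default_age_shares,
    default_ifr_table,
)

# Fixed per-stage stream indices so each generator draws from an independent,
# reproducible stream derived from the one root seed.
_STAGE = {
    "municipalities": 1,
    "prevalence": 2,
    "deaths": 3,
    "elections": 4,
    "survey": 5,
}

WINDOW_WEEKS = {"six_week": 6, "four_week": 4}
# Fraction of COVID deaths among those infected at the election that fall
# inside the observation window (shorter window catches fewer, delayed deaths).
WINDOW_EXCESS_FRACTION = {"six_week": 1.0, "four_week": 0.75}

SIZE_CATEGORIES = ["S1", "S2", "S3", "S4", "S5"]

AFFILIATIONS = ["left", "right", "other"]


@dataclass(frozen=True)
class PrevalenceSpec:
    """Zero-inflated Beta specification for the municipal prevalence field.

    ``zero_mass`` is the expected share of municipalities with exactly zero
    prevalence; the non-zero part is ``max_prevalence * Beta(shape_a, shape_b)``.
    """

    zero_mass: float = 0.40
    shape_a: float = 1.2
    shape_b: float = 30.0
    max_prevalence: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.zero_mass <= 1.0:
            raise ConfigurationError("zero_mass must lie in [0, 1]")
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ConfigurationError("Beta shape parameters must be positive")
        if not 0.0 < self.max_prevalence <= 1.0:
            raise ConfigurationError("max_prevalence must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world; defaults are the reference conditions."""

    n_municipalities: int = 2000
    n_counties: int = 40
    age_bands: tuple[str, ...] = tuple(AGE_BANDS)
    years_population: tuple[int, int] = (2010, 2020)
    years_deaths: tuple[int, int] = (2015, 2020)
    prevalence_spec: PrevalenceSpec = field(default_factory=PrevalenceSpec)

    #: planted effect of one prevalence-decile step on the 2020 incumbent vote
    #: share, in percentage points (defaults to a 2.5 pp decile-1->10 span).
    beta_true: float = 2.5 / 9.0
    #: optional leak of the same effect into the 2014 share (placebo power checks).
    beta_2014: float = 0.0
    #: moderation of the planted effect by a centred moderator (see
    #: :func:`generate_elections`).
    beta_moderation: float = 0.0
    #: planted differential pre-trend (2008->2014) for high-prevalence
    #: municipalities, in percentage points.
    pre_trend_effect: float = 0.0

    county_sd: float = 2.0
    noise_sd: float = 5.0
    #: idiosyncratic dispersion of the pre-epidemic (2008/2014) shares; kept
    #: separate so a noiseless 2020 outcome equation still has an informative,
    #: non-collinear lagged share.
    noise_sd_pre: float = 5.0
    eta_lag: float = 0.5
    alpha_2020: float = 40.0
    alpha_2014: float = 62.0
    alpha_2008: float = 60.0

    incumbent_share: float = 0.56
    affiliation_probs: tuple[float, float, float] = (0.22, 0.47, 0.31)
    share_2008_fraction: float = 0.3
    turnout_mean: float = 63.5
    turnout_sd: float = 8.0
    candidates_rate: float = 1.8

    #: log-normal population size parameters (median, sigma of log); the city
    #: scale keeps six-week mortality informative about prevalence.
    pop_median: float = 150_000.0
    pop_sigma: float = 0.6
    min_population: int = 1000

    #: multiplicative log-normal municipality frailty on baseline hazards.
    hazard_frailty_sd: float = 0.1
    #: strength of the urbanicity -> prevalence link (confounding).
    confounding_strength: float = 0.6
    #: optional within-county correlation of the prevalence field.
    within_county_corr: float = 0.0
    #: correlation knob between county-level prevalence and survey anxiety.
    anxiety_prevalence_corr: float = 0.5

    seed: int = 0

    def __post_init__(self):
        if self.n_municipalities < 0:
            raise ConfigurationError("n_municipalities must be non-negative")
        if self.n_counties <= 0 or (
            self.n_municipalities > 0 and self.n_counties > self.n_municipalities
        ):
            raise ConfigurationError("need 1 <= n_counties <= n_municipalities")
        _validate_age_bands(list(self.age_bands))
        self.prevalence_spec.validate()
        for name in ("county_sd", "noise_sd", "noise_sd_pre", "turnout_sd", "hazard_frailty_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not np.isclose(sum(self.affiliation_probs), 1.0):
            raise ConfigurationError("affiliation_probs must sum to 1")
        if not 0.0 <= self.incumbent_share <= 1.0:
            raise ConfigurationError("incumbent_share must lie in [0, 1]")
        lo, hi = self.years_population
        dlo, dhi = self.years_deaths
        if lo >= hi or dlo >= dhi:
            raise ConfigurationError("year ranges must be increasing")
        if dlo < lo or dhi > hi:
            raise ConfigurationError("death years must fall inside population years")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced (convenience for tests)."""
        return replace(self, **kwargs)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated world."""

    true_prevalence: pd.Series  # per municipality, in [0, 1]
    true_baseline_hazard: pd.DataFrame  # municipality x stratum annual hazard
    true_decile: pd.Series  # 1..10 decile of true prevalence
    beta_true: float
    county_effects: np.ndarray
    urbanicity: pd.Series
    seed: int


_BAND_RE = re.compile(r"^(\d+)(?:-(\d+)|\+)$")


def _validate_age_bands(bands: list[str]) -> None:
    if len(bands) == 0:
        raise ConfigurationError("age_bands must be non-empty")
    prev_end = -1
    for i, b in enumerate(bands):
        m = _BAND_RE.match(b)
        if not m:
            raise ConfigurationError(f"age band '{b}' not of form 'a-b' or 'a+'")
        start = int(m.group(1))
        open_ended = m.group(2) is None
        if open_ended and i != len(bands) - 1:
            raise ConfigurationError("open-ended band allowed only in last position")
        end = 10**6 if open_ended else int(m.group(2))
        if end < start:
            raise ConfigurationError(f"age band '{b}' is reversed")
        if start <= prev_end:
            raise ConfigurationError("age bands must be ordered and non-overlapping")
        prev_end = end


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STAGE[stage]])
    )


def _municipality_ids(n: int) -> np.ndarray:
    return np.array([f"M{i:05d}" for i in range(n)])


# ---------------------------------------------------------------------------
# municipalities, covariates, counties
# ---------------------------------------------------------------------------

def generate_municipalities(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw populations, census covariates, and county assignments.

    Returns ``(population_panel, covariates, counties)`` where the population
    panel has one row per municipality x age band x sex x year, the covariate
    table mirrors a municipal census extract (plus a ``size_category``
    quintile), and ``counties`` maps municipality id to county id.

    A single latent urbanicity factor drives population size, density, income,
    education, and (negatively) the old-age share, creating realistic
    confounding between demography and the epidemic field downstream.
    """
    rng = _rng(config, "municipalities")
    n = config.n_municipalities
    ids = _municipality_ids(n)
    bands = list(config.age_bands)
    y0, y1 = config.years_population
    years = np.arange(y0, y1 + 1)

    urban = rng.normal(0.0, 1.0, n)

    # total population: log-normal, partially driven by urbanicity, floored
    log_pop = (
        np.log(config.pop_median)
        + config.pop_sigma * (0.7 * urban + 0.714 * rng.normal(size=n))
    )
    total_pop = np.maximum(np.exp(log_pop), config.min_population * 1.05)

    # age structure: Dirichlet around the national shares, tilted so rural
    # (low-urbanicity) places are older
    base_shares = default_age_shares()
    if len(bands) != len(base_shares):
        # non-default banding: spread the national shares uniformly-ish
        base_shares = np.full(len(bands), 1.0 / len(bands))
    n_b = len(bands)
    old_weight = np.linspace(-1.0, 1.0, n_b)
    conc = 600.0
    tilt = base_shares[None, :] * np.exp(-0.12 * urban[:, None] * old_weight[None, :])
    tilt /= tilt.sum(axis=1, keepdims=True)
    # Dirichlet via normalised gamma draws (vectorised across municipalities)
    gam = rng.standard_gamma(conc * tilt)
    shares = gam / gam.sum(axis=1, keepdims=True) if n > 0 else np.empty((0, n_b))

    sex_frac_f = np.clip(rng.normal(0.515, 0.008, n), 0.45, 0.58)
    growth = rng.normal(0.004, 0.003, n)  # linear annual growth rate

    # counts[i, y, b, s]: linear growth applied to the 2010 strata counts
    sexes = np.stack([sex_frac_f, 1 - sex_frac_f], axis=1)  # (n, 2)
    strata_2010 = shares[:, None, :, None] * sexes[:, None, None, :] * total_pop[
        :, None, None, None
    ]  # (n, 1, n_b, 2)
    scale = (1.0 + growth[:, None] * (years - y0))[:, :, None, None]
    counts = np.maximum(np.rint(strata_2010 * scale), 1).astype(int)
    n_y = len(years)
    population = pd.DataFrame(
        {
            "municipality_id": np.repeat(ids, n_y * n_b * 2),
            "age_band": np.tile(np.repeat(bands, 2), n * n_y),
            "sex": np.tile(["F", "M"], n * n_y * n_b),
            "year": np.tile(np.repeat(years, n_b * 2), n),
            "population": counts.reshape(-1),
        }
    )

    counties = pd.Series(
        [f"C{c:03d}" for c in rng.integers(0, config.n_counties, n)],
        index=ids,
        name="county_id",
    )
    if n > 0:
        # guarantee every county appears at least once when possible
        missing = set(f"C{c:03d}" for c in range(config.n_counties)) - set(counties)
        slots = rng.permutation(n)[: len(missing)]
        for slot, cid in zip(slots, sorted(missing)):
            counties.iloc[slot] = cid

    share_65 = shares[:, -3:].sum(axis=1) * 0.75 if n_b >= 3 else shares.sum(axis=1) * 0.2
    cov = pd.DataFrame(
        {
            "municipality_id": ids,
            "county_id": counties.values,
            "pop_density": np.exp(4.5 + 1.1 * urban + rng.normal(0, 0.35, n)),
            "male_female_ratio": (1 - sex_frac_f) / sex_frac_f,
            "share_65plus": np.clip(share_65 + rng.normal(0, 0.01, n), 1e-3, 0.6),
            "share_immigrants": np.clip(
                _logistic(-2.6 + 0.5 * urban + rng.normal(0, 0.4, n)), 1e-4, 0.6
            ),
            "share_blue_collar": np.clip(
                _logistic(-1.2 - 0.35 * urban + rng.normal(0, 0.3, n)), 1e-3, 0.8
            ),
            "share_unemployed": np.clip(
                _logistic(-2.3 + 0.15 * urban + rng.normal(0, 0.25, n)), 1e-3, 0.5
            ),
            "median_income": np.exp(9.9 + 0.18 * urban + rng.normal(0, 0.12, n)) / 1000.0,
            "share_junior_hs": np.clip(
                _logistic(-1.0 - 0.3 * urban + rng.normal(0, 0.25, n)), 1e-3, 0.9
            ),
            "share_bachelor": np.clip(
                _logistic(-1.4 + 0.55 * urban + rng.normal(0, 0.3, n)), 1e-3, 0.9
            ),
        }
    )
    income_growth = rng.normal(0.04, 0.05, n)
    unemp_change = rng.normal(-0.003, 0.012, n)
    cov["median_income_2014"] = cov["median_income"] / (1.0 + income_growth)
    cov["unemployment_2014"] = np.clip(
        cov["share_unemployed"] - unemp_change, 1e-3, 0.6
    )
    if n > 0:
        tp = pd.Series(total_pop, index=ids)
        codes = (
            stable_rank_bins(tp, 5).to_numpy() - 1
            if n >= 5 and tp.nunique() > 1
            else np.zeros(n, dtype=int)
        )
        cov["size_category"] = pd.Categorical.from_codes(
            codes, categories=SIZE_CATEGORIES, ordered=True
        )
    else:
        cov["size_category"] = pd.Categorical(
            [], categories=SIZE_CATEGORIES, ordered=True
        )
    cov["_urbanicity"] = urban
    return population, cov, counties


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# prevalence field
# ---------------------------------------------------------------------------

def generate_prevalence_field(
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    counties: pd.Series | None = None,
) -> pd.Series:
    """Draw the zero-inflated Beta prevalence field.

    The probability of being untouched falls with urbanicity (epidemics reach
    cities first), with the intercept solved so the sample-average zero
    probability equals the configured ``zero_mass``; the non-zero part is
    ``max_prevalence * Beta(shape_a, shape_b)``.  With ``within_county_corr``
    > 0, a shared county shock enters the zero-propensity score.
    """
    spec = config.prevalence_spec
    rng = _rng(config, "prevalence")
    n = config.n_municipalities
    ids = (
        covariates["municipality_id"].to_numpy()
        if covariates is not None and len(covariates)
        else _municipality_ids(n)
    )
    urban = (
        covariates["_urbanicity"].to_numpy()
        if covariates is not None and "_urbanicity" in covariates
        else np.zeros(n)
    )

    score = config.confounding_strength * urban
    if config.within_county_corr > 0 and counties is not None and n > 0:
        shocks = {c: s for c, s in zip(
            sorted(counties.unique()), rng.normal(size=counties.nunique())
        )}
        score = score + config.within_county_corr * counties.loc[ids].map(shocks).to_numpy()

    if n == 0:
        return pd.Series([], index=ids, dtype=float, name="true_prevalence")

    if spec.zero_mass >= 1.0:
        pi = np.zeros(n)
    else:
        if spec.zero_mass <= 0.0:
            p_zero = np.zeros(n)
        elif np.allclose(score, score[0]):
            p_zero = np.full(n, spec.zero_mass)
        else:
            f = lambda a: _logistic(a + score).mean() - spec.zero_mass
            a = brentq(f, -40.0, 40.0)
            p_zero = _logistic(a + score)
        zero = rng.random(n) < p_zero
        tail = spec.max_prevalence * rng.beta(spec.shape_a, spec.shape_b, n)
        pi = np.where(zero, 0.0, tail)
    return pd.Series(pi, index=ids, name="true_prevalence")


def build_truth(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    counties: pd.Series,
) -> SimulationTruth:
    """Assemble the full ground truth: prevalence, hazards, deciles, county effects."""
    rng = _rng(config, "deaths")  # frailty shares the deaths stream root
    prevalence = generate_prevalence_field(config, covariates, counties)
    ids = prevalence.index.to_numpy()

    schedule = annual_mortality_schedule(list(config.age_bands))
    frailty = np.exp(rng.normal(0.0, config.hazard_frailty_sd, len(ids)))
    hz = schedule.assign(key=1).merge(
        pd.DataFrame({"municipality_id": ids, "frailty": frailty, "key": 1}), on="key"
    ).drop(columns="key")
    hz["annual_hazard"] = hz["annual_mortality"] * hz["frailty"]
    hazard = hz[["municipality_id", "age_band", "sex", "annual_hazard"]]

    decile = (
        stable_rank_bins(prevalence, 10)
        if len(ids) >= 10 and prevalence.nunique() > 1
        else pd.Series(np.ones(len(ids), dtype=int), index=ids)
    )
    county_rng = _rng(config, "elections")
    county_effects = county_rng.normal(0.0, config.county_sd, config.n_counties)
    return SimulationTruth(
        true_prevalence=prevalence,
        true_baseline_hazard=hazard,
        true_decile=decile.rename("true_decile"),
        beta_true=config.beta_true,
        county_effects=county_effects,
        urbanicity=pd.Series(
            covariates["_urbanicity"].to_numpy(), index=ids, name="urbanicity"
        )
        if "_urbanicity" in covariates
        else pd.Series(np.zeros(len(ids)), index=ids, name="urbanicity"),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# deaths
# ---------------------------------------------------------------------------

def generate_deaths(
    population: pd.DataFrame,
    truth: SimulationTruth,
    ifr: pd.DataFrame | None = None,
    window: str = "six_week",
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Draw stratified Poisson death counts for the observation window.

    Baseline years (all but the last) have rate ``N * h``; the final year adds
    the excess ``N * prevalence * IFR``, where ``h`` is the annual hazard
    scaled to the six-week window.  The four-week window is a binomial
    thinning of the same six-week draws (every death carries a time, and a
    shorter window simply catches fewer of them): baseline deaths are kept
    with probability 4/6 and COVID deaths with the four-week fraction, so
    estimates from the two windows are coherent rather than independent.
    """
    if window not in WINDOW_WEEKS:
        raise ConfigurationError(f"window must be one of {sorted(WINDOW_WEEKS)}")
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), _STAGE["deaths"], 7])
    )
    if ifr is None:
        ifr = default_ifr_table(list(cfg.age_bands))
    dlo, dhi = cfg.years_deaths

    pop = population[(population["year"] >= dlo) & (population["year"] <= dhi)].copy()
    merged = pop.merge(
        truth.true_baseline_hazard, on=["municipality_id", "age_band", "sex"], how="left"
    ).merge(ifr, on=["age_band", "sex"], how="left")
    if merged["ifr"].isna().any():
        missing = merged.loc[merged["ifr"].isna(), ["age_band", "sex"]].drop_duplicates()
        raise ConfigurationError(f"IFR table missing strata: {missing.to_dict('records')}")
    if merged["annual_hazard"].isna().any():
        raise ConfigurationError("baseline hazard missing for some population strata")

    # six-week draws first, split into baseline and excess components
    h6 = merged["annual_hazard"].to_numpy() * (6.0 / 52.0)
    pi = truth.true_prevalence.reindex(merged["municipality_id"]).to_numpy()
    excess6 = np.where(
        merged["year"].to_numpy() == dhi, pi * merged["ifr"].to_numpy(), 0.0
    )
    N = merged["population"].to_numpy()
    d_base = rng.poisson(N * h6)
    d_excess = rng.poisson(N * excess6)
    if window == "six_week":
        deaths = d_base + d_excess
    else:
        thin = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), _STAGE["deaths"], 11])
        )
        deaths = thin.binomial(d_base, WINDOW_WEEKS[window] / 6.0) + thin.binomial(
            d_excess, WINDOW_EXCESS_FRACTION[window]
        )
    deaths = np.minimum(deaths, N)
    out = merged[["municipality_id", "age_band", "sex", "year"]].copy()
    out["deaths"] = deaths.astype(int)
    return out


# ---------------------------------------------------------------------------
# elections
# ---------------------------------------------------------------------------

#: coefficients applied to the model-form (logged) covariates when building
#: vote shares; order matters and matches :data:`GAMMA_COLUMNS`.
GAMMA_COLUMNS = [
    "log_pop_density",
    "log_male_female_ratio",
    "log_share_65plus",
    "log_share_immigrants",
    "log_share_blue_collar",
    "log_share_unemployed",
    "median_income",
    "log_share_junior_hs",
    "log_share_bachelor",
    "turnout_2014",
    "n_candidates_2020",
]
GAMMA_DEFAULT = np.array([0.8, -1.5, -1.2, -0.4, -0.6, -0.8, -0.15, -1.0, 1.2, 0.05, -2.5])


def model_form_covariates(covariates: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Covariates in the exact encoding the regression design matrix uses
    (logs except median income), plus turnout and candidate count."""
    from .effects import encode_covariates

    out = encode_covariates(covariates)
    p = panel.set_index("municipality_id")
    out["turnout_2014"] = p["turnout_2014"].reindex(out.index).to_numpy()
    out["n_candidates_2020"] = p["n_candidates_2020"].reindex(out.index).to_numpy()
    return out


def generate_elections(
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
    prevalence_transform: pd.Series | None = None,
    moderator_values: pd.Series | None = None,
    gamma: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate the two-(plus one)-election incumbent panel.

    The 2020 share follows the lagged-outcome structure
    ``alpha + beta_m * decile + gamma'(z - z_bar) + eta * share_2014 + county
    + noise`` truncated to [0, 100], where ``beta_m = beta_true +
    beta_moderation * (moderator - mean)`` and ``z`` holds the model-form
    covariates.  2008/2014 shares share the covariate and county structure but
    are independent of prevalence unless ``beta_2014``/``pre_trend_effect``
    plant a leak.
    """
    rng = _rng(config, "elections")
    _ = rng.normal(0.0, config.county_sd, config.n_counties)  # county effects draw
    n = len(covariates)
    ids = covariates["municipality_id"].to_numpy()
    county_ids = covariates["county_id"].to_numpy()
    county_idx = pd.Index([f"C{c:03d}" for c in range(config.n_counties)])
    county_eff = pd.Series(truth.county_effects, index=county_idx).reindex(county_ids).to_numpy()

    turnout = np.clip(
        rng.normal(config.turnout_mean, config.turnout_sd, n), 1.0, 99.0
    )
    n_cand = 1 + rng.poisson(config.candidates_rate, n)
    incumbent = rng.random(n) < config.incumbent_share
    affiliation = rng.choice(AFFILIATIONS, size=n, p=list(config.affiliation_probs))

    panel = pd.DataFrame(
        {
            "municipality_id": ids,
            "county_id": county_ids,
            "incumbent_running": incumbent,
            "turnout_2014": turnout,
            "n_candidates_2020": n_cand,
            "affiliation": affiliation,
        }
    )
    if n == 0:
        for col in ("share_2008", "share_2014", "share_2020"):
            panel[col] = pd.Series([], dtype=float)
        return panel

    z = model_form_covariates(covariates, panel).loc[ids]
    g = GAMMA_DEFAULT if gamma is None else np.asarray(gamma, dtype=float)
    zc = z[GAMMA_COLUMNS].to_numpy() - z[GAMMA_COLUMNS].to_numpy().mean(axis=0)
    gamma_term = zc @ g

    if prevalence_transform is None:
        decile = truth.true_decile.reindex(ids).to_numpy().astype(float)
    else:
        decile = prevalence_transform.reindex(ids).to_numpy().astype(float)

    has_2008 = rng.random(n) < config.share_2008_fraction
    e08 = rng.normal(0.0, config.noise_sd_pre, n)
    e14 = rng.normal(0.0, config.noise_sd_pre, n)
    e20 = rng.normal(0.0, config.noise_sd, n)

    share_2008 = np.clip(
        config.alpha_2008 + 0.8 * gamma_term + county_eff + e08, 0.0, 100.0
    )
    top_half = (
        truth.true_decile.reindex(ids).to_numpy() > 5
        if truth.true_decile.nunique() > 1
        else np.zeros(n, dtype=bool)
    )
    share_2014 = (
        config.alpha_2014
        + gamma_term
        + county_eff
        + config.beta_2014 * decile
        + config.pre_trend_effect * top_half
        + e14
    )
    if config.noise_sd_pre > 0 or config.county_sd > 0:
        share_2014 = np.clip(share_2014, 0.0, 100.0)

    beta_m = np.full(n, config.beta_true)
    if moderator_values is not None and config.beta_moderation != 0.0:
        m = moderator_values.reindex(ids).to_numpy().astype(float)
        beta_m = beta_m + config.beta_moderation * (m - np.nanmean(m))
    share_2020 = (
        config.alpha_2020
        + beta_m * decile
        + gamma_term
        + config.eta_lag * share_2014
        + county_eff
        + e20
    )
    if config.noise_sd > 0 or config.county_sd > 0:
        share_2020 = np.clip(share_2020, 0.0, 100.0)

    panel["share_2008"] = np.where(has_2008, share_2008, np.nan)
    panel["share_2014"] = share_2014
    panel["share_2020"] = share_2020
    return panel


# ---------------------------------------------------------------------------
# survey cells
# ---------------------------------------------------------------------------

def generate_survey_cells(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    respondents_per_cell: float = 16.0,
) -> pd.DataFrame:
    """Aggregate anxiety cells per county x municipality-size category.

    Cell anxiety lives in [0, 1] and tracks the cell's mean true prevalence
    with strength ``anxiety_prevalence_corr`` (0 disables the link).  Cells
    cover every county x size combination present in the covariate table.
    """
    rng = _rng(config, "survey")
    if len(covariates) == 0:
        return pd.DataFrame(
            columns=["county_id", "size_category", "anxiety_mean", "n_respondents"]
        )
    df = covariates[["municipality_id", "county_id", "size_category"]].copy()
    df["pi"] = truth.true_prevalence.reindex(df["municipality_id"]).to_numpy()
    cells = (
        df.groupby(["county_id", "size_category"], observed=True)["pi"]
        .mean()
        .reset_index()
    )
    pi_std = cells["pi"].std(ddof=0)
    signal = (
        (cells["pi"] - cells["pi"].mean()) / pi_std if pi_std > 0 else 0.0 * cells["pi"]
    )
    anxiety = 0.45 + 0.12 * config.anxiety_prevalence_corr * signal + rng.normal(
        0.0, 0.08, len(cells)
    )
    cells["anxiety_mean"] = np.clip(anxiety, 0.0, 1.0)
    cells["n_respondents"] = 1 + rng.poisson(max(respondents_per_cell - 1, 0.0), len(cells))
    return cells.drop(columns="pi")


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    """Everything one run of the generator produces."""

    config: SimulationConfig
    population: pd.DataFrame
    deaths: dict[str, pd.DataFrame]
    covariates: pd.DataFrame
    panel: pd.DataFrame
    survey_cells: pd.DataFrame
    ifr: pd.DataFrame
    counties: pd.Series
    truth: SimulationTruth

    @property
    def census_population(self) -> pd.DataFrame:
        """The population years an analyst would observe (all but the last 3),
        mirroring a census that stops before the election cycle."""
        y1 = self.config.years_population[1]
        return self.population[self.population["year"] <= y1 - 3].copy()


def simulate_dataset(
    config: SimulationConfig, windows: tuple[str, ...] = ("six_week",)
) -> SimulatedData:
    """Run every generator under one root seed and bundle the results."""
    population, covariates, counties = generate_municipalities(config)
    truth = build_truth(config, covariates, counties)
    ifr = default_ifr_table(list(config.age_bands))
    deaths = {
        w: generate_deaths(population, truth, ifr, window=w, config=config)
        for w in windows
    }
    panel = generate_elections(covariates, truth, config)
    survey = generate_survey_cells(config, covariates, truth)
    return SimulatedData(
        config=config,
        population=population,
        deaths=deaths,
        covariates=covariates,
        panel=panel,
        survey_cells=survey,
        ifr=ifr,
        counties=counties,
        truth=truth,
    )
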