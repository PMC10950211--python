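# epivote

Estimating how an unfolding epidemic moves votes toward incumbents, from
mortality records alone — and validating the whole chain on synthetic
municipalities with known ground truth.

## The problem

Early in an epidemic, confirmed-case counts are unusable at fine geographic
resolution: testing is sparse and uneven. But all-cause mortality is recorded
exhaustively. `epivote` implements a three-stage analysis for municipal
election panels:

1. **Prevalence from excess mortality.** Deaths in municipality *m*, stratum
   *s* (10-year age band × sex), within a fixed observation window, are
   Poisson. In baseline years the rate is `N_mst · h_ms`; in the epidemic year
   it is `N_ms · (h_ms + π_m · IFR_s)`, where `π_m` is the fraction of the
   population infected and `IFR_s` the stratum's infection fatality ratio.
   Because IFRs rise steeply with age, the same excess death rate implies
   *more* circulation in a young town than in an old one — the model weights
   excess deaths accordingly. The estimator maximises the joint likelihood
   over `(h_m1..h_mS, π_m)` with `π_m ∈ [0, 1]` and reports a
   profile-likelihood interval. Census populations observed through the
   pre-epidemic years are extrapolated (linearly or log-linearly) to the
   election year.

2. **Exposure.** Under voter homogeneity, a voter with `k` acquaintances knows
   at least one infected person with probability `1 − (1 − π)^k`; even at low
   prevalence this grows quickly with `k` (the birthday-paradox effect).
   Municipalities are classified against probability thresholds
   (defaults 0.30 and 0.50 at `k = 15`, with the Dunbar `k = 150` available).

3. **Effects on incumbent vote share.** The workhorse regression is a
   lagged-dependent-variable OLS with county fixed effects,

   ```
   I_m,2020 = α + β·Cov_m + γ'X_m + η·I_m,2014 + λ_county + ε_m
   ```

   where `Cov_m` is an outlier-robust transform of estimated prevalence
   (decile rank treated as continuous, or quartile categories; quintile and
   log variants available), and `X_m` holds logged census covariates, 2014
   turnout, the number of candidates, and a baseline-mortality covariate
   (the population-weighted mean of the fitted stratum hazards). Around it
   sit the robustness designs: first differences, difference-in-differences
   (naive four-cell and two-way fixed effects), 1:1 propensity-score matching
   with a 0.025 caliper, a placebo on the previous election (2014 outcome,
   2008 lag, same 2020-based exposure), a parallel-trends contrast, and
   moderator interactions (anxiety index, welfare changes, incumbent
   affiliation) with cluster-robust errors where appropriate.

Because the real administrative inputs cannot be redistributed, the package
ships a first-class synthetic-data generator (`epivote.simulate`) that draws
stratified populations, Poisson deaths with a planted prevalence field
(zero-inflated Beta: most municipalities untouched, a hard-hit minority),
census covariates with a latent urbanicity confounder, election panels with a
planted per-decile effect, and survey cells for the anxiety index — all
byte-reproducible from one seed, so every stage can be tested against known
truth.

## Worked example

```python
import epivote as ev

cfg = ev.RunConfig(output_dir="demo_run", seed=42,
                   designs=("lagged_dv", "first_diff", "did", "psm", "placebo"))
res = ev.run_pipeline(cfg)          # simulates 2,000 municipalities, then analyses them
print(open("demo_run/report.txt").read())
```

```
lagged_dv    transform=decile     coef=+0.2139  se=0.0548  p=0.0001  n=1099
first_diff   transform=decile     coef=+0.2621  se=0.0603  p=0.0000  n=1099
did          transform=quartile_top2 coef=+1.4609  se=0.3590  p=0.0000  n=2198
psm          transform=decile     coef=+0.2175  se=0.0587  p=0.0002  n=958
placebo      transform=decile     coef=-0.0865  se=0.1008  p=0.3910  n=328
```

The generator planted a gain of 0.278 percentage points of incumbent vote
share per prevalence decile (a 2.5 pp span from decile 1 to decile 10), only
in 2020. Reading the report: the lagged-DV, first-difference, and matched
estimates recover the per-decile slope (the decile transform is computed from
*estimated* prevalence, so rank misclassification attenuates them slightly
toward zero); the DiD contrasts top-two-quartile against bottom-two-quartile
municipalities, hence its different scale; and the placebo — the same design
run on the pre-epidemic election — is correctly null. Predicted margins:

```python
pred = ev.predict_at_levels(res.estimates["lagged_dv"], [1, 10])
#  level  predicted  ci_low  ci_high
#      1      70.91   70.33    71.48
#     10      72.83   72.28    73.39
```

a 1.93 ± 0.97 pp higher predicted incumbent share in the most-affected decile.
The exposure stage reports that 35% / 21% of the simulated municipalities
cross the 30% / 50% knowing-an-infected-person thresholds at `k = 15`.

The same stages are scriptable from a shell (`epivote simulate`,
`epivote prevalence`, `epivote exposure`, `epivote effects`, `epivote run`);
every run writes CSV outputs plus a manifest with the seed, config echo, and
output checksums.

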