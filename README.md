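# cobreed

Long-term co-breeding association analysis for colonial birds.

Colonial seabirds such as large gulls breed in dense, spatially discrete
patches that are annually ephemeral — a patch persists to the next season
with low probability (mean occupation expectancy ≈ 1.5 years), so two birds
cannot keep ending up together merely by returning to the same place. That
turnover makes the system a natural experiment for a question behavioural
ecologists usually cannot ask cleanly: **do pairs of individuals maintain
social ties across years, beyond philopatry and random gregariousness — and
does a sustained perturbation (e.g. the arrival of terrestrial predators)
erode that cohesion?**

`cobreed` is a tested pipeline for that question. From individual
resighting records (one row per confirmed breeding: individual, year,
colony, patch) it provides:

- **Dyadic association** — period sociomatrices with ternary states
  (together / apart / missing, precedence together > apart > missing) and
  the half-weight association index
  `HWI = x / (x + y_ab + 0.5 (y_a + y_b))`, with edge-list export (CSV,
  GraphML).
- **Persistence tests** — a 3×3 contingency table cross-classifying each
  dyad's state in two periods, a Pearson χ² (df = 1) on its complete-case
  2×2 core, and power-matched subsampling that re-tests a data-rich period
  at a data-poor period's effective sample size.
- **Probit network regression (AME/SRM)** — a Bayesian symmetric binary
  probit with additive individual random effects and a lagged dyadic
  predictor, `z_ij = β0 + β_dyad x_ij + a_i + a_j + ε_ij`,
  `y_ij = 1(z_ij > 0)`, fitted by a Gibbs sampler that imputes missing
  dyads at every iteration (valid under missing-at-random detection).
  Coefficients are reported as pmean, psd, z = pmean/psd and
  p = 2(1 − Φ(|z|)).
- **A permutation null** — within each year, individuals are reshuffled
  among that year's patches keeping every patch size exact, the statistic
  recomputed per permutation, and the observed value located in the null.
- **A synthetic colony generator** — latent social groups that co-settle
  with configurable tie strength on turnover-prone patches, perturbation
  regimes (permanent emigration or group scrambling), and
  missing-at-random detection — so every stage is testable against known
  ground truth without any field data.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Run the full two-phase study on the default synthetic colony (300 marked
breeders, 30 social groups, tie strength 0.9, detection 0.5, group
scrambling plus elevated dispersal from 2012):

```
$ cobreed run-all --seed 1 --out results
```

or equivalently, from Python:

```python
from cobreed import AnalysisConfig, SimulationConfig, run_full_study

config = AnalysisConfig(
    simulation=SimulationConfig(
        perturbation_start=2012, perturbation_mode="scramble",
        dispersal_rate=0.15,
    ),
    perm_stat="chi_square", seed=1,
)
report = run_full_study(config, output_dir="results")
```

The text report (`results/report.txt`) from the configuration used by
`scripts/acceptance.py` reads:

```
== stable phase (2002-2011) ==
individuals: 264   dyads: 34716   complete-case dyads: 4430
chi-square (2x2 core): 501.818, df=1, P=3.822e-111, n=4430
AME coefficients (pmean, psd, z-stat, P value):
  intercept  -1.730  0.056  -30.755  0
  .dyad      +1.519  0.088  +17.313  0
permutation null (chi_square, 200 reps): observed 501.818, extremeness 0.0050, reject=True

== collapse phase (2007-2017) ==
individuals: 150   dyads: 11175   complete-case dyads: 1154
chi-square (2x2 core): 0.549, df=1, P=0.4589, n=1154
AME coefficients (pmean, psd, z-stat, P value):
  intercept  -1.709  0.085  -20.188  0
  .dyad      -0.278  0.300  -0.926  0.355
permutation null (chi_square, 200 reps): observed 0.549, extremeness 0.4378, reject=False

power-matched subsampling: 1000 draws of 1154 dyads -> 100.0% significant at alpha=0.05
```

Reading it: during the stable phase, dyads that bred together in 2002–2006
were far more likely to breed together again in 2007–2011 than chance
co-occurrence predicts — the χ² is enormous, the lagged-dyad coefficient is
strongly positive (z ≈ 17), and the observed statistic sits beyond all 200
patch-size-preserving permutations (extremeness 0.005). Once the
perturbation scrambles group cohesion, co-breeding in 2012–2017 is
independent of co-breeding in 2007–2011: χ² ≈ 0.5, the coefficient is
indistinguishable from zero, and the permutation test does not reject. The
subsampling line shows the stable-phase signal is not a sample-size
artefact: re-tested at the collapse phase's dyad count it stays significant
in essentially every draw.

Individual stages are also exposed as subcommands:

```
cobreed simulate --seed 5 --out resightings.csv
cobreed associate resightings.csv --years 2002-2006 --out soc.csv --edges-out edges.csv
cobreed test-persistence resightings.csv --period1 2002-2006 --period2 2007-2011
cobreed fit-ame resightings.csv --period1 2002-2006 --period2 2007-2011 --preset production
cobreed permute resightings.csv --period1 2002-2006 --period2 2007-2011 --stat chi_square
```

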