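# Methods

## The scientific question

Colonial birds that breed in dense, spatially discrete patches pose a
disentangling problem: if two individuals breed in the same patch in
successive periods, is that philopatry (site fidelity), shared habitat
preference, random gregariousness — or a social tie between those two
individuals? The system this package models sidesteps the first two
explanations structurally: breeding patches are annually ephemeral, with a
geometric occupation expectancy of about 1.5 seasons, so a pair cannot keep
meeting simply by both returning to the same place. What remains to be
separated is chance co-occurrence versus dyad-specific persistence, and the
package implements four complementary instruments for that separation, plus
a generator of synthetic colonies in which the truth is known.

## Dyadic association

From a resighting table (one row per confirmed breeding of an individual in
a year and patch), each unordered pair of individuals (dyad) gets an annual
state: **together** (same patch, same year), **apart** (both recorded, in
different patches), or **missing** (at least one member unrecorded). Over a
multi-year period the states combine with the precedence
together > apart > missing: a period edge means "bred in the same patch at
least once". A dyad whose members share no observed year in a period is
missing for that period. Tie strength for network export uses the
half-weight association index

    HWI = x / (x + y_ab + 0.5 (y_a + y_b))

with x = years together, y_ab = years both seen apart, y_a, y_b = years
only one member was seen. The half-weight form is the standard choice when
group censuses are incomplete; a dyad with denominator zero is undefined and
excluded. One breeding season is one sampling occasion — repeated
within-season sightings collapse.

## Persistence tests

**Contingency table.** Every dyad over the common individual set is
cross-classified by its state in a predictor period and an outcome period,
giving a 3×3 table whose missing row/column is reported but pulled apart
from inference. Independence on the complete-case 2×2 core is tested by the
Pearson chi-square with df = 1 and no continuity correction. Dyads are not
independent observations (each individual sits in N−1 of them); the
chi-square is therefore descriptive and the permutation null below is the
calibrated referee.

**Power matching.** When two phases have very different effective sample
sizes, the richer phase is re-tested at the poorer phase's power: a fixed
number of complete-case dyads (the count available in the poorer phase) is
drawn without replacement, the chi-square recomputed, and the proportion of
significant draws over many repetitions reported. Draws whose 2×2 subsample
has a zero margin are counted as degenerate and non-significant.

**Probit network regression.** The model for the binary period outcome
y_ij (together at least once) with the lagged dyadic predictor x_ij
(together in the previous period) is a symmetric social-relations probit
with additive individual effects:

    z_ij = β0 + β_dyad x_ij + a_i + a_j + ε_ij,   y_ij = 1(z_ij > 0),
    a_i ~ N(0, σ²_a),  ε_ij ~ N(0, 1)

The a_i absorb individual gregariousness and exposure (how often an
individual co-occurs with anyone), so β_dyad isolates pair-specific
persistence. The dyadic error variance is fixed at 1 (probit
identification); the network is undirected, so one additive effect per
individual enters both endpoints; no multiplicative (latent-factor) term is
fitted. Priors are weakly informative: β ~ N(0, 100 I), σ²_a ~
Inverse-Gamma(2, 1).

Inference is a Gibbs sampler: truncated-normal latent draws given observed
outcomes; unconstrained latent draws for missing dyads (iterative imputation
from the conditional distribution, valid under missing-at-random detection);
conjugate normal updates for (β0, β_dyad); a joint conjugate update of all
additive effects, whose structured precision c I + 11ᵀ
(c = N − 2 + 1/σ²_a) is sampled exactly via its two-eigenvalue
decomposition; and a conjugate inverse-gamma update for σ²_a. Missing
entries of the *predictor* are coded 0 (no evidence of prior association)
with the count reported; listwise deletion is available by flag.

Coefficients are summarized in the social-relations reporting convention:
posterior mean (pmean), posterior SD (psd), nominal z = pmean/psd, and the
two-sided normal tail p = 2(1 − Φ(|z|)). Convergence is monitored by a
split-chain R-hat per coefficient (threshold 1.1) attached to the fit as a
warning, never an exception.

## Permutation null

The null model randomizes raw data, not the network: within each year, the
observed individuals of that year are reassigned among that year's patches
keeping every patch's size exactly; who-is-seen-when is untouched, so
imperfect detection, exposure time and patch-size structure are all
preserved under the null. Both sub-periods are permuted by default (a flag
restricts shuffling to the outcome period). The chosen statistic — the
chi-square of the transition-table core, or the lagged-dyad coefficient
from a reduced-length regression fit — is recomputed on each of n_perm
permuted datasets, and extremeness is the add-one two-sided estimator
(1 + #{|null| ≥ |obs|}) / (n_perm + 1). The observed statistic is a
deterministic function of the records (the regression statistic carries its
own fixed chain seed), so re-running with a fresh permutation seed moves
the null distribution but never the observed value.

## Synthetic colony generator

The generator is the package's test bed and defines its study conditions:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 300 | marked breeders followed from year 1 |
| years | 2002–2017 | breeding seasons |
| n_groups | 30 | latent social groups (balanced, ≈10 birds) |
| patch_survival | 1/3 | geometric patch persistence → 1.5-yr expectancy |
| mean_patches | 30 | stationary patch count (≈10 breeders/patch) |
| tie_strength | 0.9 | P(settle with own group's yearly target patch) |
| annual_survival | 0.9 | per-year survival |
| p_breed | 0.85 | P(breed | alive, present) |
| p_detect | 0.5 | P(resighted | breeding), missing at random |
| perturbation_start | none | first year of the perturbation regime |
| perturbation_mode | emigrate | "emigrate" or "scramble" |
| dispersal_rate | 0 | per-year emigration under perturbation |

Each year every group draws one target patch uniformly from that year's
extant patches; each alive, present breeder follows its group's target with
probability tie_strength, else settles on an independent uniform patch.
Patch extinction/colonization follows the geometric-survival, Poisson-
replacement scheme, so persistent dyads cannot be explained by patch
fidelity — the core premise of the study system. The perturbation regime
either removes individuals permanently ("emigrate": records stop) or
re-draws group membership at random every year from the perturbation start
("scramble": cohesion is destroyed while individuals remain; annual
re-draws rather than a single reshuffle, so no new persistent groups form).
Detection thins true breeding events independently — missing at random by
construction.

The default colony is a scaled-down analogue of a large gull colony (a few
hundred rather than a few thousand analysable breeders) with the per-patch
occupancy (~10 breeders/patch/year) and group size (~10) held at realistic
values. What the generator does **not** emulate: recruitment and age
structure (the cohort only shrinks), mated-pair structure (the species is
monogamous; mates trivially co-breed — an optional exclusion list is the
hook for real data), density dependence, multi-colony geometry, and
non-random detection. Passing tests therefore demonstrate statistical
correctness and calibration of the instruments under missing-at-random
detection and group-mediated settlement — not robustness to detection
heterogeneity or demographic structure.

## The two-phase driver

`run_full_study` mirrors the two-phase field-study design: a stable phase split into two
5-year sub-periods (2002–2006 predicting 2007–2011), and a collapse phase in
which association during 2012–2017 is predicted from the last five stable
years (2007–2011). Per phase it reports the 3×3 table, the chi-square line,
the regression coefficient table (pmean, psd, z-stat, P value), and the
permutation verdict; across phases it runs the power-matched subsampling of
the stable phase at the collapse phase's complete-case dyad count, exports
HWI-weighted edge lists (CSV and GraphML), and writes a manifest with seeds
and versions. The common individual set per phase is everyone recorded in
at least one of its two sub-periods (union; intersection by flag). Because
aggregate "dyadic interactions" totals have no single natural counting unit,
the report prints three labelled candidates (dyads over common individuals,
observed dyad-years, sociomatrix cells) rather than guessing.

## Numerical and design choices

- **Chain lengths.** Default 4,000 iterations (burn-in 500, thin 5) mixes
  well on a few thousand dyads; the production preset is 100,000/500
  (thin 25); permutation replicates default to 2,000/200 since only the
  null's location matters. The end-to-end acceptance run uses 20,000/2,000
  because the sparse collapse-phase outcome mixes slowly.
- **Truncated normals** are drawn by inverse-CDF with the argument clipped
  to [1e-12, 1 − 1e-12]; adequate for |linear predictor| ≲ 6, which holds
  under the weakly informative priors.
- **Degenerate inputs.** A 2×2 core with a zero margin raises a
  degenerate-table error (full-data test) or counts as a non-significant
  degenerate draw (subsampling); an all-constant observed outcome raises a
  non-identifiability error; zero-variance posterior draws raise a
  degenerate-summary error rather than returning z = ±∞.
- **Duplicates.** Two records for one individual-year contradict the
  one-patch-per-season filter upstream; strict mode (default) rejects,
  lenient mode keeps the first with a warning.
- **Statistic choice for permutations.** The driver's default permutation
  statistic is the chi-square: refitting even reduced-length chains 200
  times per phase is disproportionate on a single CPU, and the two
  statistics agree on the verdict in every regime exercised here. The
  regression-coefficient statistic remains available (`stat="ame_beta_dyad"`)
  and the result records which was used.
- **Problem sizes in the test suite.** Statistical tests run at colony sizes
  of 60–100 individuals over 10 years with 20 seeded replicates, and
  regression recovery at N = 60 with 12,000-iteration chains — sizes at
  which every check completes in minutes while keeping binomial counting
  error well inside the asserted margins.

## Known limitations

- Quasi-complete separation (e.g. an observed predictor class with no
  outcome successes) is restrained only by the β prior; the fit then shows
  a large |pmean| with large psd and a split-chain warning. The permutation
  verdict is the reliable instrument in that regime.
- The chi-square treats dyads as independent; use its permutation version
  for inference.
- The additive-effects model omits multiplicative (latent-factor) terms;
  transitive structure beyond individual gregariousness loads onto β_dyad.
- HWI assumes equal detectability across individuals within a year.
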