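# Methods

This note documents the models implemented in `windmate`, the defaults of
the synthetic-data generator, the numerical choices made where the design
was genuinely open, and what the package's tests do and do not establish
about real data.

## Study design being emulated

The package targets a common-garden experiment on a wind-pollinated,
self-compatible, monoecious annual: replicate populations of 61 potted
plants arranged as a filled hexagon, phenotyped at season's end for
female (NF) and male (NM) flower counts, aboveground biomass, and mature
seed number; a size-stratified subsample of each mother's seeds genotyped
at nine microsatellite loci; paternity assigned by categorical likelihood
allocation; and fitness through both sexual functions analyzed as a
function of sex allocation under contrasting inbreeding-depression
scenarios.

## Synthetic populations (`synthpop`)

* **Layout.** Plants occupy a triangular lattice filling a hexagon;
  population sizes must be centered hexagonal numbers (1, 7, 19, 37,
  61, ...). Default spacing 23 cm between nearest pots — the pot spacing
  is not independently known; it was set jointly with the dispersal scale
  so the realized mean outcross mating distance is ≈ 28–30 cm.
* **Size.** Size is log biomass (log-grams); biomass is log-normal,
  size ~ Normal(3.0, 0.6). The spread was chosen so that the smallest
  16% of plants produce roughly one-fifth of the population-mean seed
  crop, matching the strong size dependence of reproduction in the
  emulated system.
* **Gender.** Target maleness is drawn from a three-part mixture: point
  masses at 0 (pure female, weight 0.25) and 1 (pure male, weight 0.15)
  plus a Beta(0.7, 0.7) hermaphroditic continuum — a U-shaped
  distribution covering the full gender range. Gender is sampled
  independently of size.
* **Flower allocation.** Per-plant capacities are power laws of biomass,
  K_f = 305·B^1.5 and K_m = 500·B^1.5 relative to the mean size (i.e.
  exp(1.5·(s − 3)) on the log scale). A plant with target maleness m
  sits on the frontier E[NF] = K_f (1 − m)^{1/γ}, E[NM] = K_m m^{1/γ},
  so (E[NF]/K_f)^γ + (E[NM]/K_m)^γ = 1. The default γ = 0.8 < 1 makes
  the fitness set concave: mixed strategies fall below the linear chord,
  i.e. intermediate allocation is less efficient at producing flowers,
  the economy-of-specialization shape required for the trade-off to
  penalize hermaphrodites. (γ = 1 is the linear trade-off; γ > 1 bows
  the frontier outward and *advantages* hermaphrodites — with such a
  frontier the downstream selection analysis correctly reports
  stabilizing selection, which is how the sign of γ was pinned down.)
  Counts are negative binomial (shape 5) around the frontier; capacity
  coefficients were set by the closed form
  E[NF] = kf_coef · e^{(k_exp·σ_s)²/2} · E[(1−m)^{1/γ}] so that
  population means land near NF ≈ 238, NM ≈ 316.
* **Optional knobs.** `gamma_size_slope` lets concavity vary with size;
  `interference` adds extra female suppression per unit male allocation
  in larger plants. Both default to 0.

## Mass-action mating (`mating`)

Every plant j contributes NM_j · k(d_ij) pollen to the cloud at mother i,
the mother herself at k(0) = 1 (an optional self-weight multiplier covers
within-canopy geitonogamy; default 1). The kernel is exponential,
k(d) = exp(−d/λ), with λ = 10.5 cm; a Gaussian kernel is available. Sires
are drawn multinomially from the normalized cloud, so the selfing
probability is the mother's own share — increasing in her absolute male
flower number, hence steeper in gender for larger plants. There is no
pollen limitation: seed number is negative binomial with mean
0.45 · NF (mean seed set ≈ 106 per plant) and every ovule is fertilized
whenever any pollen weight is positive. Inbreeding depression is *not*
applied during mating; selfed seeds are recorded and discounted in the
fitness accounting, so one simulated dataset supports any δ.

With these defaults the per-mother mean true selfing rate is ≈ 0.29 and
the realized mean outcross mating distance ≈ 30 cm.

## Microsatellite genotypes (`msatgen`)

Nine synthetic loci (5–15 alleles, Dirichlet frequencies) stand in for an
empirical marker panel, whose per-locus allele counts are not published.
Parents are Hardy–Weinberg draws; seeds inherit one uniform allele per
parent per locus. Observed genotypes pass through a frequency-weighted
allele-substitution error (each allele call replaced with probability
0.01 by a draw from the locus frequencies — the "class II" error model of
the categorical-allocation tradition) and per-locus dropout (default
0.02). The error process cannot create alleles outside a locus's set.

## Paternity (`paternity`)

The categorical allocation method is reimplemented from scratch:

* **Likelihood.** For each seed × candidate, the per-locus likelihood is
  P(observed seed genotype | mother, candidate) against
  P(observed | mother, random population sire), marginalizing exactly
  over the seed's true genotype under Mendelian transmission and the
  allele-substitution error model. Applying the error at the offspring
  observation absorbs mistyping anywhere in the trio: an excluded
  candidate gets a finite negative (not −∞) locus LOD whenever the error
  rate is positive. A brute-force enumeration over transmission events
  and error configurations defines truth in the tests (agreement to
  1e-12).
* **Eligibility.** Seeds typed (jointly with their mother) at more than
  five loci enter assignment; candidate sires are the genotyped adults
  with NM > 0 of the seed's population — the mother competes like any
  other candidate when she produces pollen, which is how selfing is
  detected. Allele frequencies for the likelihoods are re-estimated from
  the genotyped parents (pseudocount 0.5).
* **Delta calibration.** The confidence threshold is found by simulating
  offspring of known sires from the candidate pool (default 10,000,
  same error and missingness as the data), scoring them, and taking the
  smallest Delta (best-minus-second LOD gap) such that the required
  fraction (default 80%) of simulated assignments at or above it are
  correct. If every simulated assignment qualifies the threshold is 0.
  With a single eligible candidate, Delta is defined as the best LOD
  itself; exact LOD ties are left unassigned.
* **Selfing rate.** S per mother is the selfed fraction of her
  confidently assigned seeds; mothers with no assigned seed carry no
  estimate.

On default synthetic data ≈ 99% of confident assignments recover the true
sire and the population-mean selfing rate is recovered well within three
percentage points.

## Fitness (`fitness`)

Functional gender G = NM/(E·NF + NM) with E = ΣNM/ΣNF per population.
(The equivalence factor makes allocation unit-free, but the arithmetic
mean of G is not exactly 0.5 for every configuration of flower counts;
the implementation computes E as defined and does not force the mean.)

W_F = N_T (S(1−δ) + (1−S)); W_M credits each sire its share n_ij/N_G,j of
dam j's total seed crop, discounting self-sired shares by (1−δ); W_T is
their sum. Shares use confidently *assigned* seeds only (N_G = number
assigned), the same denominator as the selfing rate, which makes total
male fitness equal total female fitness identically for every δ when all
genotyped seeds are assigned (asserted to 1e-9). Mothers with seeds but
no assigned seed have undefined (NaN) female fitness and are excluded
from relative-fitness means while still accruing male fitness. Relative
fitness divides by the mean over defined values within population ×
scenario. δ is a continuous parameter; the headline scenarios are 0
and 1.

## Regressions (`selection`)

* **Trade-off.** NF ~ NM_std × size (+ population), negative binomial
  with an intercept-only zero-inflation component (pure males produce
  structural NF zeros); NM is standardized per population. Falls back,
  flagged, to a plain NB MLE and then to a quasi-NB GLM if the harder
  fits fail. `slope_at(size)` reports, by default, the response-scale
  cost (female flowers lost per SD of male flowers at the population-mean
  male flower number): on the log-link scale a frontier with
  size-scaling capacities makes the interaction structurally positive,
  while the flowers-per-flower cost at a common male-allocation level
  steepens with size — which is the sense in which the trade-off is
  stronger for larger plants.
* **Selfing.** Mother-level beta-binomial regression (logit mean on
  G × size + population, common dispersion) fitted by maximum likelihood,
  replacing an observation-level random effect with an
  equivalent-purpose, simpler overdispersion model; logistic-GLM start
  values; a dispersion-scaled GLM covariance is the fallback if the
  Hessian is unusable. All-outcrossed (or all-selfed) data are flagged
  degenerate rather than fitted.
* **Selection gradients.** WLS of relative fitness on
  (G + G²) × size × δ (+ population), weights 1/size (size shifted
  positive if needed; the exact variance form is a documented choice),
  cluster-robust SEs by plant because the two δ scenarios reuse the same
  individuals. This replaces a weighted random-intercept mixed model: the
  contract is on signs, SEs and contrasts, and WLS makes the marginal
  coefficient extraction exact linear algebra — a refit with size and δ
  re-centred at the evaluation point reproduces the extracted
  coefficients to 1e-8 (the weights are part of the model specification
  and are not re-derived from the shifted size). Population × gender
  interactions are fitted and dropped when jointly non-significant
  (Wald, α = 0.05). Marginal linear and quadratic gender coefficients at
  mean ∓ SD sizes get delta-method SEs, z-based p-values, δ-contrast
  p-values, and a regime label: disruptive (quad > 0, p < 0.05),
  stabilizing (quad < 0, p < 0.05), directional (only linear
  significant), none. No multiple-testing correction is applied.

## Pipeline and determinism

A single seed feeds a `SeedSequence` that spawns per-population,
per-stage child streams, so identical seeds give identical outputs and
stages can be re-run independently. The seed-subsampling rule genotypes
5, 6, 7, 8, 9, 10 seeds for mothers with 5–100, 101–200, 201–300,
301–400, 401–500, > 500 seeds (all of them below 5). Every CSV starts
with a `# seed=N` comment. Populations are simulated and assigned
independently and pooled only for the regressions, with population as a
fixed covariate (three levels cannot support a variance component).

## Problem sizes

The test suite and the acceptance script run the full default conditions:
3 populations × 61 plants, 9 loci, 1% genotyping error, 5–10 seeds
genotyped per mother (~850 seeds per experiment). Replicate counts are
100 for the selfing-slope and null-calibration properties, 50 for the
end-to-end selection-pattern property, and 10 averaged experiments in the
acceptance script; Delta calibration uses 1,000 simulated offspring per
population inside replicate loops and 10,000 in single runs.

## What the generator does and does not emulate

Emulated: the spatial layout and scale of mating, log-normal size
variation, the full gender continuum with unisexual extremes, a concave
allocation trade-off whose flower cost steepens with size, mass-action
selfing rising with male allocation and size, marker informativeness and
error of a realistic microsatellite panel, and the field's seed-sampling
protocol. Not emulated: growth and phenology, wind anisotropy and
temporal flowering overlap, pollen limitation, stutter/null-allele
genotyping artefacts, whole-sample genotyping failures, between-population
gene flow, and the experimental-evolution history that produced the
phenotypes. Passing tests therefore demonstrate internal consistency of
the method chain and its statistical power under these idealized
conditions, not the field result itself.

## Known limitations

* The mass-action cloud is isotropic and stationary; real wind pollination
  is neither.
* The selfing model's beta-binomial dispersion is shared across mothers.
* The zero-inflated trade-off fit can be fragile on small samples; the
  flagged fallbacks keep the pipeline running but change the variance
  model slightly.
* Selection-gradient SEs are asymptotic (z); with 183 plants per
  experiment, small-sample refinements (t with cluster-adjusted df) would
  widen intervals modestly.
* Paternity confidence is calibrated against the simulator's own error
  model; real data with miscalled large alleles or null alleles would
  need the error rate revisited.
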