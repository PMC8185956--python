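# Methods

## The natural-history model

The simulator is a discrete-time state-transition model over nine mutually
exclusive health states: `normal`, `small_adenoma`, `large_adenoma`,
`preclin_early`, `preclin_late`, `clin_early`, `clin_late`, `crc_death`,
`other_death`. Progression is a continuous-time, age-inhomogeneous Markov
process: adenoma onset follows a Weibull hazard λ₁(a) = l·γ·a^(γ−1); small
adenomas grow at rate λ₂; large adenomas become preclinical early cancer at
λ₃; preclinical early disease progresses to late (λ₄) or becomes symptomatic
(λ₅); preclinical late disease becomes symptomatic at λ₆; clinically detected
cancer carries stage-specific mortality λ₇ (early) and λ₈ (late), treated as
known from registry data and held fixed; every alive state is exposed to
background mortality μ(a).

Annual cycle probabilities come from the matrix exponential of the
age-specific generator, `P(a) = expm(Q(a))`. The exponential embeds the
continuous-time process exactly — including multi-step paths within a year
and competing risks — which per-arrow `1 − e^(−r)` conversions would not.
Cycles start at exact integer ages 50 … 94 (45 cycles) for a cohort of
50-year-old women.

Small adenomas progress only through the large-adenoma state; no direct
small-adenoma → cancer arrow exists, since only the large-adenoma arrow
carries a progression rate. The cohort starts with adenoma prevalence
`p_adeno` (a fraction `p_small` of which are small) and preclinical
early/late prevalence 0.12 / 0.08, read as absolute cohort proportions; both
seeds are parameters of `NaturalHistoryParams` and can be set to zero. These
magnitudes are epidemiologically surprising for a general 50-year-old
population, but the confirmatory study is internally consistent — the same
model generates the targets and is calibrated — so recovery conclusions do
not depend on this reading.

Two evaluation modes share one generator. The deterministic cohort model
propagates expected occupancy (used for the emulator's design data, where a
noise-free input–output map is wanted); the microsimulation samples one
categorical transition per alive individual per cycle (used to generate
targets with realistic sampling noise). Outcomes are summarised over nine
5-year age groups: adenoma prevalence and the small-adenoma proportion are
ratios of accumulated person-time among alive, not-yet-clinical individuals
(the screening-eligible population); incidence divides new clinical
detections by at-risk person-time. If an age group accrues no adenoma
person-time the small-adenoma proportion is reported as 0 with a warning (or
NaN in replicate aggregation, where such replicates are dropped).

The bundled life table is synthetic: a Gompertz schedule
μ(a) = 5·10⁻⁵·e^(0.085·a) over ages 50–100, approximating a U.S. female
period life table. Recovery experiments are self-consistent under any fixed
table; any `age,mu` CSV can be substituted.

## Design of experiments and emulator

Parameter draws come from a plain random-permutation Latin hypercube over
the uniform prior box (per parameter, one draw uniformly inside each of the
n equal-width strata; no maximin optimisation). Training and validation
designs use independent seeds (`seed`, `seed+1`); default sizes are 8,000
and 2,000 rows.

The emulator is a fully connected network with two hidden tanh layers of
100 nodes and a linear output layer, mapping 9 scaled inputs to 36 scaled
outputs. Outputs are scaled to [−1, 1] by training-set min/max. Inputs are
scaled to [−1, 1] from the *prior bounds* (not the realised draws), linearly
except for columns whose prior spans a decade or more (`upper/lower ≥ 10`;
in this model only the Weibull scale `l`), which are mapped log-linearly.
The log map matters twice over: a linear map compresses the lower decade of
`l` into a sliver of the input range (hurting emulator resolution exactly
where the posterior lives), and the l–γ likelihood ridge
(l·γ·a^(γ−1) ≈ const) is exponentially curved in linear-l coordinates but
nearly linear in (log l, γ), which the sampler's dense mass matrix can then
absorb. In measurements during development this one change moved sampler
effective sample sizes from ≈7 to >150 per parameter.

Training minimises mean squared error with Adam (learning rate 10⁻³,
minibatches of 256, up to 2,000 epochs, early stopping with patience 50 on a
10% split of the training set; scikit-learn backend, deterministic given the
seed). These settings are conventional small-MLP practice and are exposed in
`TrainingConfig`. Fidelity is measured as per-output and pooled R² on the
scaled validation pairs; the study pipeline refuses to calibrate if pooled
R² falls below a configurable gate (0.999 at full scale, 0.99 in the
desk-scale profile) because a low-fidelity surrogate yields confidently
wrong posteriors. Weights are exported as plain CSV matrices so the sampler
has no training-framework dependency.

## Likelihood, prior and sampler

The 36 targets enter an independent-normal likelihood,
y_ti ~ Normal(ϕ_ti(θ), σ_ti), with ϕ the emulator prediction mapped back to
natural units. Priors are uniform over the Table-of-parameters box; in the
emulator's scaled coordinates the prior is flat for linearly mapped columns
and ∝ exp(c·s) for the log-mapped column, a correction the sampler includes
so the prior remains uniform *in natural units*.

Sampling uses a self-contained No-U-Turn sampler (numpy implementation):
leapfrog integration, trajectory doubling with slice acceptance, divergence
guard at ΔH = 1000, dual-averaging step-size adaptation (target acceptance
0.9), and a mass matrix re-estimated from the middle 60% of warmup draws.
The mass matrix is *dense* by default: strongly correlated posteriors are
the normal case in calibration (non-identifiability), and a diagonal metric
mixes poorly along the ridges. The box constraint is enforced by sampling on
the unconstrained transform s = tanh(u/2) with its Jacobian in the target,
so draws respect the prior support exactly and the boundary has measure
zero. Defaults: 4 chains × 2,500 retained draws (10,000 total), 1,000
warmup per chain, maximum tree depth 12. Split-R̂ and effective sample size
(arviz) are attached to every run; parameters with R̂ > 1.01 raise a visible
warning rather than failing silently. Reported per-draw log posterior is the
natural-units log posterior (≡ log likelihood up to a constant under the
uniform prior); the MAP is the retained draw with the highest value, ties
broken by first index. Credible intervals are equal-tailed percentiles.

## IMIS comparison arm

The comparator runs directly on the simulator (no emulator): n₀ = 1,000
points from the prior, then per iteration b = 100 proposals from a Gaussian
centred at the current highest-weight point with covariance from its b
nearest neighbours (prior-range-scaled distances, importance-weighted, small
diagonal ridge), a defensive mixture of prior and all components as the
importance density, stopping when the expected unique fraction of a
hypothetical resample reaches 1 − 1/e, and finally 10,000 draws resampled by
weight. Proposals are truncated to the prior box by rejection. The
deterministic cohort model supplies the likelihood so weights are
noise-free. Tuning constants follow the algorithm's usual conventions and
are config-exposed; the comparison is qualitative. At desk scale IMIS
under-covers visibly — finite Gaussian mixtures underestimate the spread of
strongly correlated posteriors — which is reported, not asserted.

## The confirmatory study and its synthetic targets

Targets are generated at the base-case parameter values by running the
microsimulation 100 times with 500 individuals (adenoma-related series) and
100 times with 100,000 individuals (incidence series) on independent
streams; each target is the replicate mean. Its uncertainty σ_ti is, by
default, the *across-replicate standard deviation* — the sampling
uncertainty that a single study of the stated size would carry, which is
exactly the "different amounts of data behind different targets" the two
cohort sizes emulate. The alternative reading (standard error of the
replicate mean, SD/√reps) is available as `target_sigma: "se"`. The default
matters: under the SE reading the incidence targets claim uncertainties
(~10⁻⁶) several times smaller than the bias floor of any practical
surrogate, so recovery coverage measures emulator bias rather than the
calibration method; under the SD reading the full-scale study covers all
nine parameters and reproduces the expected posterior-correlation structure
(absolute off-diagonal correlations ranging from ≈0.01 to ≈0.96, the
l–γ pair at the top).

All randomness derives from one master seed through named substreams
(`targets`, `doe`, `training`, `sampler`, `imis`), so stages can be rerun in
isolation and a run is reproducible from its manifest (config echo, seeds,
artifact checksums).

## Problem sizes used by the tests

The shipped `test` profile (2,000/500 design, 20 replicates, 20,000
individuals for incidence targets, 2 chains × 2,000 draws) exercises the
full pipeline in under a minute and is the scale at which the recovery test
runs; the `paper` profile holds the full-scale settings. Because coverage of
all nine intervals is itself a stochastic event, the recovery test permits
one rerun with a fresh seed when exactly one interval narrowly misses.
Microsimulation-versus-cohort agreement is tested with empirical Monte-Carlo
standard errors from 8 replicates of 12,500 individuals (the information
content of one 100,000-individual run).

## Known limitations

- The emulator posterior is an approximation; its bias relative to the
  simulator is bounded by the fidelity gate but not zero, and targets with
  uncertainties far below that bias floor will dominate the fit (see the
  σ discussion above).
- The synthetic targets share the simulator's own structure; passing
  recovery says nothing about structural misspecification against real
  registry data, and no model-discrepancy term is included.
- The natural-history model is a single-cohort (50-year-old women),
  no-intervention model: no screening, costs, or stratification.
- IMIS results depend on tuning constants the comparison does not explore.
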