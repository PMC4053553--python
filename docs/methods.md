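# Methods

`pphmap` analyses counts of potentially preventable hospitalizations
(PPH) — admissions that timely outpatient care should largely avert —
aggregated over small administrative health areas, jointly across
several chronic conditions. This note documents the models, the
estimation machinery, the synthetic-data generator, and the design
choices made where the design was genuinely open.

## Data model and standardization

Inputs are a long-format stratum table (area × condition × 5-year
age–sex stratum, person-years and admission counts) plus a GAL
neighbor list defining area adjacency. Expected counts use indirect
standardization: the whole-region stratum rate
`r_sj = Σ_i count_isj / Σ_i n_is` applied to each area's stratum
person-years, `e_ij = Σ_s n_is r_sj`. By construction
`Σ_i e_ij = Σ_i O_ij` per condition; the package validates this to
relative 1e-6 at assembly and tests it to 1e-9. The standardized
hospitalization ratio is `SHR_ij = O_ij / e_ij`.

The default stratum dialect is 18 five-year age bands from 15–19
upward crossed with sex (36 strata), configurable; nothing downstream
depends on the dialect beyond the existence of an age gradient.

Descriptive surfaces follow small-area-variation practice: crude and
directly standardized rates per 100,000 person-years; the extremal
quotient EQ5–95 (ratio of the interpolated 95th to 5th percentile of
area rates, linear "type 7" quantiles), reported as undefined when the
5th percentile is 0 — the situation for rare conditions where ≥5% of
areas record no admissions — or when fewer than 20 areas are
available; a moment-based empirical-Bayes variance
`τ̂² = max(0, mean_i[(O_i/e_i − 1)² − 1/e_i])`, derived from
`Var(O_i/e_i) = τ² + 1/e_i` under a Poisson mixture with relative-risk
variance τ²; pairwise Pearson correlations of SHRs with two-sided,
unadjusted t-test p-values; and Moran's I with binary symmetric
weights and a two-sided permutation p-value (999 permutations by
default, so the smallest attainable p is 0.001). Isolated areas carry
no weight and are excluded from Moran's I with a warning.

## The shared component model

For area `i` and condition `j`,

    O_ij ~ Poisson(e_ij ρ_ij),
    log ρ_ij = α_j + δ_j φ_i + ε_ij.

`φ` is a latent risk surface common to all conditions; `δ_j > 0` is the
factor loading measuring how strongly condition `j` follows it;
`ε_ij` are exchangeable N(0, σ²_specific,j) condition-specific
effects. Two priors for `φ` are supported: exchangeable
N(0, σ²_shared) and the intrinsic CAR (pairwise-difference) prior on
the adjacency graph. Comparators sharing the same first level are the
per-condition BYM model (`log ρ_i = α + u_i + v_i`, `u` ICAR, `v`
exchangeable) and a non-spatial per-condition model (`α + v_i` only);
both reuse the same sampler with pieces switched off.

Priors: improper flat on each `α_j` (proper posterior requires at
least one admission per condition, validated at input);
`log δ_j ~ N(0, precision 5.9)` in the WinBUGS precision convention
(variance ≈ 0.17, the usual choice for this model class; a variance
reading is available as a config switch for sensitivity); Gamma(0.5,
0.0005) on each precision (1/σ²), configurable. The intrinsic CAR
normalizing constant uses rank `N − #components`; isolated areas get
an exchangeable conditional with the shared precision (and a warning),
contributing a full degree of freedom each.

Identifiability. The likelihood cannot see (a) a shift between
`mean(φ)` and the intercepts, (b) a shift between `mean(ε_·j)` and
`α_j`, (c) the δ/φ scale split. After every sweep the sampler centers
`φ` (absorbing `δ_j · mean(φ)` into `α_j`), centers each `ε` column
into its intercept, and rescales so the geometric mean of `δ` is 1
(generalizing the two-condition δ, 1/δ convention; `none` is available
to mimic prior-only identification). All three transforms leave the
likelihood invariant.

## Sampler

Metropolis-within-Gibbs, fully vectorized:

- conjugate Gamma draws for `prec_phi` and each `prec_eps,j`;
- adaptive random-walk Metropolis for `α_j`, `log δ_j`, each `φ_i`,
  each `ε_ij`. Exchangeable sites are conditionally independent given
  the rest, so whole vectors/matrices are proposed and accepted
  element-wise. Under the ICAR prior, areas are partitioned by greedy
  graph coloring and each color class (mutually non-adjacent, hence
  conditionally independent) is updated simultaneously.
- three coherent moves that cure the hierarchical variance funnel,
  which single-site updates traverse very slowly: a likelihood-
  invariant transfer `δ_j → δ_j e^c`, `ε_·j → ε_·j + (δ_j − δ_j e^c)φ`
  that lets the shared/specific split of one condition jump in one
  step; and amplitude moves `φ → e^c φ, prec_phi → e^{−2c} prec_phi`
  (and per-condition analogues for `ε`) with the exact prior and
  Jacobian terms. Without these moves the split R̂ of `log δ` for
  low-noise conditions stalls near 1.5 at desk-scale schedules; with
  them it reaches ≈ 1.00.

Proposal scales start at `2.4/√(information)` and adapt by
Robbins–Monro (`gain t^{-0.6}`, target acceptance 0.44) during burn-in
only, so the post-burn-in kernel is fixed and draws are valid MCMC
output. Post-burn-in acceptance rates are recorded per block and land
in [0.15, 0.6] on default synthetic data. One master seed derives
per-chain PCG64 streams; identical seeds reproduce draws bit for bit.
Initialization: `α_j = log(ΣO_j/Σe_j)`, `φ, ε ~ N(0, 0.1²)` per chain,
`log δ = 0`.

The default schedule is 3 chains × 49,500 iterations, 12,000 burn-in,
keep every 75th (500 retained per chain); the `--fast` profile
(3 × 5,000 / 1,000 / 5) is the desk-scale setting used throughout the
test-suite experiments. Retained draws hold ≈ 28 MB at 240 areas × 6
conditions under `--fast`.

Sampler validation: on a 2-area, 1-condition toy with fixed variances
the sampled posterior of the identifiable level `α + mean(φ)` matches
a dense 3-D grid posterior within total variation 0.05 (10,000
retained draws); the posterior-shrinkage, acceptance-band and
determinism contracts are unit-tested.

## Posterior summaries

- DIC: `D(θ) = −2 log L`; `Dbar` averages the per-draw deviances;
  the plug-in deviance is evaluated at posterior means of `α, log δ,
  φ, ε` on their sampled (log) scales; `pD = Dbar − D(θ̄)`,
  `DIC = Dbar + pD`. Negative `pD` is reported, flagged, never hidden.
- Variance decomposition: per retained draw and condition,
  `f_jt = Var_i(δ_j φ_i) / [Var_i(δ_j φ_i) + Var_i(ε_ij)]` with
  empirical variances across areas; the table reports 100 × posterior
  mean with central 95% credible intervals, alongside posterior
  medians/intervals of `σ_specific,j`, `δ_j` and `σ_shared`. Computing
  the fraction from posterior-mean summaries instead of per draw was
  rejected: it is inconsistent with the reported uncertainty of the
  fraction and biased by Jensen's inequality.
- Exceedance surfaces: the per-area fraction of retained draws with
  `exp(φ_i) > 1` (shared pattern), `ρ_ij > 1` (smoothed SHR per
  condition), or `exp(ε_ij) > 1` (discrepant component), categorized
  high / low / indeterminate at 0.8 / 0.2. These equal brute-force
  draw counting exactly.
- Convergence: split-chain potential scale reduction (each chain
  halved; plain Gelman–Rubin/Brooks–Gelman form, cross-checked against
  arviz's split R̂), and sample autocorrelations per chain. A constant
  parameter reports R̂ = 1 with a zero-variance warning.

## Synthetic data generator

The generator draws data exactly from the model above and is the
package's study-conditions bench: ~240 areas (near-square rook lattice
by default; a random-geometric alternative provides irregular
adjacency), annual person-years log-uniform on 4,065–250,616
(reproducing the heavy right skew of small-area population sizes) ×
3 years, six conditions with regional rates 11.3, 155.0, 88.9, 3.9,
23.9, 21.2 per 100,000 person-years, loadings δ = (0.92, 1.12, 0.74,
1.42, 1.11, 1.09), σ_shared = 0.121 and σ_specific = (0.243, 0.112,
0.079, 0.673, 0.489, 0.353) — the reported point estimates of the
motivating regional analysis. Counts are pure Poisson at stratum
level (no extra overdispersion; readmission clustering present in real
discharge data is deliberately not emulated), allocated across strata
proportionally to stratum person-years × an exponential age gradient
(0.25 per band), with the population profile declining 0.18 per band.
Per-condition intercepts are calibrated so the expected regional total
matches the configured rate exactly. ICAR shared fields are sampled by
spectral decomposition of the graph Laplacian and rescaled to the
requested marginal standard deviation, since the intrinsic prior has
no scale of its own. Ground truth (α, δ, φ, ε, variance components,
and the per-condition empirical shared-variance fraction) is returned
and serializable to JSON.

What passing recovery tests do **not** show about real data: the
generator has no private-sector leakage, no double insurance, no
readmission clustering, no age-by-area confounding beyond the global
gradient, and its adjacency is a lattice rather than administrative
geography.

## Recovery behaviour and a known limitation

At the study conditions the loadings δ_j are recovered within their
95% credible intervals essentially always (coverage ≥ 4/6 conditions
in 10/10 desk-scale seeds). The shared-variance percentages are
recovered without systematic bias, but per seed their posterior is
genuinely diffuse for the two conditions whose specific-effect scale
sits at or below the Poisson noise floor (σ = 0.112 and 0.079 at
~120–290 expected counts per area): the latent factor can rotate
toward either low-noise condition at little likelihood cost, so one
seed may attribute nearly all of such a condition's variation to the
shared pattern and the next seed the reverse. This is a property of
one-factor models, not of the sampler — long runs with R̂ ≈ 1.00 show
the same spread, and it matches the very wide intervals (e.g. 22–85
percentage points) reported for exactly these conditions in the
motivating analysis. Averaged over seeds the recovery is accurate;
the acceptance checks therefore assess per-seed interval coverage for
δ and seed-averaged accuracy (with per-seed interval behaviour
reported) for the percentages.

## Problem sizes

Experiments run at: 240 areas × 6 conditions with the `--fast`
schedule for recovery (10 seeds); 100 areas with 3 × 3,000 / 1,000 / 4
for the DIC model-choice comparisons (5 seeds; the comparison needs
only the ordering, which stabilizes quickly); 36 areas × 3 conditions
for sampler contract tests; 2 areas for the grid-posterior oracle.
These are the package's own desk-scale defaults; all are configurable.

## Known limitations

- Exceedance and decomposition summaries assume the retained draws are
  a fair posterior sample; the strict CLI gate (max monitored R̂ ≤ 1.1)
  is a guardrail, not a proof of convergence.
- The ICAR implementation targets the conditional specification with a
  sum-to-zero constraint per connected component; proper CAR models
  with a spatial autocorrelation parameter are out of scope.
- No covariate effects; the models are intercept + random-effect only.
- GeoJSON support is property-merging for map export, not cartography.
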