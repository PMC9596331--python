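# Methods

## The comparative question and the model

Across bird species, maximum lifespan, body mass, adult telomere length
(kb), and the telomere rate of change (TROC, kb/year; negative means
shortening) are jointly shaped by shared ancestry. Two species are similar
partly because they diverged recently, so raw cross-species correlations
conflate trait co-evolution with phylogenetic inertia. The package
addresses this with the phylogenetic mixed model (the quantitative-genetic
"animal model" transplanted to species): for a trait vector *y* over *n*
species,

    y = μ·1 + a + e,    a ~ N(0, σ²ₐ A),    e ~ N(0, σ²ₑ I)

where **A** is the phylogenetic relatedness matrix — entry (i,j) is the
branch length shared by the root-to-tip paths of species i and j, i.e. the
depth of their most recent common ancestor. Under Brownian-motion trait
evolution, **A** is proportional to the expected among-species trait
covariance. We rescale **A** by its maximum diagonal entry so that, for an
ultrametric tree, the diagonal is exactly 1; variance components are then
scale-free per trait and the *phylogenetic signal*

    ρ = σ²ₐ / (σ²ₐ + σ²ₑ)  ∈ [0, 1]

is the proportion of among-species variance statistically attributable to
the phylogeny (phylogenetic heritability). Non-ultrametric input is
accepted with a warning; the diagonal then varies and ρ is interpreted at
the deepest tip.

The bivariate model stacks two traits: phylogenetic effects have
covariance Σ_P ⊗ A and residuals Σ_E ⊗ I, with 2×2 components Σ_P, Σ_E.
Three correlations can be formed per posterior draw — from Σ_P, from Σ_E,
and from Σ_P + Σ_E. **Which of these constitutes "the phylogeny-adjusted
correlation" is a genuine modelling choice**: we report the
residual-component correlation (r_resid) as the headline adjusted value,
because it is the association remaining after the phylogenetically
heritable part of both traits is removed, and we always report r_phylo and
r_total alongside. When one trait has near-zero signal, Σ_P is weakly
identified and r_resid ≈ r_total; when signal is strong they can diverge,
and on a star tree (A = I) only r_total is well identified — the test
suite asserts exactly these identifiability facts rather than pretending
the split is always estimable.

## Lifespan decomposition

Log₁₀ maximum lifespan is regressed on log₁₀ mean adult female body mass by
OLS. Fitted values are *mass-predicted lifespan*; residuals are
*mass-independent lifespan* (lifespan at a given body size — the slow–fast
pace-of-life axis). Base-10 logs are used; every reported statistic (r, R²,
F, W) is invariant to the log base. The components satisfy, to numerical
precision: predicted + residual = log lifespan; corr(predicted, residual)
= 0; predicted is an affine image of log mass, so any third trait
correlates with mass-predicted lifespan exactly as with log mass (up to the
slope's sign). Residual normality is summarised by Shapiro–Wilk plus Q–Q
coordinates for export. Pearson correlations carry t = r·√df/√(1−r²) with
df = n−2, a two-sided p, a 95% Fisher-z interval (±1.96/√(n−3)), and Cohen
effect-size labels with closed lower bounds: |r| ≥ 0.5 large, ≥ 0.3 medium,
≥ 0.1 small, else trivial.

## Gibbs sampler

All full conditionals are conjugate, so the sampler is a plain Gibbs
scheme. We work in the eigenbasis A = U diag(d) Uᵀ: rotating the data by Uᵀ
makes the latent-effect full conditional diagonal (univariate) or a set of
n independent 2×2 Gaussian problems (bivariate), so a sweep costs O(n) and
a default chain takes well under a second. Updates per sweep:

1. latent effects ã from N(m, V) with V⁻¹ = diag(1/(σ²ₐdᵢ)) + I/σ²ₑ
   (bivariate: Σ_P⁻¹/dᵢ + Σ_E⁻¹ per eigencomponent);
2. intercept(s) from the normal full conditional under a flat prior;
3. σ²ₐ, σ²ₑ from inverse-gamma(shape (ν+n)/2, scale (νV + SS)/2); the
   bivariate Σ_P, Σ_E from inverse-Wishart(df ν+n, scale νV + S), drawn via
   Bartlett decomposition.

Priors follow the weakly-informative convention of the MCMC mixed-model
framework this emulates: V = 1, ν = 0.002 per variance; V = I, ν = 2.002
per 2×2 covariance. They are configurable through `PMMConfig`. Traits are
standardised internally (variance draws are rescaled back; correlations and
ρ are scale-free). Chain defaults: 13,000 iterations, 3,000 burn-in,
thinning 10 → 1,000 retained draws. One seeded NumPy `default_rng` per fit;
results are bit-reproducible given (seed, inputs).

Numerical choices. A singular or near-singular **A** is "bent" by flooring
eigenvalues at 1e−8, with a logged warning. A numerically non-PD
inverse-Wishart draw is retried with escalating jitter on its scale matrix
(counted and logged). The posterior point estimate of ρ and of adjusted r
is the kernel-density mode (Gaussian KDE, Silverman bandwidth, 512-point
grid) with the posterior mean reported alongside — variance-ratio
posteriors at n = 30 are skewed, and the mode is the conventional summary
for this model family. HPD intervals are the shortest contiguous window
containing ⌈0.95·n⌉ sorted draws (ties → lowest start). pMCMC is twice the
smaller sign fraction, floored at 1/n_draws. ESS uses Geyer's initial
monotone positive-sequence estimator of the integrated autocorrelation
time; Geweke z compares the first 10% and last 50% of the chain with
ESS-adjusted variances. ESS < 100 attaches a convergence warning to the
result rather than raising.

The prior is not innocuous at the identifiability boundary: with A = I the
likelihood constrains only σ²ₐ + σ²ₑ, and the symmetric scale-invariant-ish
prior makes the ρ posterior bimodal at the ends. The identity prior scale
(ν = 2.002) also shrinks posterior correlations toward 0 at small n —
roughly a factor S/(S+2) on the relevant cross-product. Both effects are
real posterior geometry, not sampler error; the quadrature-oracle test
confirms the sampler targets the exact posterior.

## Trees and consensus

Newick parsing and tree containers are dendropy's; missing branch lengths
read as 0 with a warning. The majority-rule consensus keeps clades present
in >50% of trees (strict majority, not extended), and assigns each kept
clade the arithmetic mean of its subtending branch length over the trees
that contain it — a deterministic, well-defined convention for summarising
a posterior tree sample with branch lengths. Tip labels are matched to
trait rows after normalisation (whitespace→underscore, case-fold);
unmatched species are dropped with a warning, and fewer than 3 shared
species is an error.

## Synthetic data

The generator exists so that every stage — parsing, consensus, covariance,
decomposition, correlation, MCMC — runs against data whose truth is known.
Trees are Yule (pure-birth): lineages split at unit rate until n tips, a
final exponential waiting time is appended, and the tree is rescaled to
unit height (the birth rate is irrelevant after rescaling). Traits are
drawn directly from the tip distribution N(0, Σ_P⊗A + Σ_E⊗I) via Cholesky
factors — mathematically identical to simulating Brownian motion along
branches, and easier to verify (a Monte-Carlo test checks the Kronecker
covariance entrywise).

`generate_birdlike_dataset` encodes the study conditions as generating
parameters on a 30-species tree: phylogenetic signal 0.9 for log mass, 0.07
for the mass-independent lifespan component, 0.07 / 0.06 for telomere
length and TROC; allometry log₁₀ lifespan = 0.66 + 0.23·log₁₀ mass (an
avian-range slope, masses spanning ~10 g–10 kg via log-mass mean 2.3, sd
0.75); target allometric R² 0.59; TROC correlated 0.43 with the
mass-independent component (via the residual correlation, rescaled so the
*total* trait correlation is 0.43); telomere length ~15 ± 5 kb; TROC
−0.15 ± 0.10 kb/year. One subtlety: because tips are phylogenetically
correlated, the *sample* variance of a high-signal trait falls below its
population variance, so the residual spread is calibrated against expected
sample variances on the simulated tree ((tr S − 1ᵀS1/n)/(n−1)); without
this the realized R² would sit systematically below its target. Targets
are generating parameters, not per-dataset guarantees — at n = 30 the
realized R² ranges roughly 0.4–0.75 across seeds, and calibration is
checked on replicate means.

What the generator does **not** emulate: measurement error and
between-assay heterogeneity (TRF vs Q-FISH), chick-vs-adult sampling bias
in TROC estimates, literature-sourcing variance, non-Brownian evolution
(OU attraction, rate shifts), and non-ultrametric or misspecified trees.
Passing tests on these data show the pipeline recovers the stated
generative structure; they cannot certify robustness to those real-data
features.

## Problem sizes and test design

The simulation-based checks use: quadrature-oracle comparison at n = 8
(220² grid over the two variances, 100,000-iteration chain); ρ recovery on
64-tip trees, 100 replicates per true ρ in {0.1, 0.5, 0.9} at default
chains; null calibration of the adjusted correlation with 50 star-tree
replicates at n = 30; and calibration means over 100 generator seeds.
These sizes give each check enough replication for its stated tolerance
while keeping the full suite fast enough to run routinely.

## Known limitations

- Single consensus tree per fit; no posterior averaging over the tree
  sample (matching the analysis this package reproduces).
- Gaussian responses only, intercept-only fixed effects.
- The MCMC settings of the original analysis are unpublished, so its
  printed ρ and adjusted-r values can be matched only approximately even
  with the original data.
- The df = n−3 attached to adjusted correlations is reported as metadata;
  no frequentist test is performed on posterior draws.
- No REML/ML point estimator is shipped; the Bayesian fit is the single
  estimation path (an independent quadrature oracle lives in the tests).
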