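# telopace

Phylogenetic comparative analysis of telomere dynamics and longevity in
birds: do species that lose telomeres more slowly live longer — and is that
association driven by body size, or by position on the slow–fast
pace-of-life continuum?

`telopace` is aimed at comparative biologists working with per-species trait
tables (body mass, maximum lifespan, adult telomere length, and telomere
rate of change, TROC) and posterior samples of phylogenies in Newick format.
It provides:

- **Lifespan decomposition.** OLS of log₁₀ maximum lifespan on log₁₀ adult
  female body mass splits longevity into *mass-predicted lifespan* (the
  fitted values — the body-size component) and *mass-independent lifespan*
  (the residuals — lifespan at a given body size, the pace-of-life axis),
  with R², F, and Shapiro–Wilk residual diagnostics.
- **Tree handling.** Newick parsing, strict majority-rule (>50%) consensus
  with per-clade branch-length averaging, and construction of the
  phylogenetic relatedness matrix **A** (shared root-to-MRCA branch length,
  rescaled to unit height).
- **A Bayesian phylogenetic mixed model** ("animal model"), written here as
  a Gibbs sampler. For a trait *y* over *n* species:

      y = μ + a + e,   a ~ N(0, σ²ₐ·A),   e ~ N(0, σ²ₑ·I)

  Phylogenetic signal is ρ = σ²ₐ/(σ²ₐ+σ²ₑ), the proportion of among-species
  variance attributable to the phylogeny. The bivariate model uses 2×2
  covariance components Σ_P⊗A and Σ_E⊗I and reports phylogeny-adjusted
  correlations (the residual-component correlation, with the phylogenetic
  and summed-component correlations alongside), 95% HPD intervals, and
  pMCMC. Inverse-gamma / inverse-Wishart conjugate updates use the
  weakly-informative parameterisation conventional for this model family
  (V = 1, ν = 0.002 univariate; V = I, ν = 2.002 bivariate).
- **A synthetic-data generator** (Yule trees + animal-model traits with
  chosen signal and correlation structure) so every stage is testable
  without any download.
- **A CLI** (`telopace simulate|consensus|decompose|correlate|pmm|run`)
  orchestrating the full analysis into JSON/CSV/Newick reports.

## Worked example

```python
import telopace as tp

# a synthetic 30-species dataset with known generating parameters
table, tree, truth = tp.generate_birdlike_dataset(seed=1)

d = tp.decompose_lifespan(table)
print(f"R^2 = {d.r_squared:.3f}, F = {d.f_stat:.1f}, "
      f"Shapiro-Wilk W = {d.shapiro_w:.3f}")
# R^2 = 0.670, F = 56.9, Shapiro-Wilk W = 0.971

r = tp.pearson_with_inference(table["troc"], d.mass_independent)
print(f"r = {r.r:.3f}, t = {r.t_stat:.1f}, df = {r.df}, p = {r.p_value:.4f}")
# r = 0.523, t = 3.2, df = 28, p = 0.0030

A = tp.tree_to_phylo_covariance(tree, table.species)
fit = tp.fit_univariate(table["log_lifespan"], A, tp.PMMConfig(seed=2))
print(f"rho = {fit.rho_point:.3f}, HPD = ({fit.rho_hpd[0]:.3f}, {fit.rho_hpd[1]:.3f})")
# rho = 0.846, HPD = (0.526, 0.955)
```

The allometric fit says ~60% of lifespan variation tracks body mass; the
Pearson correlation says TROC co-varies with the mass-independent lifespan
component (slower telomere loss in species living long *for their size*);
and the mixed-model fit says log lifespan carries strong phylogenetic
signal, with the wide HPD typical of n = 30. A full pipeline run
(`telopace run traits.csv trees.nwk --seed 1 --out results/`) writes
`report.json`, `correlations.csv`, `signal.csv`, plot-ready
`figure_data.csv`, and the consensus tree.

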