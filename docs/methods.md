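# Methods

This note documents the statistical procedures implemented in `sealsimm`,
their assumptions, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Data model and δ notation

Isotope values are stored in δ notation (‰), δX = (R_sample/R_standard − 1) ×
1000, with R the 13C/12C or 15N/14N ratio (standards: VPDB and atmospheric
N₂).  Records are either prey (species label, muscle tissue) or consumers
(individual id, vibrissae or lanugo).  Summary statistics use the n−1 SD
everywhere; a summary with n = 1 carries NaN SDs and an explicit
"undefined" flag rather than a silent zero, so degenerate uncertainty can
never shrink a downstream variance.

Vibrissae and lanugo of newborn pups are both grown *in utero*, so their
isotope values proxy the mother's diet during gestation; lanugo maps to the
"hair" column of TEF tables.

## TEF averaging

Experimentally determined trophic enrichment factors from multiple captive
studies are combined per tissue and isotope as

- mean: sample-size-weighted mean of the study means, Σnᵢmᵢ / Σnᵢ;
- SD: pooled within-study SD, sqrt( Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1) ).

Published averaged-TEF tables in this system do not state their averaging
convention; the weighted/pooled rule above is adopted because it reproduces
all four published averaged cells (3.0±0.4 and 3.3±0.4 for vibrissae,
2.9±0.5 and 2.7±0.5 for hair) at 1-decimal rounding, whereas the unweighted
mean does not (e.g. hair δ15N would be 2.65).  Display rounding is half-up
to one decimal; all internal computation is full precision.

## Prey comparisons

Species differences use one-way ANOVA per isotope with all-pairs Tukey HSD
(studentized range on the pooled residual mean square; Tukey–Kramer at
unequal n) at α = 0.05, summarized as a compact-letter display computed by
insert-and-absorb: groups share a letter if and only if their adjusted
pairwise comparison is non-significant.  Tissue agreement uses Pearson
correlation and paired t-tests; sex comparisons use the Welch (unequal
variance) form, the safer default at unequal n since the original convention
is unstated.  Raw (untransformed) values are assumed throughout.

## Source aggregation

Ward hierarchical clustering operates on the ten species mean vectors
(δ13C mean, δ15N mean).  Each axis is standardized by the pooled
within-species SD — this is the package's reading of clustering that
"accounts for variation in both isotopes": the axes are weighted by how
reproducible each isotope is within a species, and it is the convention
under which the published six-group partition emerges exactly ({sand lance},
{longfin + shortfin squid}, {red + silver hake}, {winter flounder + winter
skate}, {thorny skate}, {cod + white hake}).  Clustering raw ‰ coordinates
does not reproduce that partition (it splits the squids), so the
standardized form is the default and only convention.  scipy's Ward linkage
is used; on these data the merge distances are distinct, and tests verify
the partition is invariant to input order and that cuts at k and k−1 are
nested.

The three-source partition (squids / sand lance / demersal fishes) is an
ecological judgement, not a dendrogram cut, and ships as a manual scheme in
`sealsimm/data/groupings.yaml`.

Group statistics pool member species exactly as if their raw samples were
concatenated: n-weighted means, and variance [Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²] /
(N−1), so results are identical whether raw records or summaries are
supplied (verified to 1e-10 in tests).

## Mixing-polygon TEF selection

For each TEF candidate, 1500 Monte Carlo iterations (the study convention)
each draw: one TEF realization per isotope, shared across sources — TEF
uncertainty is a property of the consumer tissue, not of each prey group —
and one mean per source and isotope from Normal(group mean, group SD).  The
full SD (not SE) is used by default because the procedure is meant to
propagate prey variability, not estimation error; a `source_spread="se"`
switch exposes the alternative.  Consumers are tested against the convex
hull of the adjusted draws (boundary counts as inside); the per-consumer
inside-probability is the fraction of iterations containing it.

Candidates are ranked by the number of consumers with probability ≥ 0.05
(inside the 95% mixing region — the operationalization of "fewest consumers
near the polygon's edge"), ties broken by mean inside-probability, then by
name.  A probability raster (200×200 grid over the data extent padded by
2 ‰, 5%-step contours) can be requested for plots and CSV export; it is not
computed during ranking sweeps, where it would dominate runtime without
affecting the decision.

A note on an intuitive-but-false invariant: inflating source SDs does *not*
uniformly raise inside-probabilities.  It does for consumers at or beyond
the nominal hull, but for deep-interior consumers a more variable polygon
occasionally fails to cover even its own centroid, lowering their
probability.  The tests assert the boundary form only.

## The mixing model

Likelihood per consumer j and isotope k:

    x_jk ~ Normal( Σᵢ pᵢ(μᵢₖ + λₖ),  ξₖ Σᵢ pᵢ²(σᵢₖ² + τₖ²) )

- **Error structure.**  The default (`process_plus_residual`) multiplies the
  process variance by a per-isotope residual factor ξₖ with a half-normal
  (scale 5) prior on √ξₖ — vague over the plausible 0–3 range.  This mirrors
  the multiplicative residual-error structure of modern mixing-model
  practice and lets the model widen *or tighten* the predictive variance to
  match observed consumer spread.  A process-only variant is available for
  sensitivity analysis.
- **Concentration dependence is omitted**: prey C/N ratios in this system
  are nearly uniform (≈3.0–3.2), so digestible-element weighting would be a
  no-op within measurement error.  This is a deliberate simplification.
- **No hierarchical terms**: models are population-level per tissue, fit
  separately to vibrissae and lanugo.

**Priors.**  p ~ Dirichlet(α).  Informative priors scale nonnegative diet
weights w to α = K·w/Σw (Σα = K, the number of sources), so total prior
weight matches the uninformative Dirichlet(1,…,1).  The scat-derived weights
for the three-source model are (squid 1.4, sand lance 53.3, demersal 40.6)
percent, giving α ≈ (0.044, 1.678, 1.278).

**Sampler.**  Adaptive random-walk Metropolis on z = alr(p) ∈ R^{K−1}
(softmax inverse; Jacobian Πpᵢ folded into the target) plus log √ξ.  It was
chosen for dependency-free correctness and transparency.  During burn-in
only, the proposal covariance is re-estimated from the walk at fixed
quarter-points (Haario-style adaptation — needed because the squid/sand
lance tradeoff makes the posterior strongly correlated) and a global scale
adapts toward 23.4% acceptance in windows of 50; both freeze at the end of
burn-in, so the retained chain targets the exact posterior.  The proposal is
a mixture kernel: 90% local moves and 10% five-fold-wider jumps, which lets
chains hop between the boundary spike induced by near-zero Dirichlet
concentrations (the scat prior gives squid α ≈ 0.044) and the likelihood
mode.  Even so, split-R̂ on the squid/sand-lance split of scat-prior fits
can sit slightly above the 1.05 flag — that direction is heavy-tailed on
the log-ratio scale — while the group means remain stable to within a
percentage point or two across seeds; the convergence flag is deliberately
conservative.

**Schedule.**  Default: 3 chains × 100,000 iterations, 50,000 burn-in,
thin 25 → 6,000 retained draws, a few seconds per three-source model.  This
is the package's working scale, chosen because retained-draw Monte Carlo
error on diet proportions is well below a percentage point; the original
long schedule (3 × 1,000,000 / 500,000 / thin 500) is available through the
same configuration fields.  Chains start from seeded overdispersed points;
split-R̂ is computed for every sampled parameter and any R̂ > 1.05 flags the
posterior as non-converged (a warning flag, never an exception).

**Summaries.**  Posterior mean, median, and 2.5/97.5% quantiles, ×100 for
percent display.  Both mean and median are reported because published
diet-composition tables in this system are ambiguous between the two (the
header says mean, the text says median; the printed rows sum to exactly 100,
which only means do).

## Synthetic data

Generators emulate the statistical structure the analysis assumes:

- `gen_prey`: independent normal draws per species and isotope at specified
  moments; `exact=True` affinely moment-matches each sample so summaries
  reproduce the targets exactly.
- `matched_consumers`: n standard-normal draws per isotope, moment-matched
  to the published all-pup tissue summaries (25 vibrissae / 19 lanugo;
  published sex counts).  Because the model's likelihood depends on the data
  only through n, mean, and SD, moment-matched consumers make the posterior
  essentially seed-independent — exactly the property needed to reproduce
  published posteriors from printed summaries.
- `gen_consumers`: forward draws from the mixture model at a known diet
  vector, for parameter-recovery checks.

What they do **not** emulate: within-animal isotope covariance (isotopes are
generated independently; an optional correlation hook exists in the specs
but defaults to zero because no covariances are published), tissue-growth
timelines, or non-normal tails.  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Numerical choices and degenerate inputs

- δ ratios must be positive; non-finite isotope values are rejected at
  record construction.
- Convex hulls require ≥3 distinct non-collinear points
  (`DegenerateGeometryError` otherwise); hull membership uses facet
  equations with a 1e-9 tolerance so boundary points count as inside.
- Simplex checks tolerate 1e-8 departures from Σp = 1.
- n = 1 SDs are NaN + flag; TEF averaging refuses entries lacking n.
- All stochastic entry points take seeds; `numpy.random.SeedSequence`
  expansion keeps stages and chains independent, and identical seed + config
  reproduces draws (and pipeline reports) bit-for-bit.
- Compact-letter ties are resolved by first-appearance order of the labels.

## Known limitations

- Sources enter as summary statistics; fitting hierarchical source models
  from raw prey records (which widens posteriors slightly) is not
  implemented.
- The Dirichlet-α scaling convention for informative priors is one of
  several in circulation; others (e.g. α proportional to raw percentages)
  concentrate the prior differently.
- The sampler is exact but not gradient-based; for many more than ~8 sources
  a Hamiltonian sampler would mix better.
- Mixing-polygon ranking is a geometric screen, not a goodness-of-fit test;
  it cannot detect a missing source that lies inside the polygon.
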