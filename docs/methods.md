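# Methods

`beecastes` re-implements, as a tested pipeline, a comparative analysis of
worker sub-caste evolution in Neotropical stingless bees (Meliponini):
per-species guard-vs-forager morphometrics with colony structure,
species-level derived statistics, and phylogenetically controlled
cross-species inference. This note records the models, the numerical
choices, what the synthetic data do and do not emulate, and the known
limitations.

## Morphometric layer

**Sampling design.** Workers are collected at nest entrances in two
behavioral roles: entrance guards (identified by defensive posture) and
returning foragers. The study design this package mirrors is 28 species,
2–8 colonies per species, and roughly 70 workers per species. Head width
(mm) is the size trait; wet weight (mg) enters only the allometry analysis
because crop contents confound it as a size measure.

**Guard-vs-forager tests.** Within a species, workers from the same colony
are correlated, so the role contrast is a Gaussian random-intercept model
`head_width ~ role + (1 | colony)` fitted by REML (statsmodels `MixedLM`).
For repeated measures per bee (cuticle thickness), bee nested within
colony enters as a second variance component. The t statistic is
estimate/SE with containment degrees of freedom `N − n_colonies − 1`; this
convention is always reported with the fit and is not claimed to equal any
other software's df. A single-colony species degrades to a two-sample
t-test with an explicit fallback flag. Across the per-species tests,
p-values are Benjamini–Hochberg adjusted table-wide in two families (the
28 guard tests; the up-to-24 allometry tests); the three melanization
tests form their own small Bonferroni family, with raw p-values also
emitted.

**Derived statistics.**

- Corrected CV: `(1 + 1/(4n)) · sd/mean` per colony, averaged over
  colonies. The small-sample factor `(1 + 1/(4n))` is the standard
  correction; it tends to 1 as n grows.
- Differentiation index (DI): per colony,
  `|mean(guard) − mean(forager)| / sd(all workers of the colony)`,
  averaged over colonies. DI = 1 means the role gap equals one
  within-colony standard deviation. The denominator pools both roles;
  this is one of two defensible readings of "overall standard deviation
  in a colony" and is recorded here as the package's choice.
  Note the estimator is a folded quantity: under no differentiation its
  expectation is not 0 but `sqrt(2/π)·sqrt(1/n_g + 1/n_f)` (≈ 0.16 at
  50 bees per role), which matches the floor of DI values observed for
  clearly undifferentiated species in the published table (0.10–0.24).
- Melanization: `m = 1 − g/r` from the mean clypeus gray `g` and the
  white-background reference `r`; higher is darker.
- Allometry: reduced major axis (model II) regression of log10 head width
  on log10 cube-root weight. Slope `b = sign(r)·sd_y/sd_x`,
  `SE = |b|·sqrt((1−r²)/(n−2))`, two-sided t test of the isometry null
  b = 1 on n−2 df. Negative allometry = (b < 1 and adjusted p ≤ α):
  larger workers have relatively smaller heads. At exact perfect
  correlation the t statistic is defined as 0 when b = 1 and ±∞
  otherwise.
- Species flag "guards of increased size" requires both adjusted p ≤ α
  (α = 0.05, inclusive) and guard mean > forager mean, so a species with
  significantly smaller guards is never flagged.

## Phylogenetic layer

All tree work assumes a rooted chronogram with branch lengths in millions
of years. Zero-length branches are floored at 1e-6 my before any
likelihood computation, which keeps transition matrices non-singular while
honoring near-zero divergence scenarios.

- **Brownian VCV / PGLS.** `vcv_matrix` returns shared root-to-MRCA path
  lengths. PGLS uses the GLS estimator `(XᵀV⁻¹X)⁻¹XᵀV⁻¹y` via Cholesky
  whitening, t tests on n − p df, and R² = 1 − RSS/RSS₀ in the whitened
  space with an intercept-only GLS baseline (guaranteeing [0, 1]).
  Continuous traits are natural-log transformed by the pipeline before
  PGLS; t statistics are invariant to the log base.
- **PIC.** Felsenstein's contrasts with branch-length inflation
  `b + b_i·b_j/(b_i+b_j)`; polytomies must be resolved first (a helper
  resolves them arbitrarily with zero-length branches and logs the fact).
  Regression through the origin on contrasts reproduces the PGLS slope to
  1e-8 on every bifurcating tree — the suite asserts this identity, and
  both R² flavors (PIC-origin and whitened GLS) are reported because
  either could stand behind a published "variance explained" figure.
- **Parsimony.** Minimum state changes by unit-cost Sankoff dynamic
  programming (equals Fitch on bifurcating trees, exact on polytomies).
- **Mk1.** One-rate symmetric binary Markov model. The profile
  log-likelihood is flat for large rates (tip states then look i.i.d.
  uniform), which traps naive bounded searches on the plateau; the rate
  is therefore bracketed on a 41-point log grid over [1e-8, 100] before
  bounded Brent refinement (tolerance 1e-8). Invariant characters are
  reported at the lower bound with a degeneracy flag. Marginal ancestral
  probabilities come from the standard up-down (inside–outside)
  algorithm; the root prior is equal by default, stationary optional.
- **Stochastic mapping.** Histories conditional on tip states are drawn
  exactly: node states root-to-tips from the conditional distributions
  implied by the pruning partials, then branch paths by rejection
  sampling conditional on endpoints (budget 10,000 tries per branch).
  When endpoints differ, the first jump time is drawn from the
  exponential truncated to the branch — still an exact draw, but short
  discordant branches no longer exhaust the budget. The mapping rate is
  the Mk1 ML estimate unless supplied. Summaries: per-branch
  time-weighted state-1 density, per-node posterior, and the posterior
  distribution of 0→1 origin counts.
- **Pagel's correlated-evolution test.** Joint 4-state chain on (A,B)
  with double transitions forbidden. The independent model's likelihood
  factorizes into two asymmetric 2-state fits (4 free rates total); the
  dependent model frees all 8 context-specific rates. ML by multi-start
  L-BFGS-B on log rates (bounds e⁻²⁰–e⁵, default 5 starts, log-spaced
  random initials), with the independent optimum embedded as one start so
  LRT ≥ 0 up to tolerance. The optimizer evaluates the objective and its
  forward-difference gradient in one batched tree sweep
  (`pruning_loglik_batch`), which is what makes the calibration studies
  tractable. LRT is referred to χ² with 4 df.

**Calibration caveat (important).** On trees of this size (28 tips) the
χ²₄ reference for Pagel's LRT is conservative: simulating under the
independent model fitted to the packaged data and refitting both models
rejects at the 5% χ² cut in well under 5% of replicates (and the null LRT
95th percentile sits around 7–8 vs the χ² critical value 9.49). The test
therefore under-rejects rather than over-rejects here; published
borderline p-values from this test should be read accordingly. Power
against dependent alternatives at 28 tips is correspondingly modest. The
acceptance suite measures both and asserts the nominal bands, so the
calibration checks document this property rather than hide it.

## Synthetic data

Generators produce every input with known ground truth:

- **Colony datasets.** Head widths = colony intercept (Gaussian, sd 0.03
  mm) + role mean + within-colony noise (forager CV 0.02 at a 2 mm
  forager mean). The guard offset is solved in closed form so the
  constructed population DI equals the requested target
  (`delta = DI·s/sqrt(1 − DI²·p_f·p_g)`); bimodal species draw guards
  from a separate narrower mode, unimodal species shift the mean only.
  Role counts are max(2, Poisson(target)) with defaults (4 colonies,
  8 guards + 10 foragers per colony) matching the study's sampling scale.
  Weights follow `head_width^(3/b)·10^ε`; because the noise ε sits on
  weight only, the realized RMA slope is attenuated to
  `b/sqrt(1 + b²σ_ε²/(9·sd_y²))` — a property of model II regression
  worth remembering when choosing σ_ε.
- **Continuous traits.** Brownian motion by recursive Gaussian
  increments; tip covariance equals σ²·VCV (asserted against simulation).
- **Binary trait pairs.** Forward CTMC simulation of the joint 4-state
  chain (independent or dependent rates); constant draws are resampled up
  to 50 times and flagged if exhaustion occurs.

What the generators do **not** emulate: measurement error on individual
bees, non-Gaussian size distributions, unequal catchability of guards vs
foragers, pollen load effects on weight, and any real geographic or
colony-age structure. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
field realities.

## The packaged study fixture

The species-level summary table ships as a CSV transcription (checksummed
at load). Because neither the raw measurements nor the pruned reference
chronogram are published, the fixture tree is **synthetic**: a hand-built
genus-level topology consistent with the clade statements in the source
(Plebeia sister to the Tetragonisca pair; Lestrimelitta adjacent to
Frieseomelitta; the two robber-bee-target Frieseomelitta species as
sisters within the genus, whose internal resolution the reference
phylogeny left open), with within-genus divergences settable (2 my
default, near-zero alternative for the robustness comparison) and node
ages chosen so the packaged analysis reproduces the published
reconstruction's qualitative behavior: five parsimony origins of
increased guard size, a stochastic-map origin-count mode of 5, and a
dependent-model preference with a higher soldier-gain rate in target
lineages. Exact likelihood ratios, t statistics and origin posteriors on
this tree are fixture-dependent and are reported as such, never asserted
equal to the published values.

## Problem sizes

Simulation studies in the tests use the sizes stated with each check:
500 replicates for the type-I calibration, 200 for power/recovery checks,
10,000 histories for the mapping-vs-marginals comparison, 1,000 histories
for fixture mapping, 6 colonies × 50 bees per role for DI recovery. These
are the package's chosen desk-scale study conditions.

## Known limitations

- The LME df convention (containment) will not reproduce another
  package's denominator df; t and p values are reported under the stated
  convention only.
- Pagel's test here supports exactly two observed states per trait;
  branch-length transformations (λ, κ, δ) and OU covariance models are
  out of scope.
- The stochastic-map sampler is exact but rejection-based; pathological
  rate/branch combinations fail loudly with the branch named rather than
  silently degrading.
- The fixture tree is one plausible chronogram, not the published one;
  conclusions that depend on exact branch lengths (likelihood ratios,
  origin posteriors) transfer only qualitatively.
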