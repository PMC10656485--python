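# Methods

## The model

`bracedate` estimates absolute node ages (Ma before present) on a fixed,
rooted, strictly bifurcating topology. The data are not sequences but a
posterior sample of trees with branch lengths in expected
substitutions/site on that topology — typically the output of a Bayesian
phylogenetics run. The joint posterior over node ages `t`, branch rates
`r`, and hyperparameters is

```
log p(t, r, θ | X)  =  log L̃(X | t, r)           (approximate likelihood)
                     + log p_BD(t | t_root)       (birth–death node-age prior)
                     + log p_UCLN(r | μ_r, σ_r)   (relaxed clock)
                     + log p(μ_r, σ_r)            (hyperpriors)
                     + Σ log c_i(t)               (calibrations)
                     + Σ log b_j(t)               (braces)
                     + Σ log o_k(t)               (relative constraints)
```

### Approximate likelihood

The branch-length sample is summarised once by its mean vector `m` and
covariance `Σ` (full or diagonal), and the likelihood of a proposed state
is the Gaussian density of the model-implied lengths `x_b = r_b·Δt_b`:

```
log L̃ = −½ [(x−m)ᵀ Σ⁻¹ (x−m) + ln det(2πΣ)]
```

Because reversible substitution models cannot place the root, the two
root-incident branches are only identifiable through their sum; the
observed space merges them into one coordinate and the time-tree side
contributes `r_a·Δt_a + r_c·Δt_c`. The covariance is fitted on raw
(untransformed) lengths; a ridge of `1e-8 × mean(diag Σ)` is always added
so the Cholesky factorisation succeeds even for degenerate samples.
Whether full or diagonal covariance is preferable depends on tree size
and sample size; `full` is the default, `diagonal` is provided for large
trees where the sample covariance is rank-deficient or expensive.

### Priors and soft constraints

* **Birth–death**: conditional on the root age and the tip count, the
  non-root internal ages are iid with density `g(t) ∝ p₁(t) =
  a² e^{−a t}/(λ − μ e^{−a t})²`, `a = λ−μ`, on `(0, t_root)`, times the
  order-statistics factor `(n−2)!`. The normaliser reduces to
  `(1−e^{−a t})/(λ − μ e^{−a t})`, a cancellation-free form valid down to
  `μ = 0`. The root age itself carries no birth–death density; it must be
  governed by a calibration with a finite maximum (every analysis here is
  anchored by a root maximum). Defaults `λ = 1.0/Ga`, `μ = 0.5/Ga`,
  complete sampling (`ρ = 1`), fixed; an option samples them under
  log-uniform priors.
* **Relaxed clock (UCLN)**: per-branch rates iid log-normal,
  mean-parameterised (location `ln μ_r − σ_r²/2`, scale `σ_r`) so that
  `E[r_b] = μ_r` in substitutions/site/Ma. `σ_r = 0` is the strict clock.
* **Calibrations**: log density 0 on the plateau `[a, b]`, Gaussian tails
  `−(Δ)²/(2s²)` beyond each present boundary ("bisected normal"
  boundaries). Steepness is per-calibration; when a config omits it, the
  default is 2.5% of the boundary age — soft enough to absorb honest
  uncertainty, hard enough that a few steepness units are decisive.
  Multiple calibrations on one node multiply (their logs add).
* **Braces**: `Σ_{k≥2} −(t_k − t_1)²/(2σ_brace²)` anchored to the
  first-listed node. Anchoring costs O(members) and, as `σ_brace → 0`,
  converges to the same hard age-identity constraint as pairwise or
  deviation-from-mean variants. The default `σ_brace` is `1e-3 ×` the
  root-calibration maximum — effectively hard on the analysis scale.
* **Relative (older-than) constraints**: 0 when the order holds, a
  Gaussian tail on the violation otherwise.
* **Hyperpriors**: `μ_r` log-uniform on `[1e-6, 1e-1]` subst/site/Ma
  (spanning every plausible deep-time protein rate), `σ_r ~ Exp(1)`.

All soft penalties are continuous at their boundaries and monotone in
the violation, so the posterior is continuous and any `−∞` arises only
from hard support violations (tree ordering, hyperparameter bounds).

## The sampler

Metropolis–Hastings with seven move classes: (1) node-age slide,
reflected inside (oldest child, parent) so the proposal stays symmetric;
(2) root-age multiplier; (3) subtree age scaling (Jacobian `c^k` for `k`
scaled nodes); (4) single-branch rate multiplier; (5) log random walks on
`μ_r`, `σ_r`; (6) a global rate–age compensator (`t×c`, `r/c`, `μ_r/c`)
that travels along the rate–time non-identifiability ridge; and (7)
likelihood-invariant exchanges — a node age (or the root age) moves while
the rates of its adjacent branches are rescaled to keep every implied
length `r_b·Δt_b` exactly fixed, with Jacobian `Π(Δt_old/Δt_new)`.
Class (7) is what makes the chain mix when the branch-length posterior is
tight: pure age moves are then confined to steps of order the likelihood
width, while exchanges let ages move at the scale of the priors. Proposal
windows adapt toward a 20–50% acceptance rate during burn-in only and are
frozen afterwards, keeping the retained chain Markovian. All randomness
flows from one seeded generator; identical configuration and seed give
byte-identical traces.

Initialisation builds a feasible chronogram (internal ages proportional
to descendant tip counts, root at 90% of its calibrated maximum span) and
jitters on the rare occasion the resulting state has zero density.

Defaults: 120,000 iterations, 25% burn-in, thinning chosen so at most
12,000 samples are retained.

### Diagnostics and summaries

* **ESS**: `n / (1 + 2Σρ̂_k)` with Geyer's initial positive/monotone
  pair-sum truncation of the FFT autocorrelations; a constant series
  returns 1 by convention. Cross-checked against `arviz.ess` in the test
  suite.
* **HPD**: shortest contiguous window of the sorted sample containing
  `⌈level·n⌉` points; both bounds are sample members.
* **Derived comparisons**: per-sample node-age differences (stem lengths)
  summarised as mean and HPD; and a braced-vs-unbraced rate comparison as
  a paired Z-test across branches on posterior-mean rates,
  `Z = d̄√B / s_d`. The pairing-across-branches construction is one
  defensible definition of such a test and is labelled as such in
  reports.

## Cross-brace discovery

Given a tip → (species, copy) map, every internal node of each copy
subtree is keyed by its descendant species set intersected with the
species shared by all copies; nodes in different copies with the same key
mark the same speciation event and are braced. Intersection keys make the
matching robust to asymmetric taxon loss between copies; a strict mode
requires exact species-set equality. Only groups with ≥2 members and ≥2
species are emitted, deterministically ordered. Automated discovery is an
extension of the practice of hand-selecting equivalent nodes; an optional
scope (e.g. "within eukaryotes") restricts which nodes are braced.

## The synthetic generator

`simulate_time_tree` draws the non-root internal ages directly from the
conditioned birth–death density by analytic inverse CDF and joins
lineages youngest-first — by construction, exactly the distribution the
birth–death prior assigns conditional on root age and tip count. A
forward simulation with rejection on the tip count and rescaling to the
target root age was considered and rejected: rescaling distorts the age
density, breaking the distributional identity between generator and
prior that the recovery tests rely on. `simulate_ucln_rates` mirrors the
clock prior. `simulate_branch_sample` multiplies each true length
`r_b·Δt_b` by iid Gamma(shape `1/cv²`, mean 1) noise — independent noise
makes the moment oracles exact; a correlated mode (one shared factor per
tree) mimics the across-branch correlation of real posterior samples.
`make_duplicated_gene_tree` replicates a dated species tree under a
pre-root duplication, giving ground-truth equivalent nodes for brace
tests.

What the generator does *not* emulate: per-site likelihood peculiarities
(the noise is Gamma, not a true posterior), correlated branch-length
errors (unless the correlated flag is set), topology error, serially
sampled tips, or incomplete lineage sampling (`ρ < 1`). Passing recovery
tests therefore demonstrates the correctness of the dating machinery
under its own model, not robustness to model misspecification.

## Validation experiment conditions

The experiment drivers (`bracedate.experiments`) fix these study
conditions:

* **Recovery**: 16 tips, root 4000 Ma, `λ=1.0/Ga`, `μ=0.5/Ga`, UCLN mean
  2.6e-4 subst/site/Ma (the magnitude typical of deep-time ribosomal
  datasets) with σ=0.3, 1000-tree pseudo-posterior at cv=0.05; root
  calibration ±10% and three internal calibrations ±15% around the truth,
  steepness 2.5% of each boundary; 50,000 iterations. Pooled 95% HPD
  coverage over 20 seeds is the headline check.
* **Brace propagation**: 6-species tree (root 1500 Ma) duplicated under
  a 4500 Ma paralog split — long stems below each replica, the geometry
  of a pre-divergence gene duplication; cv=0.1, `λ=0.25/Ga`,
  `μ=0.125/Ga`; calibrations on copy 1 only; braces discovered
  automatically with the default σ_brace. Matched seeds, braced vs
  unbraced. Measures: twin mean-age agreement, copy-2 HPD widths, mean
  inferred rate, and the paired rate Z.
* **Root clash**: 8 tips, rate identified by three cherry calibrations
  only, root maximum at 87.5% of the true root age with 2.5% steepness.
  The posterior mean settles below the maximum while the interval's upper
  edge presses into the boundary zone. A note on geometry: for any
  posterior pressed against a soft maximum, the upper 95% HPD bound lands
  about two steepness units into the tail (the over-boundary layer has
  width ≈ s and the bound is near that layer's upper quantile), so
  "the interval reaches the maximum" is the robust statement, while the
  bound-to-maximum distance scales with s rather than vanishing.

Problem sizes (tips, iterations, seed counts) were chosen so the full
validation battery completes in minutes on one CPU while keeping ≥300
node-instances in the pooled coverage check.

## Numerical choices and degenerate inputs

* Cholesky factors are cached per fitted approximation; the sampler
  additionally precomputes the precision matrix once.
* Zero-length branches in the input sample are kept as-is (the Gaussian
  tolerates zeros); multifurcations and top-level trifurcations are
  rejected at parse time rather than resolved arbitrarily.
* Branch identity across a tree sample is by tip-label bipartitions, not
  file node order, so samples written by different programs map onto one
  index space; parsing is canonical (children ordered by smallest
  descendant label, post-order numbering) and deterministic.
* Ties in HPD window search resolve to the first (lowest) window;
  constant series short-circuit to ESS 1 and zero-width HPDs.
* All tips are assumed contemporaneous (age 0); ages are Ma before
  present (values on the Ga scale are a presentation concern).

## Known limitations

* No per-site likelihood: accuracy is bounded by how well a Gaussian
  describes the branch-length posterior (long-tailed posteriors for very
  short branches are summarised only through mean and covariance).
* No fossilized birth–death, serial tips, skyline models, or topology
  search; the topology is fixed throughout.
* The rate Z-test definition (paired across branches) is one reading of
  such a statistic; alternatives (per-sample pairing) would give
  different magnitudes.
* Single chain per seed; between-chain diagnostics (R̂) are not computed —
  ESS is the convergence criterion.
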