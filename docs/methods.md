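# Methods

## Model

`varcallxt` classifies missense variants by a Bayesian hierarchical model
whose first level is a mixed-effects regression on within-batch mean
log-ratios and whose second level is a semi-supervised two-component
Gaussian classification model:

- observation: `y_vb = theta_v + beta_b + eps_vb`, `eps_vb ~ N(0, sigma_e²)`;
- batch effects: `beta_b ~ N(0, sigma_b²)`;
- variant effects: `theta_v | D_v = d ~ N(mu_d, tau_d²)`, with `d = 1`
  meaning damaging/pathogenic;
- indicators: `D_v ~ Bernoulli(pi)` a priori; frozen at the label for
  control variants, inferred for VUS.

The response is the *within-batch replicate mean*, computed by
`average_within_batch` with a plain arithmetic mean.  Batch-mean
observations are equally weighted regardless of the replicate count behind
them; consequently the model's residual variance `sigma_e²` is the variance
of a batch mean (for a fixed replicate count `r` it equals the
replicate-level variance divided by `r`).  An `n_replicates` column is
carried through the tables for provenance but does not weight the default
likelihood.

Optional per-variant evidence multiplies the full conditional of `D_v`:

- **family data**: one aggregated log Bayes factor per variant, contributing
  `exp(d · logBF)`;
- **Align-GVGD**: a pathogenicity probability converted to a log Bayes
  factor under a configurable reference prior (default 0.5, a config field
  because the prior under which those probabilities were produced is
  external to this package); probabilities of exactly 0/1 are clipped to
  `[1e-4, 1 - 1e-4]` with a warning.  Interval bounds are carried through
  I/O; an optional helper converts them to a Gaussian log-BF SD
  (`(logit(hi) - logit(lo))/3.92`) but the default likelihood uses the point
  estimate only;
- **predictor PCs**: independent Gaussians per component with class-specific
  means and a pooled per-PC variance.  A full class-specific covariance over
  10 PCs would be unstable with tens of labeled variants, hence the pooled
  diagonal form.

Missing evidence contributes a factor of 1 (the term is omitted); nothing is
imputed inside the model.

## Priors and identifiability

Component-mean hyperpriors default to `N(m_d, (10 s_d)²)` where `m_d`/`s_d`
are the mean/SD of the labeled class's per-variant average response — weakly
informative and centered on the controls.  All variances carry
inverse-gamma(0.01, 0.01) priors; the prevalence `pi` a Beta(1, 1).  Every
hyperparameter is overridable via `ModelConfig`, and any of
`mu, tau2, sigma_b2, sigma_e2, pi, pc_means, pc_var` can be fixed at point
masses (used by the exact-oracle tests).

Two choices guard identifiability:

- the mixture is anchored by the frozen control labels; in addition an
  ordering guard on `(mu0, mu1)` — direction taken from the labeled-control
  means — rejects mean draws that would swap the components (relevant only
  when controls are very few; the guard logs when it engages);
- the prevalence `pi` is updated from the *unlabeled* indicators only.  The
  controls are chosen by study design rather than sampled from the VUS
  population, so their class split carries no information about the VUS
  prevalence.  This also makes the simulation-based calibration of `pi`
  exact.

## Sampler

Inference is blocked Gibbs with conjugate updates.  Two non-obvious moves:

- `D_v` is sampled with `theta_v` integrated out in closed form given the
  batch effects (the within-variant residual mean is
  `N(mu_d, tau_d² + sigma_e²/n_v)` under class `d`), then `theta_v` is
  redrawn given the new `D_v`.  This joint (D, theta) block removes the
  slow mixing a conditional-on-theta update would have.
- The likelihood constrains only `theta_v + beta_b`, so the common level of
  the two effect vectors is weakly identified through the `beta` prior and
  random-walks under one-at-a-time updates.  A translation-group move
  resamples the shift `(theta + c, beta − c)` directly from its Gaussian
  conditional each iteration, which restores good mixing of `mu0`/`mu1`.

Defaults are 4 chains × 20,000 iterations with 10,000 burn-in and thinning
5; the tests and acceptance runs use 1–2 chains × 800–22,000 iterations
because the collapsed sampler mixes quickly at those problem sizes (split-R̂
≈ 1.00 on all scalar parameters at 2 × 1,000 retained draws on the small
preset).  Convergence is flagged when split-chain R̂ exceeds 1.01 on any
scalar parameter (computed via ArviZ).  A single seed reproduces draws
bit-identically; chains derive independent streams from spawned seed
sequences.

Posterior probabilities are the post-burn-in mean of the `D_v` draws.
Before the logit transform for reported log-odds they are clipped to
`[1/(M+1), M/(M+1)]` (`M` retained draws) so log-odds stay finite; the
reported probability itself is unclipped.  Calls use
`prob < 0.05` → benign, `prob ≥ 0.99` (inclusive) → pathogenic, else
no-call.

Degenerate inputs: a class with no labeled variants while functional data
are present raises an identifiability error (unless the component means are
supplied or fixed); a non-finite full conditional aborts with a state dump;
probabilities outside [0, 1] passed to `classify` raise.

## Evaluation

- **LOVO**: each labeled variant is unlabeled in turn and the model refit;
  refits warm-start from the full fit's final chain states (burn-in is still
  discarded, so only the initialization — not the stationary distribution —
  changes).  Folds that would empty a class are skipped with a warning and
  flagged in the output.
- **Dirichlet-multinomial**: three call categories per condition with
  Jeffreys prior Dirichlet(1/2, 1/2, 1/2); posterior category mean
  `(count + 1/2)/(n + 3/2)`, reported as percent.
- **HDR**: the category marginal is Beta(count + 1/2, n − count + 1),
  the exact marginal of the Dirichlet posterior.  Interior-mode densities
  get the narrowest interval of the requested mass by minimizing
  `ppf(F(lo) + mass) − lo` over the left endpoint; monotone densities (a
  shape parameter ≤ 1) get boundary-attached one-sided intervals — this is
  what produces intervals such as (87, 100) for a sensitivity marginal of
  Beta(21.5, 1), whose lower bound is the closed form `0.05^(1/21.5)`.
- **Raw accuracy**: correct calls over all known variants, with no-calls
  counted as errors.
- **Scaled Brier**: mean squared error of the predicted probabilities
  divided by the Brier score of the constant prevalence predictor
  `p̄(1 − p̄)`.  This is the one "scaled" variant consistent with published
  values exceeding 1 (an anti-calibrated predictor is worse than ignoring
  the data).  If all labels are identical the reference is undefined and the
  unscaled score is returned with a warning.
- **Odds shifts**: per-variant `odds_B/odds_A` between two fits plus call
  transitions and per-class geometric means.  Note the log-odds of variants
  at probability 0 or 1 are clipped (above), so odds ratios between two
  saturated fits equal 1 by construction.

## Synthetic data

`simulate_dataset` draws from exactly the generative structure above:
mixture-distributed variant effects, Gaussian batch effects, replicate
noise, independent Bernoulli batch-occupancy masks with control variants
forced into every batch (every variant is guaranteed ≥ 1 observation), PC
scores from class-conditional Gaussians separated by `pc_effect` per
dimension, family log-BFs as `N(±scale, scale)` with the sign set by the
true class for a coverage-limited subset, and Align-GVGD probabilities as
logistic-transformed noisy copies of the true indicator.  Everything is
deterministic given the seed.

Default generating values are chosen to look like a well-calibrated
reporter assay: benign variants centered at log-ratio 0 (wild-type-like,
SD 0.3), damaging variants shifted to −2.5 (activity loss, SD 0.6 — the
damaging class is more heterogeneous), batch SD 0.3, replicate noise SD
0.4, three replicates per occupied cell, and a 30% prevalence of pathogenic
variants among VUS.  Presets:

- `small` — 60 labeled variants (29 + 29 plus the two always-present
  controls), 150 VUS, 30 batches at 20% occupancy; sized for
  parameter-recovery studies;
- `brca1_ta` — 42/21 labeled + 281 VUS + 2 controls in 126 batches at 2.07%
  occupancy with 3 replicates (≈ 3,450 replicate rows);
- `brca2_hr` — 22/11 labeled + 168 VUS + 2 controls in 162 batches at 1.66%
  occupancy with 2–3 replicates.

What the generator does **not** emulate: hypomorphic variants with
intermediate effects (the indicator is binary by assumption), non-Gaussian
assay artifacts, correlated predictor PCs within a class, per-family
pedigree structure behind the family Bayes factors, or any dependence
between evidence sources given the true class.  Passing recovery tests
therefore demonstrate correctness of the inference under the model's own
assumptions — not robustness to their violation on real data.

`recovery_experiment` runs repeated simulate → fit cycles and reports the
MAE of `Pr(pathogenic)` against the true indicators among the unlabeled
variants plus central-95% interval coverage for each generating parameter.
LOVO-against-truth tallies are behind an `include_lovo` flag (default off:
one refit per labeled variant per replicate multiplies cost ~60-fold).

## Problem sizes used by the test and acceptance runs

The exact-oracle checks use a 3-variant, 2-batch instance with point-mass
hyperparameters, where the posterior over the unlabeled indicators is
computable by enumeration with theta and beta integrated out analytically.
Recovery uses the `small` preset with 20 replicates at 2 chains × 1,600
iterations (800 burn-in), which recovers all seven generating parameters
with 85–100% interval coverage and MAE ≤ 0.015.  These sizes were chosen so
the full study runs comfortably on a single CPU while keeping Monte-Carlo
error an order of magnitude below every tolerance tested.

## I/O conventions

TSV/CSV dialect is inferred from the extension and overridable; missing
values are empty strings (or "NA") on read and empty strings on write;
labels are normalized through a configurable alias map (e.g. IARC classes
1/2 → benign control, 4/5 → pathogenic control); variant identifiers are
opaque strings.  Batches with no control variants are accepted; their batch
effects are exchangeable draws from the `N(0, sigma_b²)` prior like any
other.  Outputs are written with 6 significant digits.
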