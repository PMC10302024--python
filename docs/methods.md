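# Methods

This note records the models, conventions and numerical choices behind
`toxmetnet`, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute themselves.

## 1. Synthetic cohort model

Intensities are log-normal: for sample *i* and feature *j*,

    log X_ij = mu_j + kappa_j z_i + lambda_j h_i + offset_j g_i + eps_ij

* `mu_j ~ N(baseline_log_mean, baseline_log_sd^2)` — feature baselines
  (defaults 13.8 and 1.5 on the natural-log scale, i.e. median intensities
  around 10^6 spanning roughly two decades, typical of profiling data).
* `z_i` — latent injury score; normal with mean 0 (CON) or
  `injury_separation` (DOX) and within-group sd 1. The default separation
  of 6 produces treated-group serum ALT around 2.8× control with clearly
  non-overlapping groups, the regime in which targeted panels at n = 5–6
  per group yield p < 0.001 for fold changes near 0.55.
* `kappa_j = log(FC_j) / injury_separation` for planted biomarkers under
  marker coupling, so the group difference of mean log intensity is exactly
  log FC_j. Without marker coupling the same fold change is applied as a
  plain group offset (`offset_j`).
* `h_i` — latent hub factor, independent of `z`. The hub metabolite loads
  at correlation r_h = 0.98 (or sqrt(rho) if larger), partners at
  r_p = rho / r_h, giving hub–partner correlation rho and partner–partner
  correlation rho^2·(r_h is near 1), the minimum any single shared factor
  permits. Hub features have total log-sd `hub_log_sd` (default 0.3).
* `eps_ij` — independent noise, sd `noise_log_sd` (default 0.2, ~20% CV)
  for unstructured features; for planted biomarkers the residual sd is
  *calibrated* (below).

Serum markers are affine in the injury score,
`ALT = 100 + 30 z + N(0, tau^2)` (AST: 120 + 35 z), in arbitrary units on
a U/L-like scale. QC samples are the raw-scale per-feature mean of the
study samples times log-normal noise at one fifth of the empirical
per-feature study log-sd, emulating pooled aliquots re-injected on a stable
instrument. The internal standard has 2% CV and is never missing. Missing
cells are MCAR at rate `missing_rate`, with doubled dropout probability in
the lowest intensity decile (a light detection-limit proxy).

### Marker-coupling calibration

The generator guarantees that the population Pearson correlation between
each planted biomarker's raw intensity and ALT equals the requested
magnitude (sign following the fold-change direction). Because
`X = exp(L)` with `L` a normal given the group, all moments of the
log-normal mixture are closed-form, and

    corr(X_j, ALT) = corr(X_j, z) * corr(z, ALT)

since ALT couples to X_j only through z. The calibration therefore:

1. computes each biomarker's maximum attainable `c_j = |corr(X_j, z)|`
   (residual noise 0; any hub-factor variance counts as irreducible noise);
2. sets a common `c* = 0.999 * min_j c_j` and solves each biomarker's
   residual variance by root-finding so that `|corr(X_j, z)| = c*` exactly;
3. sets the marker noise `tau` so that `corr(z, ALT) = |r_target| / c*`.

Targets exceeding `c*` raise an error rather than silently attenuating.
A consequence worth knowing: biomarkers carrying strong marker coupling are
necessarily low-noise features — exactly as in real data, where |r| ≈ 0.9
against ALT is only observable when technical noise is small relative to
injury-driven biological variance.

### Targeted panel

Panel concentrations preserve the true fold change and the injury coupling:
`C_ij = base_j · FC_j^[i in DOX] · u_ij / mean_group(u) · eta_ij` where
`u_ij = exp(kappa_j w_i)` (w the within-group injury component) and `eta`
is mean-one log-normal noise with the requested CV. Dividing by the group
mean of `u` makes the group-mean ratio equal FC exactly when CV = 0, at the
cost of a (small, O(1/n)) empirical renormalisation of the coupling term.

### What the generator does not emulate

No retention-time drift, batch effects, chromatographic peak shapes, or
spectra; no between-feature correlation beyond the planted hub and the
shared injury factor; missingness is not a true censoring process. A green
test therefore establishes correctness of the statistical pipeline under
the stated model, not robustness to instrument artefacts.

## 2. Preprocessing conventions

* Half-minimum imputation per feature; features missing in more than
  `max_missing_fraction` (default 0.5) of study samples are dropped;
  features missing everywhere are dropped with a warning, never imputed.
* Default normalization is internal-standard when the table declares one,
  else total-sum (row/sum × median row sum). Total-sum's median rescale is
  exactly invariant to a single-sample distortion only when the median row
  sum is unchanged; the per-sample *profile* is always invariant.
* Default scaling is UV without log2, matching the defaults of the
  multivariate tool family this pipeline emulates; fold changes are always
  computed on normalized, unscaled intensities because scaling destroys
  ratio meaning.
* QC samples never enter group statistics, model fits, or scaling recipes
  used for modelling; they exist only for stability assessment.

## 3. Chemometrics

* One predictive component (a binary response identifies only one);
  orthogonal components via the deflation loop, added while Q² improves by
  ≥ 0.01, capped at 5. The deflation stops early (with a warning) if no
  orthogonal variation remains.
* Cross-validation is stratified k-fold with deterministic fold assignment
  from the seed; the requested 7 folds are reduced to the smaller group
  size when necessary (e.g. 6 at n = 6+6). Training folds are re-centered;
  test samples are projected through the training orthogonal filter.
* Sign convention: the predictive score is positively associated with the
  second group label in sorted order (DOX when labels are CON/DOX).
* VIP uses the predictive weights only, keeping mean(VIP²) = 1 exact.
* Degenerate cases: zero-variance features must be removed by scaling
  before the fit; a vanishing Xᵀy raises.
* The permutation diagnostic refits with the observed model's orthogonal
  component count and reports (1 + #{null Q² ≥ observed}) / (n_perm + 1).

## 4. Network stage

* SCC is the Pearson correlation of average ranks; p-values use the
  t-approximation with n−2 df (exact permutation p-values are out of
  scope). Constant metabolites are excluded from edge ranking, with a
  warning.
* Top-K selection sorts by |rho| with a deterministic lexicographic
  tie-break on the sorted name pair. Density counts only incident nodes —
  under the all-metabolites reading density would increase monotonically in
  K and the density scan would be vacuous.
* Both cutoff modes are exposed: fixed K = 30 (the default) and the
  density-scan argmin over K ∈ {10, …, 80}; the scan table is always
  emitted so the two can be compared.
* Eigenvector centrality: power iteration from the all-ones vector,
  convergence at 1e-10 in L2 after normalization, max 10 000 iterations.
  Bipartite dominant components (e.g. perfect stars) make plain power
  iteration oscillate indefinitely, so on non-convergence the iteration
  restarts from 1 + 1e-3·degree on A + I, which has the same eigenvectors
  with a strictly dominant leading eigenvalue. Scores are rescaled to
  max 1; nodes below 1e-6 are flagged as outside the dominant component.
* A known statistical limitation, documented rather than hidden: when a hub
  and its partners form a near-complete clique in the top-K graph (which
  the single-factor hub model guarantees at realistic K), unweighted
  eigenvector centrality ranks hub and full-degree partners almost
  identically, and at n ≈ 12 pooled samples the sampling noise of rank
  correlations (sd ≈ 0.15) frequently promotes a partner above the hub.
  The |rho|-weighted variant (`weighted_ec`) discriminates better but
  cannot beat the information limit of 12 samples.

## 5. Validation stage

Fold change and equal-variance t-tests on raw absolute concentrations
(panel data are quantitative, unlike profiling intensities); Pearson
correlations against ALT/AST over pooled CON+DOX samples (per-group
correlations behind a flag). Pairs with missing values are dropped
pairwise-complete; fewer than 4 complete pairs is reported as not
assessable rather than a number.

## 6. Pipeline and reproducibility

A single seed drives cohort generation, CV fold assignment and
permutations through derived streams. Every output file is SHA-256 hashed
into `manifest.json`; the config snapshot written alongside suffices to
replay the run bit-identically. Warnings (dropped features, degenerate
tests, saturated K) never abort a run; stage failures abort with a partial
manifest naming the failed stage.

## 7. Open design choices resolved here

* QC injections default to 6 per platform (a common convention; the
  studies this emulates do not state a count).
* The density-scan argmin and the fixed K = 30 coexist deliberately: the
  source procedure reports both a scan winner and a fixed final cutoff
  without reconciling them, so the pipeline exposes `k_mode` rather than
  guessing.
* Multi-platform merge keeps the entry with the lower MSI level, then the
  lower QC RSD, then the lexicographically smaller platform name — merges
  are idempotent and order-invariant by construction.
* No multiple-testing correction by default (raw p-values are reported, as
  in the emulated workflow); Benjamini–Hochberg is available via
  `adjust="bh"`.
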