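# Methods

This note documents the models implemented in `gradmap`, the choices made
where the method family leaves them open, and what the synthetic phantoms
do and do not establish.

## Connectopic mapping

**Inputs and conventions.** A 4D BOLD image, a binary ROI mask on the same
grid, and a brain mask containing the ROI. ROI voxels are ordered
lexicographically by their 0-based (i, j, k) indices; that order is the
single source of truth for every per-voxel product (fingerprints,
similarity rows, mode entries, saved maps). All spatial math uses world
(mm) coordinates obtained through the image affine; nothing depends on a
particular template. ROI and reference time series are demeaned per voxel;
they are not variance-normalized, because every downstream quantity is a
Pearson correlation and therefore scale-invariant.

**Reference reduction.** The non-ROI matrix B (time × W) is factorized by
an economy SVD; components with singular values above
`max(t, W) · ε · σ₁` (machine epsilon ε) are retained. This is lossless for
the purpose at hand: fingerprints depend on B only through its column
space. Note that η² similarity is *not* invariant to the choice of
orthonormal basis within that space (only the numerator is
rotation-invariant), so the principal-axis basis is part of the method
definition, not an arbitrary convenience; the test suite checks a second,
independent routine that compresses identically.

**Similarity.** The η² coefficient between fingerprint vectors, clipped to
[0, 1], symmetrized, unit diagonal. A pair of identical constant
fingerprints (zero total variance) is defined as similarity 1 with a
warning. η² is invariant to a joint shift of both profiles (the grand mean
absorbs it) but not to shifting one profile alone — the property that
distinguishes it from correlation-type similarities.

**Eigenmaps.** Weight matrix W = S with zeroed diagonal (dense by default;
a symmetrized k-nearest-neighbour sparsification is available via `knn`
but dense solves are cheap and deterministic at the ROI sizes this package
targets, 10²–10³ voxels). Degree D = diag(W·1), Laplacian L = D − W,
generalized problem L v = λ D v solved densely (`scipy.linalg.eigh`). The
trivial constant eigenvector at λ ≈ 0 is discarded; modes are indexed from
0 at the first nontrivial eigenvector, so the literature's "second-order
mode" is `order=2`. Each mode has its D-weighted mean removed, unit
Euclidean norm, and a deterministic sign (first entry above 1e-8 in
magnitude made positive) *before* any alignment; alignment to a reference
mode may only flip the sign (inversion iff Pearson r < 0). Disconnected
similarity graphs are an error naming the component sizes. An eigenvector's
overall sign is arbitrary; analyses against external references either
align to a designated reference mode or interpret |r|.

**Group level.** The group similarity matrix is the element-wise mean of
subject matrices; group modes are eigenmaps of that average. The pipeline
computes subject and group decompositions in a single pass over sessions.

## Trend surface model

**Basis.** For degree d ∈ {2..5}: columns x¹..x^d, y¹..y^d, z¹..z^d of
world coordinates affinely mapped per axis onto [−1, 1] — exactly 3·d
columns, no cross-terms, no intercept column. Raw mm coordinates raised to
the 4th power are catastrophically ill-conditioned, hence the
normalization; it is computed once per ROI mask and must be reused across
subjects sharing the ROI so coefficients are comparable (pass
`normalization=` to reuse). An axis with zero extent is an error.

**Fit.** Bayesian linear regression with isotropic Gaussian prior
(precision α) and Gaussian noise (precision λ). Both y and the design
columns are centred before fitting — even powers of centred coordinates
have nonzero means, and centring the regression problem is what makes the
"intercept absorbed by the mean" contract exact; the stored y-mean and
column means are reapplied on reconstruction. (α, λ) maximize the
closed-form log evidence, optimized over (log α, log λ) by L-BFGS with
analytic gradients (envelope theorem) from four documented starts, bounded
to ±30 in log space; evaluations are O(3d) after one eigendecomposition of
XᵀX. At fixed hyperparameters the posterior mean equals the ridge solution
with penalty α/λ (asserted to 1e-8 in tests), and perturbing the optimized
hyperparameters by ±10% never increases the evidence. Non-convergence of
every start raises with the last evidence value.

**Degree selection.** Scores are the variance explained of the
empirical-Bayes fit at each candidate degree (log evidence is available as
an alternative criterion that simply maximizes). The scree elbow is
operationalized as: the chosen degree is the largest candidate whose
relative gain over the previous candidate, (s_d − s_{d−1}) / max(s_{d−1},
0.05), exceeds τ = 0.05; if none does, the smallest candidate is chosen
and logged. τ is exposed. Relative (not absolute) gains make the rule
insensitive to the overall noise floor; the denominator floor guards
near-zero scores.

## Group statistics

**Correlations.** Voxel-wise spatial correlation carries an explicit
caveat: its t-approximation p-value ignores spatial autocorrelation. The
coefficient-space correlation — Pearson r across concatenated TSM
coefficient vectors of the two maps, fitted on the same basis — is the
preferred inferential quantity, since coefficients are orthogonal model
summaries. Quality filtering keeps subjects with r > r_min (strictly)
against the group mode, default r_min = 0.5.

**Reliability.** ICC(2,k): two-way random effects, absolute agreement,
average measures, from the two-way ANOVA decomposition,
(MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n); CI by percentile bootstrap over
subjects (default 1000 draws, seeded). The primary reliability target is
each TSM coefficient (summarized as the mean ICC across coefficients per
ROI); voxel-wise ICC can be computed by passing voxel matrices instead —
the quantity entering the ICC is the caller's choice and both dialects are
legitimate. The within/between permutation test computes the mean
within-subject mode correlation minus the mean between-subject correlation
and permutes session-2 subject labels; p uses the add-one estimator
(1 + #{perm ≥ obs}) / (1 + N_perm), so p > 0 always and the minimal
attainable p is 1/(N_perm + 1) (default N_perm = 10,000).

**Omnibus tests.** Binary: logistic regression of group on all
coefficients (plus optional covariates) vs the nested null;
X² = ((n − p)/n) · 2ΔLL with p the full model's parameter count.
Continuous: Gaussian GLM; X² = (n − p) · log(RSS₀/RSS₁). Both are referred
to χ² with df = number of coefficients. The (n − p) scalings are standard
small-sample (Bartlett-type) corrections: the raw n-scaled statistics are
anti-conservative at the design sizes this package targets (empirical
type-I ≈ 0.09–0.11 at n = 60, df = 6, vs 0.04–0.06 corrected), and the
uncorrected statistics remain available via `bartlett_correction=False`.
Predictors are z-scored internally (the LR statistic is invariant; the
optimizer and the separation diagnostic become scale-free). Perfect
separation in the logistic model is detected (solver failure or diverging
standardized coefficients) and flagged on the result rather than silently
reported; the flagged statistic comes from a weakly regularized fit and
should be read as a bound. Change-score analysis forms Δ = session B −
session A per paired subject for both coefficients and outcome and reuses
the continuous omnibus. Post-hoc per-coefficient Pearson correlations are
deliberately uncorrected — they are descriptives run after a significant
omnibus, not hypothesis tests. Bonferroni control is a plain α/m.

## Synthetic phantoms

**What is emulated.** (a) ROI voxels whose series are mixtures of K
"network" time courses (smoothed Gaussian noise, unit variance) with
mixing weights that are Gaussian kernels in *gradient-value space* between
the voxel's planted-gradient values and K anchor points, so fingerprint
similarity decays smoothly with gradient distance — precisely the manifold
structure Laplacian eigenmaps recovers; (b) non-ROI voxels carrying one
network's series plus white noise; (c) two-session cohorts with subject-
and session-level gradient perturbations; (d) group shifts and
coefficient→outcome couplings injected in the orthonormalized TSM
coefficient space of the target ROI, so ground-truth effect sizes are
exact; (e) density maps that are identity/affine/logistic transforms of a
planted gradient.

**Key generator choices.** Planted gradients are low-order polynomials of
per-axis normalized coordinates, centred, Gram–Schmidt-orthogonalized,
unit-normalized. Successive gradients influence the mixing weights with
scale ratio 0.7 — above the 1/2 threshold at which the second eigenmap
would instead be a higher harmonic of the first gradient, and far enough
below 1 to keep the eigenvalue ordering stable. The kernel bandwidth is
half the mean per-dimension anchor range: weights must vary over the
*whole* manifold for the similarity matrix to carry a global ordering
(with a much narrower kernel the recovered mode distorts at the gradient
extremes because all distant pairs saturate at the η² background level of
~0.5 for unrelated fingerprints). SNR is signal sd / noise sd per voxel;
snr=0 means pure noise. RNG streams are spawned per subject from the
design seed, so adding subjects never changes earlier subjects' data, and
everything is bit-reproducible given the seeds.

**Default study conditions.** Recovery phantoms: V ≈ 300 ROI voxels on a
20×16×12 grid of 2 mm voxels, t = 300 timepoints, snr = 5, K = 12
networks. Cohorts: 12 subjects per group, between-subject coefficient
perturbation sd 0.2 (relative to the unit-norm gradient), within-subject
sd 0.05, group shifts of 0.5 in coefficient norm — a large, clearly
detectable effect — with t = 120–150 and V ≈ 180–300. Calibration
simulations use coefficient tables directly (n = 60, df = 6, 1000
replicates). These sizes keep the full test suite and the acceptance
script in the minutes range on one CPU while leaving all asserted margins
wide.

**What phantom validation does not show.** The generator reproduces the
second-order statistical structure the method consumes (smooth fingerprint
change along gradients, session/subject variance components, linear
effects in coefficient space) but not fMRI realism: no hemodynamics, no
physiological or motion artefacts, no spatial autocorrelation of noise, no
registration error, and network time courses are exactly shared across
voxels rather than approximately. Passing tests therefore establish the
*correctness and calibration of the machinery*, not the effect sizes or
reliabilities to expect on real data.

## Known limitations

- Dense eigen-solves are O(V³); ROIs much beyond ~2000 voxels would need
  the kNN-sparsified graph and an iterative solver.
- The isotropic prior treats all 3·d basis columns exchangeably; grouped
  (per-axis) precisions are a possible refinement.
- Voxel-wise spatial correlation p-values are not corrected for spatial
  autocorrelation (by design; use the coefficient-space correlation).
- The flagged perfect-separation omnibus result depends weakly on the
  regularization strength used for the bound.
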