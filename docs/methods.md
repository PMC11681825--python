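# Methods

## Pipeline model

The package implements the inferential chain of a source-space EEG
functional-connectivity group study. Its input is either (a) region-level
time series — one regions×samples matrix per subject, in the canonical
68-region Desikan–Killiany order (left hemisphere 0–33, right 34–67,
FreeSurfer `aparc` ordering) — or (b) precomputed per-band symmetric
connectivity matrices, together with a subject table carrying a group
factor and real-valued covariates. Everything upstream (recording,
artifact removal, source localization, parcellation) is out of scope; the
pipeline assumes a clean contiguous segment.

## Connectivity estimation

Per band (defaults θ 4–8, α 8–13, β 13–30, low-γ 30–45 Hz):

1. zero-phase band-pass: 4th-order Butterworth applied forward-backward
   (`sosfiltfilt`, reflect padding), giving an effective 8th-order
   magnitude response with > 40 dB attenuation one octave outside the
   band;
2. analytic signal via the Hilbert transform;
3. weighted phase lag index on sliding windows (default 1 s, 50 %
   overlap) inside consecutive epochs (default 6 × 30 s):
   `wPLI = |mean Im(z_i z_j*)| / mean |Im(z_i z_j*)|` over window samples;
4. static connectivity = element-wise mean over the pooled windows of all
   epochs (for equal-length epochs, pooling and epoch-then-grand
   averaging coincide).

Numerical conventions:

* **0/0 convention.** When every imaginary cross term vanishes
  (denominator < 1e−12 — identical or exactly zero-lag signals) the wPLI
  is defined as 0: "no lagged coupling". This is what makes the estimator
  insensitive to volume-conduction-like instantaneous mixing.
* **Edge transients.** Up to 1 s per end of the filtered signal is
  dropped before phase statistics, but only from samples *surplus* to the
  epoch budget: a recording that exactly covers `n_epochs × epoch_s` is
  used in full, with the reflect-padded zero-phase filter relied on to
  keep end transients small. (Dropping samples unconditionally would make
  the nominal 180-s protocol unsatisfiable on a 180-s recording.)
* **Small-sample bias.** For independent signals the wPLI estimate on a
  window with K ≈ 2·bandwidth·T_window effective samples has expectation
  ≈ √(π/2K), not 0 — about 0.45–0.52 for the θ and α bands under 1-s
  windows and ~0.25–0.3 for β/low-γ, independent of total recording
  length (averaging windows shrinks variance, not bias). Group
  comparisons are unaffected (the bias is common to all subjects), but
  absolute wPLI values for narrow bands must not be read as evidence of
  coupling. The null-noise regression test asserts the < 0.35 bound on
  the β band, where it is meaningful.

## Network-based statistic

Edge-wise inference uses a k-group ANCOVA per upper-triangle edge: full
model intercept + (k−1) treatment dummies + covariates, reduced model
without the dummies;
`F = [(RSS_red − RSS_full)/(k−1)] / [RSS_full/(N−k−Ncov)]`. The
implementation residualizes responses and dummies against the reduced
design once (QR) and vectorizes over edges; with no covariates it is the
classical one-way ANOVA F, and for k=2 it equals the squared pooled t.

Cluster-level FWER control follows the maximum-component-size logic:
edges with F strictly above the primary threshold form a graph, the
largest connected component's edge count is the test statistic, and the
null distribution is built by relabelling subjects across groups (group
sizes preserved; covariate rows stay attached to their subjects — simple
relabelling, not residual permutation) and recording the maximum
component size per permutation. `p = #(null ≥ observed)/n_perm`, without
+1 smoothing, so p can be exactly 0; study-scale default `n_perm = 5000`
(calibration suites use 200 for speed).

The primary threshold is chosen by an effect-size-guided scan: the grid
starts at the smallest multiple of the step (default 0.1) whose
omega-squared effect size `ω² = df_b(F−1)/(df_b(F−1)+N)` (floored at 0;
ω² → 1 as F → ∞) reaches the medium bound 0.06, and rises until the
largest component is significant at α=0.05. For N=138, k=4 this formula
starts the grid at F=4.0; published analyses sometimes quote slightly
different starting points depending on the ω² estimator used, so
`f_initial` is an explicit override. A non-significant scan is a valid
result carrying the full trace. Only the largest component is tested per
threshold (max-statistic logic); single-threshold mode (`scan=False`) is
used by the error-rate calibration, since the scan's stop-at-first-
significant rule performs multiple correlated looks.

Conventions: strict `F > threshold` for suprathreshold edges, `≥` in the
p-value count; component ties broken by smallest node index (reporting
only).

## Post-hoc layers

Mean network connectivity (mNC) is the per-subject average FC over a
component's edges. Group differences in mNC use one-way ANOVA plus
Tukey–Kramer pairwise comparisons
(`q = |m_i − m_j| / sqrt((MSW/2)(1/n_i + 1/n_j))`, studentized-range
p with k groups and N−k error df; for equal n this is Tukey's HSD, and
for k=2 it reduces to the pooled t-test). Zero within-group variance is
flagged degenerate rather than raising.

Directional subnetworks: every parent-component edge gets an all-pairs
Tukey–Kramer test on its raw FC values; an edge is retained for a named
contrast when that pair's adjusted p < α, and retained edges are split by
sign of the mean difference into at most two one-direction subnetworks.
Beyond Tukey's per-edge family correction no additional correction across
parent edges is applied — a deliberate mirror of common practice in this
literature, and a statistical caveat for interpretation.

Summaries report nodes, links, percent of parent links (rounded half-up
to one decimal), node degrees, lobe composition (share of degree mass per
lobe, using the packaged ROI→lobe table — a reporting convention, not
anatomical ground truth), and hemispheric lateralization in three named
variants (node share, intra-hemisphere link share, degree-mass share),
because published network descriptions are inconsistent about the base of
such percentages.

## Associations

Partial Pearson correlation = Pearson correlation of least-squares
residuals of x and y on [1, covariates];
`t = r·sqrt((n−2−ncov)/(1−r²))`, two-sided. Confidence intervals are
nonparametric percentile bootstrap over subjects (default 1000
resamples); resamples with collapsed residual variance are skipped, and
more than 20 % of them is an instability error. Percentile intervals at
n≈25 are known to undercover slightly (~91–94 % for a nominal 95 %);
the calibration suite measures this. Binary covariates enter as 0/1
indicators. No multiplicity correction is applied across a correlation
table.

## Predictive cross-validation

For a two-group contrast, each leave-one-out fold recomputes a two-sample
F (= t²) per edge on training subjects only, keeps edges above a fixed
threshold, extracts the largest connected component, standardizes those
edge values with training statistics, and fits a linear discriminant with
empirical priors; the held-out subject receives a label and a posterior
score. A fold where no edge passes falls back to the single highest-F
edge (logged). Metrics: accuracy, precision, Cohen's κ, Mann–Whitney AUC
(ties ½), sensitivity, specificity; 95 % CIs by percentile bootstrap over
the fold-level prediction set — a labelled choice, since fold outcomes
are not strictly independent. Selection inside the fold guarantees no
leakage from the held-out subject, which the mutation test asserts.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not EEG physics:

* **Time-series mode.** Each region is a sum over bands of its own
  stochastic narrowband oscillator (band-pass-filtered white noise,
  unit variance — pure tones would make wPLI degenerate at exactly 0/1)
  plus, on planted edges, a shared narrowband latent source injected into
  one region directly and into the other with a constant phase lag
  (default π/4; 0 and π are rejected because wPLI cannot see them), plus
  white noise (sd 1). Coupling on a planted edge for group g is
  `base_coupling + group_deltas[g]`.
* **Direct-FC mode.** Edge weights are independent logit-normal draws
  `expit(logit(m) + σz)` (defaults m=0.3, σ=0.5, giving a subject-level
  edge sd ≈ 0.1, a realistic wPLI spread); planted effects shift the
  location `m` on the [0,1] scale per group. The exact mean of a
  logit-normal is not `m` (it is the median); shifts are monotone in `m`,
  which is what the recovery and calibration claims need. Independence
  across edges and subjects makes this the reference global-null model.
* **Covariates.** Age (N(60,10) years), disease duration (|N(28,19)|
  months), LEDD (|N(105,135)| mg/day), most-affected side (Bernoulli ½),
  BMI (N(25,3)) — typical of early, L-dopa-naive PD cohorts; drawn
  independently of group, so relabelling is exact under the null.
* **Hormone linkage.** A hormone-like column is
  `a + b·resid(mnc | covariates) + ε` with b calibrated so the partial
  correlation with mNC equals a target; linear-Gaussian because the
  downstream statistic is a (partial) Pearson r.
* **Sampling-rate guard.** Configurations require fs ≥ 2.5× the highest
  band edge — a margin above the Nyquist rate so the band-pass has
  transition room (e.g. fs=100 with a 30–45 Hz band is rejected).
* Defaults mirror the study conditions (groups 27/42/30/39, 68 regions,
  1024 Hz, 180 s); tests pass desk-scale values (typically 256 Hz,
  20–60 s, 3–20 regions) explicitly.

What passing tests do **not** show about real data: no volume-conduction
forward model, no 1/f background, no artifacts, no spatial correlation
between edges in direct mode, and planted effect sizes are calibration
knobs, not empirical estimates.

## RNG discipline

All stochastic stages take an integer seed and are bit-reproducible.
Generator functions draw from `default_rng([seed, tag])` streams with a
per-function tag, so reusing one study seed across stages cannot alias,
e.g., a hormone noise vector with a covariate draw.

## Problem sizes of the shipped simulations

The test and calibration suites run at desk scale, chosen to give the
Monte-Carlo precision each claim needs: FWER over 500 null cohorts of
4×12 subjects × 20 regions with 200 permutations; planted-component
recovery over 50 seeds at n=15/group, shift +0.2, threshold F=6.0 (a
level planted edges clear comfortably while per-edge null exceedance is
~10⁻³); bootstrap coverage over 200 replicates of n=25 with 1000
resamples; hormone recovery over 100 seeds; null p-uniformity over the
2278 independent edges of a 68-region null cohort.

## Known limitations

* The wPLI small-sample bias for narrow bands (above) makes absolute
  values band-incomparable; compare within band only.
* The threshold scan's sequential looks make the *scanning* procedure's
  overall false-positive rate slightly higher than α; the per-threshold
  permutation test is what is calibrated.
* Tukey–Kramer subnetwork extraction controls error per edge, not across
  the parent component.
* The direct-FC generator has no between-edge correlation, so it cannot
  probe sensitivity to spatially structured null dependence.
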