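# Methods

`presympto` re-implements, as a tested pipeline over synthetic cohorts, an
analysis chain for presymptomatic disease detection from multi-region
electrophysiology: band-power feature extraction, bias-regularized
matrix-factorization completion of structurally missing region blocks,
supervised multiview canonical correlation analysis (sMVCCA) with
cross-loading ranking of signal sources, and leave-mouse-out classification
over top-R region subsets. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic experiments
do and do not establish.

## The analysis chain

**Band-power features.** Signals are sampled at `fs` (full recording scale
2 kHz; reduced desk scale 400 Hz) and segmented into non-overlapping 60-s
Hamming-tapered windows. For each window and each canonical band — delta
(1–4 Hz), theta (6–10 Hz), gamma (40–100 Hz) — two statistics are computed
from the one-sided FFT magnitude spectrum: the *band amplitude* (mean
magnitude over in-band bins; the mean makes the statistic window-length
independent) and the *band ratio* (summed in-band magnitude divided by the
summed magnitude over all positive frequencies up to Nyquist). The bands
are disjoint, so the three ratios sum to at most 1. This yields the D = 6
vector (delta_amp, theta_amp, gamma_amp, delta_ratio, theta_ratio,
gamma_ratio) per window and region. Band statistics are taken from the FFT
bins of the raw tapered segment; a zero-phase 4th-order Butterworth
band-pass (applied forward–backward) exists as an optional pre-filter mode.
Trailing partial windows are dropped; an all-zero segment produces a zero
vector with a warning rather than NaN, so the mask remains the only
missingness channel.

**The observed matrix.** Feature vectors are arranged into X with one row
per observation unit and D·M columns (M regions, region-major order). Rows
are individual windows by default (e.g. 180 per mouse for 3×1-h sessions);
a per-mouse-mean row level is also supported. Whole (mouse, region) blocks
absent from the recording are flagged in a boolean mask. Because the raw
amplitude features are mean FFT magnitudes of order 10³ while ratios are of
order 10⁻¹, the pipeline configs z-score each column over its observed
entries before completion (`features.normalize: zscore`); the library
default applies no normalization.

**Completion.** Missing blocks are imputed by a regularized factorization
with per-row and per-column bias terms:

    x̂_ij = μ + b_row,i + b_col,j + p_iᵀ q_j,

with μ the mean of observed entries, fitted by SGD over observed entries
(p_ik ← p_ik + α(2 e_ij q_jk − λ p_ik), likewise for q; e_ij the residual),
visiting entries in a seed-fixed shuffled order. Bias terms receive a batch
update after each pass, driven by row-/column-mean residuals; a fully
online bias variant sits behind a flag. The bias terms are what make
whole-block (structural, not element-wise random) missingness tractable:
a block's row factors are identified from the row's other observed blocks,
and the column biases carry the per-feature offsets. The completed matrix Z
copies observed entries verbatim and fills only missing entries — this is
enforced bit-exactly. Defaults: α = 2.0·10⁻⁵ and λ = 1.0·10⁻⁵ (the study's
values; α of that size matches raw-magnitude feature scales). On z-scored
or unit-scale planted matrices the desk-scale experiments use α = 5·10⁻³
(or 2·10⁻³), which converges in a few hundred epochs; the latent dimension
K (unreported in the source analysis) defaults to 2, with the planted
recovery tests sweeping K implicitly through their ground truth. Epoch cap
5000, early stop when the relative change of observed RMSE drops below
10⁻⁶; the best-RMSE epoch is returned and its regularized objective is
asserted not to exceed the initial one. Divergence (non-finite parameters)
raises an error advising a smaller α. The per-entry loop is JIT-compiled
with numba, with a pure-Python fallback.

**sMVCCA.** The M region views Z_m (N×D) plus the one-hot label view Z_l
(N×D_l, D_l = 2; column order wild, diseased) are projected jointly by
maximizing the sum of between-view covariances under per-view unit
variance, i.e. the generalized eigenproblem C̄V = ε(C̲ + ηI)V with C̄ the
between-view cross-product blocks (zero diagonal) and C̲ the block diagonal.
Choices: views are column-centered (required for the correlation reading of
cross-loadings; raw mode behind a flag) and scaled by 1/√(N−1) so the
blocks are covariance-scaled and η = 0.01 has a stable meaning across N;
C̄ is explicitly symmetrized before the solve; the solver is
`scipy.linalg.eigh(a, b)`; eigenvectors are B-orthonormal and sign-fixed by
making the label block's first nonzero coefficient positive. Every solution
must pass a relative eigen-residual check at 10⁻⁸, and the M = 1 case is
required (in tests) to match an independent whitening+SVD two-view CCA to
10⁻⁸. D_p defaults to 2 = min(D, D_l).

**Cross-loadings and ranking.** For region m, the cross-loading CL_m is the
mean over the D feature columns of the Pearson correlation with ẑ_l¹, the
label view's projection on the top eigenvector. Since canonical directions
carry an arbitrary sign, the default aggregation takes mean *absolute*
correlations (a signed-mean mode is selectable); constant columns
contribute 0 with a warning. Regions are ranked by descending CL_m with
ties broken by the canonical region order. On the real recordings this
procedure orders the sources THL > PAG > PL > AMY > S1 > ACC > BR > NAc >
EMG; that ordering is reference behavior, not a test, because the data are
not releasable.

**Classification.** For R = 1..9 the projections of the R top-ranked
regions are concatenated (D_p·R columns) and fed to four classifiers:
pooled-covariance LDA, KNN (k = 9, Euclidean), linear soft-margin SVM
(cost 1.0, an engineering default), and an extreme learning machine —
random unit-Gaussian input weights, sigmoid hidden layer (1000 units at
full scale), ridge least-squares readout (ridge 10⁻⁶), seed-fixed. At desk
scale the experiments use 100–200 hidden units with ridge 10⁻², since a
training fold of a few hundred rows would otherwise be interpolated.
Evaluation is leave-mouse-out: one fold per mouse, per-mouse accuracy is
the fraction of the held-out mouse's windows classified correctly, and
summaries average unweighted over mice. The argmax-R of an accuracy-vs-R
curve is the smallest R attaining the maximum (parsimony tie-break). Two
evaluation modes exist and are recorded in every output: *transductive*
(completion and sMVCCA fitted once on the full cohort — the ordering the
original protocol implies; note the label view then contains the held-out
mouse, which at small N measurably inflates apparent accuracy) and *strict*
(both stages refitted per fold on training mice; the held-out mouse's rows
are folded into the completion model with Q, column biases and μ frozen,
then projected with the training-fitted directions, and the fold's own
ranking selects regions). Test-row leakage into classifier training is
asserted per fold.

## The synthetic cohort generator

Real recordings are not releasable, so the generator defines the study
conditions. Each (mouse, session, region) signal is a sum over the three
bands of band-limited Gaussian noise plus a broadband floor at
noise_floor/10. Band components are synthesized in the frequency domain
(complex-Gaussian rfft coefficients on in-band bins only), so their
spectral support is exactly the nominal band and a configured power gain g
maps exactly onto a √g amplification of the band-amplitude feature.
Diseased mice receive per-(region, band) power gains in the configured
informative regions. Three heterogeneity terms, all log-normal on the power
scale, emulate real-data structure: per-(mouse, region, band) gains
(individual differences; shared by both classes), per-(session, region)
gains (day-to-day drift, e.g. electrode impedance), and per-60-s-window
amplitude modulation (slow band-power fluctuation). Structured missingness
removes whole (mouse, region) cells — never single windows — uniformly at
random subject to every mouse keeping ≥ 1 region and every region being
observed for ≥ 1 mouse; the cell count is round(fraction · n_mice · M),
26/225 at the default 11.6%. A single master seed fans out to per-stream
sub-seeds keyed by (mouse, session, region) counters, so adding mice or
sessions never reshuffles existing draws.

Default conditions mirror the study design: 15 diseased / 10 wild mice,
nine sources (THL, PAG, PL, AMY, S1, ACC, BR, NAc, EMG) of which the first
seven are informative with graded delta+theta gains, three sessions per
mouse, 11.6% missingness. The default recording scale is reduced (400 Hz,
600-s sessions) to keep experiments fast; `full_recording_scale()` restores 2 kHz /
3600 s.

Two frozen experiment conditions deserve their rationale:

* **Ranking recovery** (`ranking_recovery_config`): 10 mice, one 300-s
  session, THL and PAG at power gain 6 (2.45× amplitude), 11.6%
  missingness imputed by completion. Strong effects and a small cohort make
  100 replicates cheap while still exercising the full chain.
* **Accuracy-vs-R peak recovery** (`r_sweep_config`): 25 mice, 3×900-s
  sessions (45 windows per session, so per-fold accuracies are estimated
  on 135 windows), seven informative regions at an equal modest gain
  (1.6), and two pure-noise channels (NAc, EMG) given strong session-level
  drift (log-power sd 4.0). Equal gains keep each added informative
  region's contribution above fold noise; the session drift is the
  mechanism by which the noise channels actively *hurt* a held-out mouse
  (the drift of its own sessions cannot be anticipated from training
  data), producing a genuine peak at R = 7. Session-level rather than
  mouse-level drift is deliberate: with only 25 mice, mouse-level offsets
  can align with class by chance and then genuinely help leave-mouse-out
  classification, whereas day-to-day drift cannot generalize and only
  harms. This experiment runs in strict mode, because at desk-scale N the
  transductive label leakage through the sMVCCA is large enough to mask
  the noise-channel penalty. A minority of cohorts (~10% of seeds) still
  place the peak at R = 8: their realized drift draws chance-align with
  class across the cohort's 75 sessions, an irreducible small-cohort
  effect.

**What the synthetic experiments show — and don't.** They establish that
the chain recovers planted structure: the imputation recovers held-out
blocks of mean+bias+low-rank matrices far better than column means, the
ranking finds planted informative regions, and the R-sweep peaks at the
planted number of informative regions under the stated heterogeneity
model. They do not validate the biological claims: real LFP is
non-Gaussian, nonstationary, cross-regionally correlated, and its class
effects are not clean band-power gains. The generator also models no
artifacts, line noise, or quiescence detection (inputs are assumed to be
quiescent-period extracts, per a config-level assumption).

## Numerical and degenerate-input choices

* Completion with no observed entries raises "nothing to fit"; μ of an
  empty mask is never computed.
* Observed entries pass through completion bit-exactly (`np.where` on the
  mask; asserted in tests).
* The eigen solve raises (suggesting a larger η) if LAPACK fails; the
  residual check at 10⁻⁸ is a hard error, not a warning.
* Cross-loadings require N ≥ 3; constant columns give 0 with a warning.
* Ties in region ranking keep canonical order (stable argsort); argmax-R
  ties resolve to the smallest R.
* Mask files use the ✓/− cell encoding (true/false and 1/0 accepted);
  validation rejects any mouse with no observed region and any region
  observed for no mouse, naming the offender.
* All randomness flows from explicit integer seeds; derived sub-seeds stay
  below 2³¹.

## Problem sizes

Unit tests run on miniature cohorts (4–10 mice, 60–300-s sessions,
fs 256–400 Hz). The replicated recovery experiments use the frozen
conditions above (100 ranking replicates; 20 sweep replicates in the test
suite, 8 in the acceptance script, which also reports every n it used).
Feature-counting checks run at full recording scale (2 kHz, 3×3600 s) for
a single region.

## Known limitations

* The strict mode folds the held-out mouse into the completion model
  transductively at the *row* level (its own observed entries inform its
  row factors); only the label and the other mice's data are excluded.
* The ELM readout solves dense normal equations; for hidden layers much
  larger than 10³ a factorization-based solver would be preferable.
* `run_pipeline` caches by config digest only at whole-run granularity;
  per-stage re-use requires driving the stages individually.
* The generator's band components are stationary within a modulation
  block; no 1/f background or cross-band coupling is modeled.
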