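# Methods

`rapidvol` implements a quantitative cross-sequence comparison between a
standard high-resolution T1-weighted structural acquisition and a rapid,
reduced-field-of-view T1-weighted acquisition (an EPI-based multicontrast
sequence of the EPImix family), at four levels: tissue-volume agreement
(global and voxel-wise), grey-matter–age associations, brain-age prediction
quality, and within-session test-retest reliability. Because the analysis is
exercised on synthetic cohorts, this note describes both the statistical
procedures and the generative model behind the synthetic data, including
what the generator does and does not emulate.

## Statistical procedures

**Correlation.** All pairwise agreement measures report Spearman's rank
correlation r_s with a two-sided p-value from the t transform
`t = r_s sqrt((n-2)/(1-r_s^2))` on n−2 degrees of freedom (an exact
permutation test is unnecessary at n = 64 and the t approximation is the
field's default), together with r² from the squared Pearson coefficient.
Numerically perfect monotone data (1 − |r_s| < 1e−12) reports r_s = ±1 with
the limiting p = 0. Constant inputs raise an error rather than returning 0:
the correlation is undefined, not null.

**Voxel filter.** Voxel-wise analyses are restricted to voxels with at
least 0.001 mm³ of tissue in at least 95% of participants. The participant
count is compared to `ceil(fraction · n)` — the conservative reading of
"at least 95%" — and the volume comparison is `≥ threshold`. Both
conventions are recorded constants so counts are exactly reproducible.
Voxels with zero variance across participants yield missing values (not 0)
in correlation and ICC maps and are excluded from distribution summaries.

**Distribution summaries.** Median and quartiles use linear interpolation
between order statistics (numpy's default percentile convention), after
dropping missing values.

**Bootstrap difference in association strength.** To test whether the
GM–age association differs between contrasts, participants are resampled
with replacement 10,000 times (configurable). Within each replicate the
*same* resample indices are applied to every contrast, the statistic
(r_s or r²) of (age, volume) is recomputed per contrast, and pairwise
differences are formed; the 95% CI is the percentile interval of each
difference distribution, and a CI excluding 0 indicates a difference.
Sharing indices across contrasts is essential — it makes the differences
paired, which is what gives the difference distribution its meaning.
Replicates in which any statistic is undefined (a zero-variance resample)
are redrawn, keeping exactly n_boot replicates; the redraw count is
reported. Everything is reproducible from one integer seed.

**ICC(3,1).** Test-retest reliability uses the intraclass correlation for
consistency of single measurements from a two-way mixed model:
`ICC = (MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error)`, with the
measurement (rater) main effect removed from the error term, so a constant
shift between test and retest leaves ICC = 1. The 95% CI follows
Shrout–Fleiss from F = MS_subjects/MS_error with (n−1) and (n−1)(k−1)
degrees of freedom. Published descriptions of this design sometimes mix
"one-way random effects" language with the ICC(3,1) label; the label and
the word "consistency" are operative here, and a one-way ICC(1,1) is
available behind the `form="icc1"` option. The voxel-wise ICC map is the
same computation vectorised over voxels.

**Brain-age metrics.** The error metric is the *median* absolute error
(MAE) in years — median, not mean, taken literally. Each model is
benchmarked against the worst possible brain-age model: predicting one
constant, the mean age of the external pre-trained model's training sample
(40.6 y), for everyone. The null-MAE ratio (null MAE / model MAE) is the
fold improvement over that benchmark; it is reported as missing when the
model MAE is exactly 0, and it is *not* guaranteed to be ≥ 1 — a model can
lose to the constant.

**Leave-one-out offset correction.** A systematically offset prediction
(rapid sequence) is corrected by regressing the standard-sequence
predictions on the rapid-sequence predictions with ordinary least squares,
leaving one participant out at a time; the held-out participant's adjusted
prediction is `intercept + slope · pred_rapid`. The per-fold coefficients
are computed exactly by downdating the full-sample sums. LOO rather than
k-fold mirrors the small-sample setting this correction is designed for.

## The synthetic cohort generator

The generator emulates the *statistical structure* of a paired-acquisition
study, not brain anatomy. Defaults are the study conditions and are not
meant to be tuned per run.

**Cohort.** Ages are drawn from a normal(28.2, 9.2) truncated to
[18, 59] years by rejection sampling. Note the truncated distribution's
mean is ≈ 30.5 y — truncating an off-centre normal shifts the mean above
the nominal location. The first `n_retest` (default 10 of 64) participants
carry a retest flag.

**Templates.** Each tissue class has a fixed template T (mm³ of tissue per
voxel) on a 24×24×16 grid of 4×4×6 mm voxels: an ellipsoidal white-matter
core, a grey-matter shell, and CSF in a central ventricle-like blob plus a
thin outer rim, capped at the voxel volume. Shapes are schematic; what
matters is that supports differ and taper axially, so an axial
field-of-view cut removes tissue.

**Generative model.** For participant i, tissue t, voxel v:

    latent_iv   = T_v (1 + e_i/G) + T_v (A_iv − 1)
    standard_iv = latent_iv · N_iv
    rapid_iv    = mask_v · smooth( (latent_iv + T_v d_i/G) · M_iv )
    retest_iv   = same as rapid with a fresh noise field M'

where G = ΣT, `e_i = u_i + slope_t (age_i − μ)` is a global subject mode
(random effect plus linear age trend; GM declines at −800 mm³/y, CSF grows
at +250 mm³/y, WM is flat — the paper-style data fix only the sign of the
GM trend, so the magnitudes are free parameters chosen once), `A_iv` is a
stable per-voxel anatomical field (unit-mean lognormal with coefficient of
variation `voxel_effect_cv`, shared between sequences and retest — it is
what gives voxel-wise agreement its signal), `d_i` is a stable
sequence-specific deviation (what limits cross-sequence agreement while
leaving retest reliability near unity), and `N, M` are unit-mean lognormal
acquisition-noise fields, independent per voxel and acquisition. All
multiplicative terms are positive by construction, so voxel volumes are
non-negative without clipping; clipping would otherwise bias the variance
algebra below.

**Exact calibration.** At the global-volume level the model yields

    standard = G + e_i + H_full + ε_std
    rapid    = s (G + e_i + d_i) + H_mask + ε_acq

with s the in-mask template fraction (after smoothing), H the summed
anatomical field (only the in-mask part is shared between sequences), and
noise variances solved from `c² = log(1 + v / (f ΣT²))` so the summed noise
variance equals its configured global value exactly (f is the per-voxel
second-moment factor of the latent map). The sequence-deviation variance
var(d) is then solved in closed form so the expected cross-participant
Pearson correlation of global volumes equals the per-tissue target
(GM 0.84, WM 0.84, CSF 0.56). The implied retest ICC,
`(s²(v_e + v_d) + v_H,mask) / (… + v_acq)`, lands at ≈ 0.99 for GM with the
default acquisition noise — high cross-sequence *dis*agreement and
near-unity retest reliability coexist because d_i is stable across retest,
as in real sequence effects. `variance_components()` exposes this algebra.

**Smoothing and field of view.** Rapid maps are smoothed with a separable
Gaussian (σ = FWHM/2.355 per axis, truncated at 4σ, default FWHM 4 mm) and
truncated by removing the top and bottom 3 of 16 axial slices (≈ 19% of
template GM volume, emulating consistently missing inferior/superior
coverage). Smoothing conserves the global sum up to edge effects, so the
global-volume calibration is unaffected; the recorded boolean mask lets
volumetrics treat the truncation exactly.

**Brain-age table.** Standard-sequence predictions are age plus N(0, 4 y)
noise; rapid and FoV-reduced predictions are affinely compressed
(`intercept + slope · age`, slopes 0.42 and 0.30) plus noise, chosen once
so the rapid sequence shows MAE ≈ 14 y with r_s ≈ 0.6 and the FoV-reduced
standard sequence MAE ≈ 13 y with r_s ≈ 0.36 — the signature of a model
applied outside its training domain: rank order largely preserved, absolute
calibration lost.

**What the generator does not emulate.** Real anatomy, spatial
autocorrelation of the anatomical field (it is independent per voxel before
smoothing), registration/segmentation error structure, age-distribution
skew (the study cohort is right-skewed; the generator's truncated normal
is not, which lowers the null MAE from the study's 15.6 y to ≈ 10–11 y),
sex effects, and scanner drift. Consequently, passing tests demonstrate
that the *procedures* are correct and that the pipeline recovers known
generative parameters — not that the specific published point estimates
would be reproduced from real scans.

## The GP brain-age stand-in

`GprAgeModel` is a deliberately small Gaussian-process regressor: squared
exponential kernel with *fixed* hyperparameters (no marginal-likelihood
optimisation), observation-noise variance added to the diagonal, and a
constant prior mean equal to the mean training age; features are the three
global tissue volumes plus eight octant GM volumes, z-scored by training
statistics. The default length scale is 3× the median pairwise training
distance — generous, so the regressor behaves near-linearly inside the
training range, which is what a large-sample trained model looks like
locally. The point of the stand-in is the offset mechanism: features from
truncated-FoV maps are scaled down relative to the (full-coverage) training
distribution, producing predictions that remain rank-correlated with age
but are systematically offset — exactly the failure mode the LOO regression
corrects. It is a mechanism demonstration, not a reimplementation of any
pre-trained model.

## Numerical and design choices

- Report determinism: one seed fans out to fixed per-purpose RNG streams
  (ages, subject modes, anatomy field, sequence deviation, each noise
  field, brain-age noise), so identical config + seed gives byte-identical
  JSON reports, and the retest generator can re-derive the first
  acquisition's latent maps without storing them.
- Degenerate inputs raise typed errors (constant vectors, zero-variance
  folds, empty masks, all-missing summaries) rather than returning NaN,
  except in voxel-wise maps where per-voxel NaN is the documented missing
  value.
- Problem sizes in the test suite: parameter-recovery checks run at
  n = 2000 participants (global correlations; the ±0.02 band is ~1.3σ for
  CSF, a deliberately sharp check), n_retest = 200 (ICC), 500 outer
  replicates × 1000 resamples (bootstrap coverage), and study-sized n = 64
  everywhere else.
- NIfTI round trips store float64 so written and re-read maps agree to
  < 1e−6 mm³; TSV tables are parsed with round-trip float precision so a
  written-and-reloaded dataset reproduces the in-memory report exactly.

## Known limitations

- The per-voxel anatomical field is spatially white before smoothing, so
  voxel-wise correlation maps lack the smooth regional structure of real
  data (their medians land near, but below, the published ones: GM ≈ 0.63
  vs 0.70; voxel-wise ICC ≈ 0.85 vs 0.95).
- The null-MAE ratio on synthetic cohorts is smaller than the published
  values because the synthetic age distribution is symmetric (see above);
  the worked ratio arithmetic on the published error table is reproduced
  exactly.
- ICC confidence intervals assume balanced, complete tables; missing cells
  are rejected, not imputed.
- The LOO correction assumes an affine offset; a non-affine miscalibration
  would be only partially corrected, by design.
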