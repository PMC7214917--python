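# Methods

## The measurement

Systemic low-frequency oscillations (sLFOs) are non-neuronal BOLD
fluctuations in the 0.01–0.15 Hz band that travel with the blood. A voxel's
**BOLD delay** (hemodynamic lag) is the time shift, searched over ±20 s,
that maximizes the Pearson correlation between the voxel's time course and
a reference time course averaged over the major venous sinuses. Positive
lag means late arrival; in acute stroke, tissue downstream of an occluded
vessel shows delays of several seconds, so thresholding the delay map
(> 0, > 2.3, > 4.6 s) inside the stroke-affected vascular territory yields
a perfusion-lesion estimate analogous to a Tmax > 6 s lesion from
contrast-bolus perfusion imaging.

The venous-sinus reference is used rather than the global mean because the
sinuses lie outside the parenchyma: the reference cannot be contaminated by
the hypoperfused tissue it is meant to detect.

## Lag estimation

Correlations are evaluated at integer multiples of the repetition time
(TR = 0.4 s by default) on the truncated overlap of the shifted pair — no
zero-padding, each overlap mean-centered separately. Zero-padding was
rejected because it biases r toward 0 at large shifts; sub-sample
interpolation is omitted because TR-resolution (0.4 s) is an order of
magnitude finer than the delineation thresholds (whole and half-whole
seconds). Ties in peak correlation are broken toward the smallest |lag|
(then toward the negative shift), which is deterministic and favors the
no-delay null. A constant (zero-variance) series yields a NaN lag flagged
invalid rather than an exception, so one degenerate voxel cannot abort a
map. The estimator is verified against an exhaustive per-shift
`np.corrcoef` oracle — equality is exact, not approximate.

## Significance calibration

The per-voxel peak correlation is compared against the null distribution of
the *maximum* correlation over the whole ±20 s search range — using the max
matches what the search itself reports and absorbs the multiple comparisons
across shifts. The null is built from surrogates correlated against the
realized reference; the threshold is the empirical (1 − α) quantile of the
per-surrogate maxima (α = 0.05, n_null = 10,000 by default; the experiment
harness uses 500, which sets the threshold to within ~0.01 in r).

Three surrogate schemes are implemented:

- **`filtered_noise` (default).** White noise passed through the pipeline's
  own zero-phase band-pass. This is the explicit null model — "a voxel
  containing only scanner noise, filtered like the data" — and it is
  calibrated for every reference realization: measured type-I rate
  0.033–0.080 (mean 0.0485) across reference draws at α = 0.05, with the
  residual spread attributable to the empirical-quantile and
  shared-reference Monte-Carlo noise.
- **`spectral_shuffle`.** Random phases plus a permutation of the amplitude
  bins within the reference's spectral support. Data-driven (needs no
  filter parameters); keeps band limitation and total power.
- **`phase`.** Plain phase randomization. Preserves the exact amplitude
  spectrum, but because surrogate and reference then share the same
  realized Rayleigh bin amplitudes, the null max-correlation variance is
  about twice that of independent band-limited noise
  (Σ|X|⁴/(Σ|X|²)² ≈ 2/n_band vs 1/n_band) and the threshold is
  conservative: measured type-I ≈ 0.001 at α = 0.05. Retained for
  comparison; not the default for exactly this reason.

Naive sample permutation of the autocorrelated reference is not offered —
it destroys the autocorrelation and gives an anticonservative threshold.
Sub-significance voxels are retained in the map with `valid = False`, so
downstream consumers choose whether to mask (the delineation masks by
default, switchable with `use_validity`).

## Preprocessing

Fixed order: initial-volume discard (25 volumes = 10 s) → OLS regression of
the six rigid-body parameters (plus intercept; collinear columns dropped
with a warning) → 6 mm FWHM Gaussian smoothing → zero-phase band-pass
0.01–0.15 Hz (order-2 Butterworth per direction via `sosfiltfilt`, mean
removed). Zero-phase filtering is mandatory: any phase distortion would
bias every delay estimate. DVARS is computed after confound regression and
before smoothing, matching its role as a motion-artifact metric; FD uses
the Power convention (Σ|Δtranslation| + 50 mm · Σ|Δrotation|), with a ×10
rescaled value reported alongside for comparability with regression
coefficients.

**Segment accounting.** Scan-length fractions refer to the original
(pre-discard) 850-frame scan: a segment keeps the first
round(fraction × 850) frames of the post-discard data, capped at its
length. This makes the reported durations equal the actual data length —
68/136/204/272 s for fractions 0.2–0.8 and 330 s for the full post-discard
segment — and is the only accounting under which both sets of printed
durations are simultaneously consistent. FD, DVARS and the null threshold
are recomputed per segment (shorter series have wider null distributions).

## Synthetic cohort

Each subject is a 32 × 32 × 16 grid at 3 × 3 × 4 mm (desk-scale but
genuinely 3D), 850 frames at TR 0.4 s. The shared sLFO is Gaussian white
noise brick-wall limited to 0.01–0.15 Hz and standardized — band-limited
without committing to a parametric waveform. Each voxel receives the sLFO
delayed by its true lag via a frequency-domain phase ramp (exact for
band-limited signals; no interpolation bias), scaled by a smooth positive
amplitude field, on a baseline of 100 units, plus white noise of standard
deviation amplitude/snr. The true lag field is a smoothed Gaussian random
field mapped to −2..+2 s in normal tissue; an ellipsoidal lesion placed in
one vascular territory carries lags spanning 3..10 s (above the 2.3 and
4.6 s thresholds, inside the ±20 s tracking range). The venous-sinus block
sits outside the parenchyma with lag 0; the territory atlas partitions the
brain into anterior→posterior slabs; the DWI core is a concentric
sub-ellipsoid of the lesion. Motion traces are smoothed random walks scaled
by `motion_amplitude` (0.2 mm default); `motion_coupling` (default 0) adds
a motion-locked intensity artifact.

Default noise levels: snr = 10 for recovery testing (the regime where
estimator error should be quantization-dominated), snr = 5 ("moderate") for
the 20-subject scan-length cohort. Both were fixed before the corresponding
experiments were first run.

**What the generator does not emulate:** anatomy, draining-vein topology,
dispersion (lag is a pure shift, not a shape change), cardiac/respiratory
physiology, susceptibility dropout, scanner drift. Passing recovery tests
therefore demonstrates correctness of the estimator under the stated signal
model, not clinical performance: synthetic Dice values (≈ 0.9+ at fraction
0.8) are far higher than the patient-scale medians the method achieves in
practice, because the model contains no physiological confounds.

One definitional consequence: DVARS of motion-free, noise-free synthetic
data is *not* zero — any temporally varying signal has positive DVARS; it
is zero exactly for temporally constant data. FD of a motion-free trace is
identically zero.

## Delineation

Within the union of affected territories (those holding ≥ 5% of the DWI
lesion voxels, never empty — fallback to the largest overlap), voxels with
delay strictly greater than the threshold are kept; connected components
under 26-connectivity smaller than `min_cluster_ml` (default 1.0 mL) are
discarded; no hole-filling. Volume is voxel count × voxel volume / 1000.
The identical procedure serves Tmax-like maps at > 6 s. Strict inequality
and the 0/2.3/4.6 s defaults follow the delineation convention this
pipeline reproduces; connectivity and the cluster floor are exposed in
configuration because the upstream convention does not pin them down.

## Agreement statistics

Dice = 2|A∩B|/(|A|+|B|); undefined (None, excluded from summaries) when
both masks are empty, 0 when exactly one is. Bland-Altman: bias = mean
difference, limits of agreement = bias ± 1.96 × sample SD (n − 1); percent
bias uses the mean of the pairwise means as denominator. Cohen's kappa is
computed directly from the k × k table with disagreement weights 0/1 or
((i−j)/(k−1))²; expected disagreement from marginal products; degenerate
marginals yield None. The kappa route is cross-checked against
scikit-learn on expanded label vectors in the test suite.

## Experiment harness

`run_cohort` derives per-subject seeds from one master seed
(`SeedSequence.spawn`), processes each subject at every fraction (full scan
first — it is the Dice/Bland-Altman reference), asserts threshold nesting
on every map, and emits `rows.tsv` (one row per subject × fraction ×
threshold), `summary.json` (median/IQR Dice and Bland-Altman per fraction ×
threshold, plus a config hash) and a plain-text report. Output directories
created under a different configuration are refused without `force`. A
failing subject is logged and skipped; the run aborts only if every subject
fails.

## Problem sizes

The shipped test suite and the acceptance script use the 32 × 32 × 16 grid
with 10-subject (snr 10) and 20-subject (snr 5) cohorts, 500 null
surrogates, and 100 oracle pairs — sizes at which the full study runs on a
single CPU in minutes while leaving every statistical check comfortably
powered.

## Known limitations

- No dispersion modeling or regressor refinement: the reference is taken as
  given, matching the single-pass sinus-reference design.
- Integer-sample lag resolution; the optional parabolic peak refinement was
  judged unnecessary for threshold-based delineation and is not
  implemented.
- The null calibration assumes noise voxels share the data's temporal
  filtering; colored physiological noise inside the pass band would require
  a subject-specific noise model.
- Bland-Altman proportional-bias regression is not computed (visual-only in
  the convention this follows).
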