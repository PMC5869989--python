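# Methods

This note documents the models and numerical choices behind `ramanbone`: what
the synthetic-study generator emulates, how each preprocessing step is
realized, how the composition metrics are estimated, how the decision
algorithm is trained and validated, and where the genuinely open design
choices were settled.

## Study design and data model

A study consists of raw Raman spectra of murine femurs and vertebral columns
harvested at weeks 0, 2, 4 and 5 after intracardiac tumor-cell inoculation.
Each femur is measured at 7 sites along its length with 5 replicate spectra
per site (35 spectra); each spine at the 12 vertebrae L1–L6, S1–S4, C1–C2,
also with 5 replicates (60 spectra).  Sites map to regions: femur sites 1–2 →
distal metaphysis, 3–5 → diaphysis, 6–7 → proximal metaphysis (a symmetric
2-3-2 split mirroring long-bone anatomy; the site numbering itself carries no
published region assignment), and vertebrae group into lumbar (L1–L4),
lumbar–sacral (L5–S2) and sacral–caudal (S3–C2), four vertebrae each.

Spectra live on one shared wavenumber axis, by default 600–1800 cm⁻¹ in
2 cm⁻¹ steps (601 channels) — a convention covering the six fingerprint bands
at typical dispersive-spectrograph resolution, not a reproduction of any
particular instrument.  Replicates are kept as independent spectra because
validation is leave-one-*spectrum*-out; metric summaries average over
replicates downstream.

## Synthetic-study generator

Each raw spectrum is built as

    measured = (Σ bands + fluorescence + probe background) · response + noise
               [+ cosmic rays],  clipped at 0.

* **Bands.** Six pseudo-Voigt profiles (linear Gaussian/Lorentzian mix sharing
  one FWHM, height-parametrized so the profile FWHM equals the parameter
  exactly).  Defaults (center cm⁻¹ / apex height / FWHM cm⁻¹): phosphate ν₁
  958/100/15, phenylalanine 1004/16/10, carbonate 1070/40/16, amide III
  1250/22/30, CH₂ 1450/38/28, amide I 1660/42/38.  The default Gaussian
  fraction is 0.98: near-Gaussian bands keep the analytic Lorentzian tail
  pedestal small enough that the baseline-recovery and band cross-talk
  tolerances hold; the mixing fraction remains a free parameter.  The
  carbonate apex at 0.40 of phosphate sits inside the 0.25–0.45 range typical
  of bone spectra and keeps the weakest metric operand at workable SNR.
* **Composition effects.** A class-effect table multiplies the phosphate,
  carbonate and amide I amplitudes and the phosphate FWHM per
  (week, bone, region).  Magnitudes are free parameters — no figure bars were
  read off — chosen once so the qualitative findings hold with clear margin:
  mineral-to-matrix strictly rising through weeks 0→5 in femur metaphyses;
  carbonate substitution up at week 2 (phosphate-to-carbonate below baseline)
  and down by week 5; carbonate-to-matrix elevated at all tumor weeks;
  crystallinity dipping at week 2 in femur while exactly unchanged in spine,
  then rising everywhere; diaphysis deviations scaled to 0.2× the metaphysis
  deviations; spine deviations largest in L5–S2 (other groups scaled 0.6×).
* **Variability.** Per spectrum: log-normal amplitude jitter (CV 2%), center
  jitter (SD 1 cm⁻¹), FWHM jitter (SD 0.4 cm⁻¹ phosphate, ~1 elsewhere).  Per
  subject: a log-normal per-band factor (CV 0.5%) that induces within-mouse
  correlation of band *ratios*.  These magnitudes are calibrated to the
  recovery tolerances below: with 3 subjects/week and ~30–60 spectra per
  (week, bone, region) class, per-class mean ratios must carry sampling error
  well under the 3% recovery tolerance.  A global per-mouse intensity scale
  would be removed by normalization and is not simulated.
* **Instrument.** White-light response: a broad bell in [0.5, 1.0] across the
  axis.  The stored substrate background is the *measured* substrate spectrum
  (intrinsic smooth curve × response), which is what subtracting a recorded
  substrate spectrum removes; with this convention the printed correction
  order (subtract, then divide) inverts the forward model exactly.
* **Noise.** Additive Gaussian with SD = 0.15 + 0.06·√signal (detector floor
  plus a shot-noise surrogate), giving peak SNR ≈ 100 — consistent with the
  300 s exposures of the emulated acquisition.  Cosmic rays: Poisson count
  (mean 0.3/spectrum), width 1–2 channels, amplitude 5–50× the local signal.
* **Ground truth.** Closed-form metrics per class: ratios of
  multiplier-adjusted apex amplitudes; crystallinity exactly 1/(configured
  phosphate FWHM).  With all noise and jitter scales at zero the simulated
  spectrum reduces to the band sum, and computed metrics converge to these
  values.

What the generator does **not** emulate: wavenumber miscalibration or drift,
detector etaloning, saturation, spatial heterogeneity within a site,
non-polynomial fluorescence shapes, and inter-animal biology beyond band-ratio
scaling.  Passing tests therefore demonstrate correctness of the pipeline's
inference under the stated forward model, not robustness to every artifact of
real acquisitions.

## Preprocessing

1. **Cosmic-ray removal.** Candidate channels exceed the running median
   (window 5, edges padded with the global median so rays on the first/last
   channels are still seen) by more than 8× the robust (MAD) SD of the median
   residual.  Two additional conditions separate rays from band apexes, whose
   residuals can also clear a globally estimated threshold under shot noise:
   the excess must be *isolated* (> 5× the excess two channels away on both
   sides) and *large relative to the local signal* (> 0.5× the local median).
   Flagged channels are replaced by linear interpolation from the nearest
   clean neighbors — the running median itself overshoots badly on steep band
   flanks.  Replicate-consensus despiking was rejected so single spectra can
   be processed.
2. **Substrate subtraction** and 3. **white-light division** are exact
   element-wise operations against the instrument profile; a non-positive
   response is an error.
3. **Fluorescence removal.** Iterative constrained polynomial fit (default
   order 5, tolerance 1e-6 of the input maximum, ≤ 100 iterations): fit by
   least squares, exclude channels rising more than twice the residual spread
   above the fit, refit until fit and exclusion set stabilize.  Excluding
   peak channels instead of clipping them to the fit keeps the polynomial
   centered in the noise of peak-free channels; the classic clip-to-fit
   iteration converges into the lower noise envelope and under-estimates the
   baseline by several percent.  On the default study the true order-5
   polynomial is recovered within ~1% relative RMS (≤ 0.1% noiseless).
   Non-convergence is flagged, not fatal.  Negative channels after
   subtraction are retained to keep noise statistics unbiased for PCA.
4. **Normalization** divides by the window maximum in 938–978 cm⁻¹ — cheap,
   monotone, idempotent and positive-scale invariant, and it makes the
   normalized apex exactly 1.

Running the steps in another order (e.g. removing fluorescence before the
response division) measurably worsens ground-truth recovery; the printed order
is kept and tested.

## Band quantification

Heights default to the apex of a pseudo-Voigt + linear-baseline least-squares
fit over the band window (`scipy.optimize.curve_fit`; initial values: window
argmax, edge-anchored window-max height, FWHM 15 cm⁻¹ for phosphate or a
third of the window span, fraction 0.5).  The plain local-baseline-corrected
window maximum remains available (`method="max"`) but is extreme-value biased
by up to +10% for broad noisy bands (the amide I window spans 49 channels) and
is used only as initial guess, fallback and positivity check.  Crystallinity
uses the fitted phosphate FWHM; if the fit fails, the interpolated
half-maximum crossing width is used and flagged.  Band windows are narrow
enough that neighboring-band cross-talk stays below ~1% with default widths;
no multi-peak decomposition is performed.

## Decision algorithm

Normalized spectra (or the 164 band-window channels — 27% of the 601-channel
axis — in the selected-feature variant) are centered and projected by PCA,
retaining the fewest components explaining ≥ 95% variance (cap 20).  An
RBF-SVM is trained on the scores with C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2³} (steps of
2²) selected by stratified 5-fold CV accuracy; the scan order is fixed and the
folds seeded, so selection is deterministic, with ties resolved toward the
first grid entry.  Multiclass handling is the SVM's built-in one-vs-one
voting.

Validation is leave-one-spectrum-out, run separately per bone region
(reproducing the region × week accuracy-table shape), with PCA refit inside
every fold.  Two hyperparameter modes exist: `nested` repeats the grid search
inside every fold's training set (leakage-free, the default) and `global` runs
it once on the full data before the loop — the comparability mode matching a
single global optimization, and roughly 40× cheaper.  Chance-level and
region-pattern results are indistinguishable between the modes; the heavy
study-level checks and the negative control use `global`.  Accuracies are
averaged per week within a region, then across weeks, then across regions
("overall accuracy" = mean of region averages).  Predictions are invariant to
input ordering (spectra are processed in id-sorted canonical order).

The negative control permutes the week labels (a permutation, preserving
class counts), reruns the full region-stratified protocol, and reports every
iteration's average accuracy and their maximum.  Two design points matter for
its stability.  First, the control randomizes the labels of the *developed*
algorithm: C and γ are selected once per region on the true labels and held
fixed across iterations; re-running the grid search on every permuted
labelling lets the optimizer chase chance structure and inflates the maximum
by several points.  Second, it is run on the whole study (femur and spine,
six region groups): a single-region control (~120 spectra) has a
20-iteration maximum spanning 0–37% across permutation draws, and even the
full femur set leaves a ~2.4-point per-iteration binomial SD whose
20-iteration maximum sits near 30%; averaging over all six region groups
halves that SD and concentrates the maximum at the 27–28% expected for the
maximum of twenty ~25%-mean draws.

## Group statistics and visualization

Fold changes are ratios of group means to the week-0 mean per (bone, region,
metric); their SD comes from the delta method on independent group means.
Group comparisons use the two-sided Student t-test (equal variance) by
default, Welch by flag; both published star conventions are provided
(* p<0.05, ** p<0.005; and * p<0.05, ** p<0.01, *** p<0.001) and none is
hard-coded.  No multiple-testing correction is applied by default, mirroring
per-comparison reporting; a Holm option exists.  The radial visualization
min–max normalizes each metric over the plotted table (a constant metric maps
to 0.5), anchors the four metrics at 90°, 0°, 270°, 180° on the unit circle,
and places each sample at the normalized-weight average of the anchors, so
all points lie in the unit disk.  Mean ± SD spectrum overlays are channelwise
with configurable vertical offsets.

## Problem sizes

The default study (3 subjects/week) yields 1140 spectra; simulation plus full
preprocessing takes a few seconds, the metric table ~10 s, a global-mode
femur LOOCV ~10 s, the nested variant ~6 min, and the 20-iteration negative
control ~3 min.  Test fixtures use 1 subject/week (380 spectra); Monte-Carlo
oracles use 100–500 draws.

## Known limitations

* The fitted-height convention, the exact baseline algorithm variant, the
  number of PCs, the hyperparameter grids and the nesting of the grid search
  are all conventions where the emulated study is silent; each is
  parameterized, defaulted as above, and documented rather than presented as
  a reproduction.
* Effect magnitudes in the generator are directions with convenient sizes,
  so absolute accuracy tables are not comparable to any published table —
  only structural and chance-level quantities are.
* The modified-polynomial baseline assumes fluorescence is polynomial of
  known order over the axis; strongly non-polynomial backgrounds would need a
  different estimator.
* Classification treats femur and spine separately; pooling bones in one
  classifier is untested territory.
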