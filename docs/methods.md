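# Methods

This note documents the models, default parameters and design choices
behind `trackrel`, and what its synthetic experiments do and do not
show about real fluoroscopy.

## Synthetic fluoroscopy

Projections follow a 2-D parallel-path Beer–Lambert model,
`I = i0 · exp(−Σ_m μ_m(E) · t_m)`, with precomputed per-material
path-length maps — not cone-beam ray tracing. That is sufficient to
create the phenomenon the pipeline must exercise (bone structures
occluding and corrupting the template match) while staying fast enough
to regenerate every dataset from a seed at test time.

Scene model (defaults in `PhantomSpec`):

* **Tissue slab** with a lateral elliptical body profile
  (160 mm max thickness), `μ = 0.017/0.022 mm⁻¹` at HE/LE.
* **Spine** (vertical) and **ribs** (horizontal, 44 px spacing,
  elliptical chord profiles). Bone coefficients are
  `0.035/0.0507 mm⁻¹`, chosen so the bone-cancelling weight
  `μ_bone(HE)/μ_bone(LE)` equals 0.69, the conventional weight for
  thorax-phantom subtraction; the physical dual-energy contrast
  condition (bone LE/HE ratio > tissue LE/HE ratio) is validated at
  construction. One rib sits 13 px inferior of the tumor rest
  position: clear at exhale (so breath-hold runs track cleanly) but
  crossed during breathing.
* **Spherical tumor** (5–15 mm) moving along the superior–inferior
  (row) axis, with an optional small lateral component.
* **Clutter**: static spheres of two kinds. Soft-tissue blobs
  (vessel-like, tumor-equivalent material) confuse both energy
  streams; bone blobs ("costal knobs" seated on rib lines) survive in
  SE frames but cancel under subtraction, and are the physical carrier
  of the SE-specific failure mode. Phantom datasets carry 12 bone
  knobs by default; patient-like difficulty classes mix both kinds.
* **Acquisition**: alternating HE/LE pulses at 15 fps (HE first), the
  LE frame of each pair rendered at its own, later timestamp and
  rigidly shifted by the inter-pulse offset (default 1 px), emulating
  gantry motion between the pulses of a pair. Gaussian photon noise
  with sd `scale·√I`. Incident fluence defaults: 5·10⁵ (phantom) and
  5·10⁴ (patient-like; noisier, as clinical frames are). No DE noise
  filtering is applied anywhere, so the fluence is chosen to carry the
  effective SNR of clinically processed frames.

Breathing uses the even-power model `z(t) = A·cos⁴(π(t−φ)/T)` with
`A = 7.5 mm` interpreted as peak-to-peak (a flag switches to the
half-range reading) and periods 5 s (slow) / 2.5 s (fast); the
patient-like mode draws per-cycle amplitude and period jitter
(±15%) and adds a linear baseline drift (0.05 mm/s), reducing exactly
to the smooth model when jitter and drift are zero.

## Dual-energy subtraction

Each HE/LE pair is aligned by exhaustive integer-translation search
maximizing mutual information (32-bin joint histogram), then combined
as `ln I_H − w_s · ln I_L` (intensities clamped at `10⁻⁶·i0`). The
study pipeline registers within an ROI spanning the tumor motion path
rather than globally: global MI is dominated by static bone and leaves
the tumor's own inter-pulse displacement uncorrected. Weights default
to 0.69 (phantom) and 0.42 (patient). The DE stack is min–max rescaled
to [0, 1] with *global sequence* statistics so template and search
frames share one scale; the affine rescale is recorded in metadata.

A known physical limitation survives by design: at fast breathing the
bright LE tumor ghost (amplitude `w_s·μ_L/μ_H ≈ 0.89` of the dark HE
blob at phantom weight) biases the correlation centroid by up to a few
times the inter-pulse displacement, producing occasional DE errors of
2–3 mm around peak velocity. This is the DE motion artifact of
fast-kV switching, and it is why the dedicated SE-vs-DE comparison
study uses the slow-breathing protocol, where the artifact stays below
the 2 mm reliability threshold.

## Tracking

Masked zero-normalized cross-correlation of a tumor template (derived
from a noiseless tumor-only reference render — the analog of a
planning-CT contour; disk mask = projected radius + 3 px). SE frames
are matched in log-intensity space, where line integrals are additive;
DE frames are already log-domain. The peak of the match surface gives
the predicted location (deterministic tie-break: smallest row, then
column; optional parabolic subpixel refinement, off by default) and the
peak value is the match score. Confidence is the peak-to-sidelobe
ratio, `(peak − mean(side)) / std(side)` with an 11×11 exclusion
window — the established correlation-filter convention.

The search window (±20 px by default; ±18 in the study configs) is
anchored at the reference (planned) tumor position, matching the
clinical setup in which the search region is programmed around the
planned target; this makes occlusion failures transient. A
follow-previous-position mode exists (`window_mode="follow"`) but with
periodic synthetic anatomy it suffers terminal mislocks. A frame is
*missing* when the surface is flat, the score falls below 0.3, or the
peak lies on the window boundary; all three criteria are configurable
and logged. Positions are reported in mm at isocenter
(detector mm ÷ (SDD/SAD), defaults 150/100 cm).

## Ground truth, TSR, quality bands

Phantom runs take the programmed waveform as ground truth (shared code
path with the generator). Patient-like runs estimate it: a per-axis
constant-acceleration Kalman filter over the tracked positions
(state [p, v, a]; white acceleration-noise spectral density
`q = 10 mm²/s⁵`, measurement variance `r = 1 mm²`, both artifact
choices selected by maximizing recovery of the irregular-breathing
generator — RMSE 0.73 mm under 1 mm measurement noise). Missing frames
receive predict-only steps, as do measurements rejected by a 3.5σ
innovation gate (the standard robust-filtering device). Filtering is
causal by default; an RTS smoother pass is available but off.

Because a filter built from the measurements cannot see smooth biases
or confidently locked mistracks — exactly the failures a human
reviewer corrects when refining an estimated ground truth — the
pipeline adds a reviewer surrogate: estimates departing more than 2 mm
from the simulated actual trajectory are corrected to it, while
sub-threshold subtleties stay uncorrected. An automated outlier report
(4σ robust deviations of measurement vs estimate) is produced
alongside and never auto-corrects.

A frame is reliable when its Euclidean error versus the reference is
strictly below 2 mm. TSR is the percentage of *tracked* frames that
are reliable; missing frames are excluded from the denominator and
reported as a separate MF count. Patient-like datasets are stratified
by their SE-stream TSR into poor (< 59.5), moderate (59.5–78.0,
closed) and good (> 78.0); the arithmetic midpoints of the phantom
size baselines (47.6/72.2/84.2 → 59.9/78.2) are available through
`quality_midpoints`, and both threshold pairs live in `QualityBands`.

## Features and model

Per tracked frame: match score, PSR, and central-difference velocities
over the tracked frames' actual timestamps (mm/s at isocenter;
endpoints and gap-adjacent frames use the available side; gaps are not
interpolated and missing frames contribute no rows). The match score
is standard-scaled (population std); PSR and velocities, being
outlier-prone, are robust-scaled (median/IQR, with an automatic
std-based fallback when the IQR degenerates). Scalers are fit per
domain on training rows only and reapplied unchanged to validation
data.

The design matrix columns are fixed to `x1..x4, DI, DI·x1..DI·x4`
(phantom rows have the last five identically zero). Fitting minimizes
the weighted mean cross-entropy plus `λ·R(β)` with the intercept
unpenalized; `R` is L1, L2 (Σβ²), or the elastic-net mix
`l1_ratio·Σ|β| + (1−l1_ratio)·Σβ²`. Two optimizers honor the same
loss: FISTA (proximal gradient with Nesterov momentum and a Lipschitz
step; deterministic default) and a seeded proximal SGD with tail
averaging. Defaults: `λ = 0.01`, L2. Sample weights: phantom and
good-band 1.0, moderate 0.6, poor 0.2 (sweep grids 0.4–0.8 / 0.1–0.3
available through `sweep_weights_and_hyper`, which selects by mean
validation sensitivity subject to the specificity target).

Cross-validation leaves one patient-like dataset out per fold
(phantom runs stay in every training set); scalers, model, and
per-domain 95%-specificity cutoffs (smallest cutoff whose training
specificity reaches the target — deterministic and conservative toward
false positives) are all refit per fold, and final operating cutoffs
are fold averages. Coefficient intervals are 2.5/97.5 percentiles
across folds. Evaluation reports confusion counts, sensitivity
`TP/(TP+FN)`, specificity `1 − FP/(TN+FP)`, and trapezoidal AUC; a
metric with an empty denominator is reported absent, not zero. The
paired SE-vs-DE comparison uses an exact McNemar test (binomial test
on discordant frame-level correctness) and a matched-specificity
sensitivity (sensitivity at the smallest cutoff reaching 95%
specificity), which is robust to the threshold-averaging noise of
small negative counts.

## Study configurations and problem sizes

* Default study: 96×96 px frames (0.776 mm detector pixels,
  magnification 1.5), 120 pulses per dataset, 9 phantom runs
  (3 sizes × stationary/slow/fast) and 20 patient-like datasets with a
  good/moderate/poor difficulty mix; 3 datasets (one per realized
  band) held out.
* Fixture (`make_fixtures`): 48 pulses, 6 phantom runs, 9 patient-like
  datasets, 3 held out; completes in ~20 s and spans all three bands.
* Direction-of-effect replicate (`StudyConfig.replicate`): slow
  breathing only, 56 pulses, 3 phantom + 4 patient-like datasets,
  20 costal knobs — the configuration in which bone overlap, not the
  fast-motion artifact, dominates SE failure.

Patient-like difficulty is a generator *design*, not an assignment:
poor = 5 mm tumor, 40 clutter blobs, rib mid-path; moderate = 6 mm,
34 blobs, rib near peak inhale; good = 13 mm, 12 blobs, rib clear.
The realized band is always measured from the SE TSR.

## What passing tests do and do not show

The generator reproduces the *mechanisms* that matter — bone occlusion
degrading SE matching, dual-energy cancellation restoring it,
noise-driven confusion with vessel-like clutter, irregular breathing,
subtraction motion artifacts — but not the texture statistics, scatter,
detector lag, or anatomy deformation of real fluoroscopy. Passing
tests therefore demonstrate that the pipeline's statistics behave as
designed under controlled conditions (oracle-verified matching,
calibrated thresholds, coefficient recovery, the SE-vs-DE ordering at
matched specificity), not that the fitted coefficients transfer to
clinical data. Absolute sensitivities depend on the synthetic
difficulty mix and should be read relative to each other, not as
clinical performance claims.

Known limitations: sustained mislocks onto static structures are
invisible to any self-referential estimated ground truth and are
handled here by the reviewer surrogate (which uses the simulator's
actual trajectory); the fast-breathing DE motion artifact produces
borderline 2–3 mm errors with pristine appearance, which no
feature-based model can flag; and with few unreliable frames in a
domain, the 95%-specificity operating point is estimated from a small
negative sample and is accordingly noisy.
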