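# trackrel

Reliability assessment of markerless lung-tumor tracking (MTT) on
single-energy (SE) and dual-energy (DE) kilovoltage fluoroscopy.

During lung SBRT, template-based tracking follows the tumor on kV
projections without implanted fiducials, but overlying ribs and spine
can pull the match off target. Fast-kV switching acquires alternating
low/high-energy pulses (60/120 kV at 15 fps), and weighted logarithmic
subtraction of each pair,

```
DE = ln I_H − w_s · ln I_L
```

cancels the bone signal (`w_s` = bone attenuation ratio
`μ_bone(HE)/μ_bone(LE)`), yielding a bone-suppressed DE stream at
7.5 fps. The question this package addresses: **frame by frame, can the
tracked position be trusted?**

For each tracked frame the pipeline extracts the NCC match score,
peak-to-sidelobe ratio (PSR), and x/y velocities, labels the frame
*reliable* when its error against the reference trajectory is < 2 mm,
and fits a domain-adapted, sample-weighted logistic model

```
P(reliable) = σ(β₀ + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄ + β₅·DI
                 + β₆·DI·x₁ + β₇·DI·x₂ + β₈·DI·x₃ + β₉·DI·x₄)
```

where `DI` is a domain indicator (phantom = 0, patient-like = 1) whose
interaction terms let one model adapt between the controlled phantom
domain and irregular patient-like breathing. Training minimizes the
sample-weighted cross-entropy plus an L1/L2/elastic-net penalty;
patient-like datasets are weighted by tracking quality (good 1.0,
moderate 0.6, poor 0.2) as stratified from the tracking success rate
(TSR, % of tracked frames with error < 2 mm). The operating cutoff is
chosen per domain on each training fold to reach 95% specificity and
averaged across leave-one-dataset-out folds.

Because clinical images of this kind cannot be shared, the package
ships a synthetic fluoroscopy generator (thorax-like background, ribs
and spine, spherical tumors of 5–15 mm, cos⁴ breathing with optional
cycle jitter and drift, photon noise, inter-pulse misregistration) with
known true trajectories, so the whole pipeline is exercised end to end
on data it can regenerate from a seed.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from trackrel import StudyConfig, run_study

bundle = run_study(StudyConfig.small(seed=1, n_holdout=3))
m = bundle["study"]["matched_specificity_sensitivity"]
print(f"SE pooled sensitivity @95% spec: {m['SE']['pooled']:.3f}")
print(f"DE pooled sensitivity @95% spec: {m['DE']['pooled']:.3f}")
print(bundle["datasets"][["dataset_id", "band", "tsr_se", "tsr_de"]].tail(5))
```

prints

```
SE pooled sensitivity @95% spec: 0.640
DE pooled sensitivity @95% spec: 0.695
    dataset_id   band     tsr_se     tsr_de
10  patient_05   poor  37.500000  37.500000
11  patient_06   poor  33.333333   8.333333
12  patient_07   good  86.666667  94.117647
13  patient_08   good  79.166667  66.666667
14  patient_09   poor  25.000000  33.333333
```

i.e. on this miniature paired study, the DE model keeps more truly
reliable frames (sensitivity 0.695 vs 0.640) at the same 95%-specificity
operating point, and the patient-like arm spans the three
tracking-quality bands (poor < 59.5% ≤ moderate ≤ 78.0% < good) used to
weight training samples.

A command-line interface covers the individual stages
(`trackrel simulate | desub | track | truth | run`); `trackrel run
--out <dir> --seed N` writes model-fit JSONs, per-dataset TSR/band
tables, training and held-out reports, and a run manifest.

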