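# motioncpm

Connectome-based prediction of head motion in fMRI.

Head motion during scanning is not just a nuisance: how much a person
moves in the scanner behaves like a stable, subject-level trait, and the
functional connectome itself carries enough information to predict it.
`motioncpm` implements the full analysis chain for studying this
phenomenon — from rigid-body realignment parameters and ROI timeseries to
cross-validated prediction of motion summaries and the extraction of
*motion-sensitive networks* — together with a synthetic-cohort generator
so that every stage can be exercised and validated without access to
restricted cohort data.

It is aimed at neuroimaging methodologists who work at the ROI-timeseries
level (the package deliberately does not ingest 4D NIfTI volumes).

## What it computes

**Motion metrics.** From each frame's translations (x, y, z, mm, relative
to the first volume) and rotations (α, β, γ, radians):

- absolute displacement d_i = √(x_i² + y_i² + z_i²),
- relative displacement Δd_i = √((x_i−x_{i−1})² + (y_i−y_{i−1})² + (z_i−z_{i−1})²),
- framewise displacement
  FD_i = |Δx_i| + |Δy_i| + |Δz_i| + 50 mm · (|Δα_i| + |Δβ_i| + |Δγ_i|),
  with rotations converted to arc length on a 50 mm sphere.

Frames are censored ("scrubbed") when the frame-to-frame RMS BOLD change
exceeds 0.5 % **and** FD_i exceeds 0.5 mm (0.2 mm for strict scrubbing;
an "either" rule is available).  Subject-level summaries are the RMS of
d and Δd over the first 150 surviving frames pooled across scans.

**Connectomes.**  Per-node demean/detrend, optional regression of the six
realignment parameters, optional global signal regression, zero-phase
low-pass filtering (0.10 Hz), Pearson correlation over surviving frames,
Fisher transformation z = atanh(r), and element-wise averaging of the
LR/RL phase-encoding scans.

**CPM.**  Connectome-based predictive modeling in four nested steps:
edge-wise feature selection against the motion score (two-sided
parametric p < 0.01), summation of selected edges into positive (X) and
negative (Y) network strengths, a bilinear model

    Ψ = a + bX + cY

(restricted variants fix c = 0 or b = 0), and assessment by
leave-one-out or twofold (train/test swap) cross-validation.  Statistical
inference uses Bonferroni-corrected critical correlations
(`critical_r(207, 0.05, 16)` → 0.204), fully nested permutation nulls,
and Williams's / Steiger's tests for dependent correlations.

**Motion-sensitive networks.**  Edges selected in at least a configured
fraction of session/sample mask sets, summarized by node degree (hubs),
with fixed-coefficient application to new cohorts for external
validation, and within-/between-network restricted prediction over a
node partition.

**Synthetic cohorts.**  Subjects carry a log-normal motion trait driving
a bounded random walk (plus spikes) in their realignment parameters;
connectivity is shifted on a planted edge set in proportion to the
standardized motion score (in Fisher-z units); an optional global
artifact proportional to Δd mimics motion artifacts.  A geometric
simulator also produces displacement-only datasets (rigid transform
applied to a voxel grid, parcel-averaged) as a negative control.

## Worked example

```bash
python examples/simulate_and_predict.py
```

```
cohort: 60 subjects, 435 edges, 40 motion-coupled
LOO-CPM accuracy: R = 0.966 (rho = 0.974, p = 6.69e-36)
degenerate folds: 0
```

Sixty synthetic subjects are generated whose connectivity is shifted on
40 planted edges by 0.5 z-units per SD of their relative-motion score
(RMS Δd).  The full pipeline — censoring, cleaning, Fisher-z
connectomes, LR/RL averaging — feeds nested leave-one-out CPM.  R is the
Pearson correlation between observed and predicted motion across the 60
held-out predictions: 0.97 means the planted motion–connectome coupling
is recovered almost perfectly.  The other scripts in `examples/` walk
through motion metrics and censoring, permutation nulls, motion-sensitive
network extraction with hub tables, and the displacement-only negative
control.

A thin CLI mirrors the pipeline for file-based cohorts
(`motioncpm simulate | motion | connectome | cpm-train | cpm-predict |
permute | networks | overlap | apply`); see `motioncpm --help`.

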