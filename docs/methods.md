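# Methods

This note documents the models, parameters, and numerical choices behind
`motioncpm`, and what the synthetic cohorts do and do not establish.

## Motion metrics and censoring

Absolute displacement d uses translations only, measured from the first
volume; rotations enter only framewise displacement FD, converted to arc
length on a sphere of radius 50 mm (configurable `sphere_radius`).  Δd
and FD are undefined at frame 0 and reported as NaN, never as zero; a
single-frame series therefore has no Δd/FD.

Censoring combines two per-frame criteria: FD above `fd_threshold`
(default 0.5 mm; 0.2 mm for strict scrubbing) and frame-to-frame RMS
BOLD change above `bold_change_threshold` (default 0.5 %).  The default
`censor_rule="both"` requires both exceedances (a conjunctive reading of
the protocol); `"either"` is available as a variant.  The BOLD-change
series is computed on cleaned-but-unfiltered signals.  Frame 0 is never
censored (no predecessor).  Censoring selects which frames enter
summaries and correlation; it does not redefine Δd — the value at the
first surviving frame after a gap is still the realignment-series
neighbour difference.

RMS summaries take the first `frames_keep` (default 150) surviving
frames per scan and, under the default `summary_style="pooled"`, pool
frames across scans before a single RMS.  The `per_scan_mean` style (one
RMS per scan, then averaged) is exposed because the protocol wording is
compatible with both; differences are second-order.

## Timeseries cleaning and connectivity

Cleaning order is fixed: per-node demean + linear detrend → regression
of the six realignment parameters (no derivatives or squares) → global
signal regression → low-pass filter.  GSR before filtering is a
documented choice; no switch is exposed.  The filter is a 4th-order
Butterworth at `lowpass_cutoff` (default 0.10 Hz) applied
forward-backward (zero phase), so the effective amplitude response is
|H(f)|² and artifact frames are not shifted relative to the censor mask.
Filtering happens before censored-frame deletion, so the filter never
runs across gaps; censored frames are deleted, not interpolated.

Pearson correlations on the first `frames_keep` surviving frames are
Fisher-transformed with |r| clipped at 1 − 1e-7 to keep z finite; the
diagonal is zeroed and excluded everywhere.  LR/RL matrices of a session
are averaged element-wise.  Edges are vectorized over the strict upper
triangle, row-major with i < j.

## CPM

Feature selection correlates every edge with the motion score and keeps
edges with two-sided parametric p < `selection_p` (default 0.01),
routed by sign into positive/negative masks.  Thresholding is
implemented on |r| via the exact t-quantile transform, which is
arithmetically identical to thresholding the p-value and allows an
O(n_edges) leave-one-out update from per-edge sufficient statistics
(sums and cross-products minus the held-out subject's contribution).
The fast path is verified against a literal fold-by-fold reference to
1e-10.

Network strengths are plain sums of selected edge z-values.  The model
is ordinary least squares of the score on (1, X, Y); restricted variants
use (1, X) or (1, Y).  In leave-one-out CV both selection and fitting
are nested inside every fold.  Folds whose required masks are empty (or
whose strengths are constant) predict the fold-mean score and are
counted; a run where every fold is degenerate is flagged invalid rather
than reporting the spurious R that fold-means alone produce.  If exactly
one strength column is constant in a bilinear fold, the fold falls back
to the informative restricted variant instead of fitting a
rank-deficient design.

Permutation inference reruns the complete nested LOO pipeline on each
shuffled score vector — the expensive but faithful choice — with all
randomness drawn from `rng_seed`; empirical p-values use the +1
correction and are never zero.  Critical correlations come from the
t-distribution with n − 2 df: r* = t*/√(t*² + n − 2) at the
Bonferroni-corrected level.  Williams's t (shared-variable dependent
correlations, df = n − 3) and Steiger's z (no shared variable, Dunn–
Clark covariance of Fisher z's) are both validated by simulated null
calibration at α = 0.05; the Steiger statistic reduces exactly to the
independent-samples Fisher z-difference when all cross-correlations are
zero.

## Motion-sensitive networks

The overlap network keeps edges present in at least `overlap_fraction`
(default 0.5) of the supplied per-session/per-sample mask sets,
independently for positive and negative masks.  The protocol literature
uses both 25 % and 50 % thresholds and both 8- and 16-set poolings, so
the fraction and the mask-set list are caller-supplied configuration,
with 0.5 as default.  An edge qualifying on both sides is assigned to
the side with the higher count; exact ties are dropped to keep the lists
disjoint.  The count-vs-fraction comparison subtracts 1e-9 so that an
edge present in exactly the threshold fraction is retained despite
floating-point representation of the fraction.  Hub tables rank nodes by
degree over the union of both edge lists, ties broken by node index;
coordinates come from optional node metadata (none is shipped).

## Synthetic cohorts

The generator emulates the statistical skeleton the analysis assumes,
not fMRI physics:

- **Motion trait**: m_j ~ log-normal(`trait_log_mean`=0,
  `trait_log_sd`=0.5), the premise that motion is a stable subject
  trait.
- **Realignment**: translations follow an AR(1)-bounded random walk
  (φ = 0.95) with step scale `walk_sd`·m_j (default 0.02 mm) plus spikes
  (rate 0.02, scale 0.3 mm·m_j); rotations analogous at `rot_scale`
  (2e-4 rad).  With these defaults median RMS Δd ≈ 0.03–0.04 mm,
  matching task-fMRI relative motion; the first frame is exactly zero.
- **Cohort geometry**: 207 subjects × 2 scans (LR/RL) × 176 frames at
  TR = 0.72 s by default; the default parcellation is 60 nodes (1,770
  edges), chosen so edge-level statistics are meaningful while cohorts
  simulate in seconds — full 268-node connectomes are supported but not
  the default.
- **Coupling**: the true score (RMS Δd by default, RMS d optionally) is
  computed from the generated realignment *via the pipeline's own
  metric code*, standardized across the cohort, and added to the base
  correlation matrix on the planted edges in Fisher-z space
  (`coupling_strength` z-units per SD), then mapped back through tanh —
  this keeps entries in (−1, 1) and makes the planted effect linear in
  the same units the analysis measures.  The shifted matrix is projected
  to the nearest correlation matrix by eigenvalue clipping at 1e-8 with
  diagonal renormalization.
- **Signals**: node timeseries realize the subject's correlation matrix
  via its symmetric factor applied to white noise (unit variance,
  amplitude 1 on a baseline of 100, i.e. ~1 % fluctuations), plus
  independent noise (`noise_sd`=0.5) and a global artifact of
  `artifact_gain` (default 5 %/mm) of baseline per mm of Δd.

What passing tests on these cohorts show: the pipeline recovers planted
linear motion–connectivity coupling, localizes it to the correct network
cells, controls type-I error without coupling, and generalizes fixed
networks across cohorts sharing the planted structure.  What they do not
show: behaviour under hemodynamics, task structure, spatially structured
artifacts, scanner noise spectra, or real inter-subject FC variability —
conclusions about real data rest on the published analyses, not on these
simulations.  Because the added `noise_sd` white noise attenuates all
correlations by 1/(1 + noise_sd²), the generator's target matrix is the
correlation of the *neural component*; consistency checks against the
target are run with `noise_sd = 0`.

The displacement simulator applies each frame's rigid transform
(intrinsic x–y–z rotation order about the volume center — at
micro-motion scales order effects are ≪ 1 µm) to a voxel lattice
(default 20×20×20 at 8 mm pitch, ±76 mm) and averages ‖(R_i v + t_i) −
v‖ within parcels.  No re-registration of the simulated series is
performed; they are generated directly in the analysis frame.

## Problem sizes

Routine tests use 30–60 node cohorts of 50–120 subjects; the recovery
and contrast studies use n = 200/80 with 40 nodes; the permutation-null
study uses the full n = 207 with 5,000 edges and 200 permutations,
feasible because the per-fold selection update is O(n_edges).

## Known limitations

- Realignment dialect detection is never guessed; the caller states
  `hcp` or `mcflirt`.  Whether upstream rotation columns were degrees or
  radians cannot be verified from the numbers alone.
- The conjunctive censoring default and the pooled RMS summary are
  documented readings of ambiguous protocol wording; both alternatives
  are configuration switches, and results near threshold can differ.
- The permutation-null width depends strongly on the across-subject
  dependence structure of the edges: independent edge features give a
  much wider null (≈ 0.20 at n = 207) than strongly inter-correlated
  real connectomes (published ≈ 0.09), because nested selection overfits
  each fold more when features are independent.  Null widths should
  always be computed on data with the dependence structure of interest.
- Under the null, leave-one-out fold-mean effects make the assembled
  predictions anti-correlate with observed scores; R near −1 in
  degenerate cells is an artifact of this and is why all-degenerate runs
  are flagged invalid.
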