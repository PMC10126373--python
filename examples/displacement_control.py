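"""Displacement-only data as a negative control for motion prediction.

Applies each frame's rigid-body transform to a voxel grid and averages the
per-voxel displacement magnitude within parcels, producing timeseries that
contain motion geometry but no BOLD signal.  Connectomes built from such
data should predict motion far worse than BOLD cohorts with genuine
motion-coupled connectivity — evidence that CPM accuracy reflects more
than motion geometry itself.
"""

import numpy as np

import motioncpm as mc

n_nodes, n_subjects = 30, 50
n_edges = n_nodes * (n_nodes - 1) // 2
picker = np.random.default_rng(99)
planted = tuple(sorted(picker.choice(n_edges, 40, replace=False).tolist()))
spec = mc.SyntheticSpec(n_subjects=n_subjects, n_nodes=n_nodes, n_frames=150,
                        coupling_edges=planted, coupling_strength=0.5,
                        artifact_gain=0.0, seed=13)
cfg = mc.RunConfig(rng_seed=13)
cohort = mc.simulate_cohort(spec)
scores = cohort.scores_rms_dd

bold_edges = mc.cohort_edge_matrix(cohort, cfg)

grid = mc.regular_grid(n_side=10, pitch=16.0, n_parcels=n_nodes)
rows = []
for subj in cohort.subjects:
    mats = [mc.connectivity_matrix(
        mc.simulate_displacement_dataset(series, grid), None,
        cfg.frames_keep) for series in subj.realignment]
    rows.append(mc.edge_vectorize(mc.average_scans(*mats)).values)
disp_edges = np.vstack(rows)

bold = mc.loo_cv(bold_edges, scores, cfg)
disp = mc.loo_cv(disp_edges, scores, cfg)
print(f"BOLD cohort (planted coupling): LOO R = {bold.pearson_r:.3f}")
print(f"displacement-only cohort:       LOO R = {disp.pearson_r:.3f}")
print("\nPearson correlation is scale-invariant, so the displacement")
print("connectome encodes little about *how much* a subject moved —")
print("prediction from motion geometry alone is far weaker than from")
print("BOLD connectivity with genuine motion coupling.")
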