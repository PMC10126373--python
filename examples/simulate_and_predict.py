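"""Simulate a motion-coupled cohort and predict motion with nested CPM.

Generates a small synthetic cohort whose connectivity is shifted on 40
planted edges in proportion to each subject's relative-motion score,
builds censored Fisher-z connectomes through the full pipeline, and runs
leave-one-out CPM.  The Pearson R between observed and predicted motion
shows how well the planted coupling is recovered.
"""

import numpy as np

import motioncpm as mc

n_nodes = 30
n_edges = n_nodes * (n_nodes - 1) // 2
picker = np.random.default_rng(99)
planted = tuple(sorted(picker.choice(n_edges, 40, replace=False).tolist()))

spec = mc.SyntheticSpec(n_subjects=60, n_nodes=n_nodes, n_frames=150,
                        coupling_edges=planted, coupling_strength=0.5,
                        artifact_gain=0.0, seed=21)
cohort = mc.simulate_cohort(spec)
cfg = mc.RunConfig(rng_seed=21)

edges = mc.cohort_edge_matrix(cohort, cfg)   # subjects x edges, Fisher z
scores = cohort.scores_rms_dd                # RMS frame-to-frame motion, mm

result = mc.loo_cv(edges, scores, cfg)
print(f"cohort: {spec.n_subjects} subjects, {n_edges} edges, "
      f"{len(planted)} motion-coupled")
print(f"LOO-CPM accuracy: R = {result.pearson_r:.3f} "
      f"(rho = {result.spearman_rho:.3f}, p = {result.pearson_p:.2e})")
print(f"degenerate folds: {result.n_degenerate_folds}")
print("\nR near 1 means the connectome carries enough motion-coupled "
      "signal to rank subjects by how much they move.")
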