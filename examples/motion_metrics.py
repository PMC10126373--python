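"""Per-frame motion metrics and censoring from realignment parameters.

Builds a tiny realignment series with one obvious movement spike, computes
absolute displacement d, frame-to-frame displacement Δd, and framewise
displacement FD (50 mm sphere), then shows which frames the default
censoring rule would scrub.
"""

import numpy as np

import motioncpm as mc

translations = np.zeros((8, 3))
translations[4] = [0.4, 0.3, 0.0]   # a 0.5 mm excursion at frame 4
rotations = np.zeros((8, 3))
rotations[4, 2] = 0.004             # plus a 0.23-degree roll

series = mc.RealignmentSeries(translations, rotations, tr=0.72)
trace = mc.motion_trace(series, sphere_radius=50.0)

print("frame   d (mm)  dd (mm)  FD (mm)")
for i in range(series.n_frames):
    print(f"{i:5d}  {trace.d[i]:7.3f}  {trace.dd[i]:7.3f}  {trace.fd[i]:7.3f}")

# censor when FD > 0.5 mm AND the BOLD frame change exceeds 0.5 %
cfg = mc.RunConfig()
rng = np.random.default_rng(0)
bold = 100 + rng.normal(0, 0.2, (10, 8))
bold[:, 4] += 1.5                    # signal jump at the moving frame
mask = mc.censor_mask(trace, mc.bold_frame_change(bold), cfg)
print("\ncensored frames:", np.where(~mask.keep)[0].tolist())

summary = mc.summarize_motion([trace], [mask], cfg.frames_keep)
print(f"RMS d = {summary.rms_d:.4f} mm, RMS dd = {summary.rms_dd:.4f} mm "
      f"over {summary.n_frames_used} surviving frames")
print("\nFD at the spike is the L1 translation change plus 50 mm times the")
print("rotation change; the frame is scrubbed because both the FD and the")
print("BOLD-change thresholds are exceeded.")
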