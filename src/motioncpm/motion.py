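"""Per-frame head-motion metrics, censoring, and RMS summaries.

Motion is quantified from the six rigid-body realignment parameters of each
frame: translations x, y, z (mm) relative to the first volume and rotations
alpha, beta, gamma (radians).  Three per-frame metrics are derived:

* ``d_i``  — absolute displacement, the Euclidean norm of the frame's
  translation vector (measured from the first volume);
* ``dd_i`` — relative displacement, the Euclidean norm of the
  frame-to-frame translation difference;
* ``FD_i`` — framewise displacement, the L1 sum of absolute translation
  increments plus rotation increments converted to arc length on a sphere
  (50 mm radius by default).

Frames are censored ("scrubbed") when both the framewise displacement and
the frame-to-frame RMS BOLD signal change exceed their thresholds (an
"either" rule is available as a configuration variant).  Subject-level
summaries are the RMS of d and Δd over the first ``frames_keep`` surviving
frames pooled across scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import RunConfig
from .exceptions import DegenerateDataError, DimensionError, ValidationError


@dataclass
class RealignmentSeries:
    """Rigid-body realignment parameters for one scan.

    ``translations`` is (n_frames, 3) in mm, ``rotations`` (n_frames, 3) in
    radians, both relative to the first volume.  ``tr`` is the repetition
    time in seconds.
    """

    translations: np.ndarray
    rotations: np.ndarray
    tr: float = 0.72
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValidationError("translations must be (n_frames, 3)")
        if self.rotations.shape != self.translations.shape:
            raise DimensionError("rotations and translations shapes differ")
        if self.n_frames < 1:
            raise ValidationError("a realignment series needs at least one frame")
        if not (np.isfinite(self.translations).all()
                and np.isfinite(self.rotations).all()):
            raise ValidationError("realignment parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class MotionTrace:
    """Per-frame motion metrics; ``dd`` and ``fd`` are NaN at frame 0."""

    d: np.ndarray
    dd: np.ndarray
    fd: np.ndarray
    sphere_radius: float
    scan_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.d.shape[0]


@dataclass
class CensorMask:
    """Keep/censor flags per frame plus the thresholds that produced them."""

    keep: np.ndarray
    fd_threshold: float
    bold_change_threshold: float
    censor_rule: str

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    @property
    def n_frames(self) -> int:
        return self.keep.shape[0]

    @classmethod
    def all_keep(cls, n_frames: int) -> "CensorMask":
        """A mask that censors nothing (e.g. for synthetic inputs)."""
        return cls(np.ones(n_frames, dtype=bool), np.inf, np.inf, "both")


@dataclass
class MotionSummary:
    """RMS motion summaries for one subject-session (pooled across scans)."""

    rms_d: float
    rms_dd: float
    n_frames_used: int
    subject_id: str = ""
    session_id: str = ""


def motion_trace(series: RealignmentSeries,
                 sphere_radius: float = 50.0) -> MotionTrace:
    """Compute d, Δd and FD for every frame of a realignment series.

    d_i = sqrt(x_i² + y_i² + z_i²);
    Δd_i = sqrt((x_i − x_{i−1})² + (y_i − y_{i−1})² + (z_i − z_{i−1})²);
    FD_i = |Δx_i| + |Δy_i| + |Δz_i| + r·(|Δα_i| + |Δβ_i| + |Δγ_i|)
    with r = ``sphere_radius`` converting rotation increments (radians) to
    arc length in mm.  Frame 0 has no predecessor: Δd and FD are NaN there
    (marked unavailable, never zero).
    """
    t = series.translations
    d = np.linalg.norm(t, axis=1)
    n = series.n_frames
    dd = np.full(n, np.nan)
    fd = np.full(n, np.nan)
    if n >= 2:
        dt = np.diff(t, axis=0)
        dr = np.diff(series.rotations, axis=0)
        dd[1:] = np.linalg.norm(dt, axis=1)
        fd[1:] = np.abs(dt).sum(axis=1) + sphere_radius * np.abs(dr).sum(axis=1)
    return MotionTrace(d=d, dd=dd, fd=fd, sphere_radius=sphere_radius,
                       scan_id=series.scan_id)


def bold_frame_change(values: np.ndarray) -> np.ndarray:
    """Frame-to-frame RMS BOLD signal change in percent.

    ``values`` is (n_nodes, n_frames).  For frame i ≥ 1 the value is the
    RMS over nodes of ``100 · (s[n,i] − s[n,i−1]) / mean_n`` where
    ``mean_n`` is node n's timeseries mean.  Frame 0 is NaN.

    Raises :class:`DegenerateDataError` if any node mean is ≤ 0 (percent
    change undefined).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("values must be (n_nodes, n_frames)")
    if values.shape[1] < 2:
        raise ValidationError("need at least two frames")
    means = values.mean(axis=1)
    bad = np.where(means <= 0)[0]
    if bad.size:
        raise DegenerateDataError(
            f"percent change undefined: non-positive mean at nodes {bad.tolist()}")
    pct = 100.0 * np.diff(values, axis=1) / means[:, None]
    out = np.full(values.shape[1], np.nan)
    out[1:] = np.sqrt(np.mean(pct ** 2, axis=0))
    return out


def censor_mask(trace: MotionTrace, bold_change: np.ndarray,
                cfg: RunConfig) -> CensorMask:
    """Flag frames for exclusion from connectivity and summaries.

    Under the default ``censor_rule="both"`` a frame is censored iff
    FD_i > ``fd_threshold`` *and* the BOLD change exceeds
    ``bold_change_threshold``; ``"either"`` censors on either exceedance.
    Frame 0 (no predecessor) is always kept.
    """
    bold_change = np.asarray(bold_change, dtype=float)
    if bold_change.shape[0] != trace.n_frames:
        raise DimensionError(
            f"bold_change length {bold_change.shape[0]} does not match "
            f"trace length {trace.n_frames}")
    with np.errstate(invalid="ignore"):
        over_fd = trace.fd > cfg.fd_threshold
        over_bold = bold_change > cfg.bold_change_threshold
    if cfg.censor_rule == "both":
        censor = over_fd & over_bold
    else:
        censor = over_fd | over_bold
    censor[0] = False
    return CensorMask(~censor, cfg.fd_threshold, cfg.bold_change_threshold,
                      cfg.censor_rule)


def summarize_motion(traces: Sequence[MotionTrace],
                     masks: Sequence[CensorMask],
                     frames_keep: int = 150,
                     summary_style: str = "pooled",
                     subject_id: str = "",
                     session_id: str = "") -> MotionSummary:
    """RMS summaries of d and Δd over surviving frames, across scans.

    Per scan the first ``frames_keep`` surviving frames are taken; with the
    default ``pooled`` style the frames of all scans are pooled and a single
    RMS computed (Δ-undefined frames are excluded from rms_dd); the
    ``per_scan_mean`` style computes one RMS per scan and averages the
    scans.  Censoring selects which frames are summarized — Δd at a frame
    after a censored gap is still the realignment-series neighbour
    difference.
    """
    if len(traces) != len(masks) or not traces:
        raise DimensionError("need equally many traces and masks, at least one")
    d_pools: list[np.ndarray] = []
    dd_pools: list[np.ndarray] = []
    n_used = 0
    for trace, mask in zip(traces, masks):
        if mask.n_frames != trace.n_frames:
            raise DimensionError("mask length does not match trace length")
        surviving = np.where(mask.keep)[0][:frames_keep]
        if surviving.size == 0:
            raise DegenerateDataError(
                f"no surviving frames for subject={subject_id!r} "
                f"session={session_id!r} scan={trace.scan_id!r}")
        n_used += surviving.size
        d_pools.append(trace.d[surviving])
        dd_scan = trace.dd[surviving]
        dd_pools.append(dd_scan[np.isfinite(dd_scan)])
    if summary_style == "pooled":
        d_all = np.concatenate(d_pools)
        dd_all = np.concatenate(dd_pools)
        rms_d = float(np.sqrt(np.mean(d_all ** 2)))
        rms_dd = float(np.sqrt(np.mean(dd_all ** 2))) if dd_all.size else float("nan")
    else:
        rms_d = float(np.mean([np.sqrt(np.mean(p ** 2)) for p in d_pools]))
        rms_dd = float(np.mean([np.sqrt(np.mean(p ** 2))
                                for p in dd_pools if p.size]))
    return MotionSummary(rms_d=rms_d, rms_dd=rms_dd, n_frames_used=n_used,
                         subject_id=subject_id, session_id=session_id)
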