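"""End-to-end helpers: cohort → motion summaries → edge matrix.

These functions chain the per-stage operations in the documented order for
a whole cohort, either in memory (a :class:`~motioncpm.synthetic.SyntheticCohort`)
or from files listed in a :class:`~motioncpm.io.CohortManifest`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .connectome import (ROITimeseries, average_scans, connectivity_matrix,
                         edge_vectorize, preprocess)
from .io import CohortManifest, read_realignment, read_roi_timeseries
from .motion import (CensorMask, MotionSummary, RealignmentSeries,
                     bold_frame_change, censor_mask, motion_trace,
                     summarize_motion)
from .synthetic import SyntheticCohort


@dataclass
class SubjectData:
    """In-memory inputs for one subject-session (any number of scans)."""

    subject_id: str
    realignment: list[RealignmentSeries]
    timeseries: list[ROITimeseries]


def subject_motion_summary(subject: SubjectData, cfg: RunConfig,
                           censor: bool = True) -> MotionSummary:
    """Motion trace + censoring + RMS summary for one subject."""
    traces = [motion_trace(s, cfg.sphere_radius) for s in subject.realignment]
    if censor:
        masks = []
        for series, ts, trace in zip(subject.realignment, subject.timeseries,
                                     traces):
            bold = bold_frame_change(ts.values)
            masks.append(censor_mask(trace, bold, cfg))
    else:
        masks = [CensorMask.all_keep(t.n_frames) for t in traces]
    return summarize_motion(traces, masks, cfg.frames_keep,
                            cfg.summary_style, subject.subject_id)


def subject_edges(subject: SubjectData, cfg: RunConfig,
                  do_preprocess: bool = True,
                  do_motion_regression: bool = True,
                  do_gsr: bool = True,
                  censor: bool = True) -> np.ndarray:
    """Edge vector for one subject: clean each scan, censor, correlate,
    average scans, vectorize."""
    matrices = []
    for series, ts in zip(subject.realignment, subject.timeseries):
        trace = motion_trace(series, cfg.sphere_radius)
        if censor:
            bold = bold_frame_change(ts.values)
            mask = censor_mask(trace, bold, cfg)
        else:
            mask = CensorMask.all_keep(ts.n_frames)
        clean = preprocess(ts, series, cfg, do_motion_regression,
                           do_gsr) if do_preprocess else ts
        matrices.append(connectivity_matrix(clean, mask, cfg.frames_keep))
    avg = matrices[0]
    for m in matrices[1:]:
        avg = average_scans(avg, m)
    return edge_vectorize(avg).values


def _as_subject_data(cohort: SyntheticCohort) -> list[SubjectData]:
    return [SubjectData(s.subject_id, s.realignment, s.timeseries)
            for s in cohort.subjects]


def cohort_edge_matrix(cohort: SyntheticCohort, cfg: RunConfig,
                       **kwargs) -> np.ndarray:
    """(n_subjects, n_edges) Fisher-z edge matrix for a synthetic cohort."""
    return np.vstack([subject_edges(s, cfg, **kwargs)
                      for s in _as_subject_data(cohort)])


def cohort_motion_table(cohort: SyntheticCohort, cfg: RunConfig,
                        censor: bool = True) -> pd.DataFrame:
    """Per-subject motion summary table (rms_d, rms_dd, frames used)."""
    rows = []
    for s in _as_subject_data(cohort):
        summ = subject_motion_summary(s, cfg, censor=censor)
        rows.append({"subject": s.subject_id, "rms_d": summ.rms_d,
                     "rms_dd": summ.rms_dd,
                     "n_frames_used": summ.n_frames_used})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based processing (manifest-driven)


def load_subject(manifest: CohortManifest, subject_id: str,
                 session_id: str | None = None,
                 base_dir: str | Path = ".") -> SubjectData:
    """Load one subject's scans (realignment + timeseries) from disk."""
    base = Path(base_dir)
    entry = next(s for s in manifest.subjects if s.subject_id == subject_id)
    sessions = entry.sessions
    if session_id is not None:
        sessions = [s for s in sessions if s.session_id == session_id]
    realignment, timeseries = [], []
    for sess in sessions:
        for scan in sess.scans:
            realignment.append(read_realignment(
                base / scan.realignment_path, manifest.realignment_dialect,
                tr=manifest.tr, scan_id=scan.scan_id))
            timeseries.append(read_roi_timeseries(
                base / scan.timeseries_path, tr=manifest.tr,
                scan_id=scan.scan_id))
    return SubjectData(subject_id, realignment, timeseries)


def manifest_motion_table(manifest: CohortManifest, cfg: RunConfig,
                          base_dir: str | Path = ".",
                          censor: bool = True) -> pd.DataFrame:
    rows = []
    for entry in manifest.subjects:
        for sess in entry.sessions:
            data = load_subject(manifest, entry.subject_id, sess.session_id,
                                base_dir)
            traces = [motion_trace(s, cfg.sphere_radius)
                      for s in data.realignment]
            if censor:
                masks = [censor_mask(t, bold_frame_change(ts.values), cfg)
                         for t, ts in zip(traces, data.timeseries)]
            else:
                masks = [CensorMask.all_keep(t.n_frames) for t in traces]
            summ = summarize_motion(traces, masks, cfg.frames_keep,
                                    cfg.summary_style, entry.subject_id,
                                    sess.session_id)
            rows.append({"subject": entry.subject_id,
                         "session": sess.session_id,
                         "rms_d": summ.rms_d, "rms_dd": summ.rms_dd,
                         "n_censored": sum(m.n_censored for m in masks),
                         "n_frames_used": summ.n_frames_used})
    return pd.DataFrame(rows)


def manifest_edge_matrix(manifest: CohortManifest, cfg: RunConfig,
                         base_dir: str | Path = ".",
                         **kwargs) -> tuple[np.ndarray, list[str]]:
    edges, ids = [], []
    for entry in manifest.subjects:
        data = load_subject(manifest, entry.subject_id, base_dir=base_dir)
        edges.append(subject_edges(data, cfg, **kwargs))
        ids.append(entry.subject_id)
    return np.vstack(edges), ids
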