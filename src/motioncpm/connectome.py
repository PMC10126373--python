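"""Timeseries cleaning and Fisher-z functional connectivity matrices.

The connectome of one scan is the matrix of Fisher-z-transformed Pearson
correlations between all pairs of ROI timeseries, computed on the first
``frames_keep`` frames that survive motion censoring.  Cleaning happens in
a fixed order: per-node demean and linear detrend, optional regression of
the six realignment parameters, optional global signal regression (GSR),
and zero-phase low-pass filtering (4th-order Butterworth, 0.10 Hz cutoff by
default).  Filtering precedes frame deletion so the filter never runs
across censored gaps.  The LR and RL matrices of one session are averaged
element-wise to increase signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .config import RunConfig
from .exceptions import (DegenerateDataError, DimensionError, ValidationError)
from .motion import CensorMask, RealignmentSeries

FISHER_CLIP = 1.0 - 1e-7  # |r| clip keeping atanh finite


@dataclass
class ROITimeseries:
    """BOLD (or simulated) signal per node; ``values`` is (n_nodes, n_frames)."""

    values: np.ndarray
    node_ids: list[str] | None = None
    tr: float = 0.72
    scan_id: str = ""
    detrended: bool = False
    motion_regressed: bool = False
    gsr: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be (n_nodes, n_frames)")
        if not np.isfinite(self.values).all():
            raise ValidationError("timeseries contains non-finite values")
        if self.node_ids is not None and len(self.node_ids) != self.n_nodes:
            raise DimensionError("node_ids length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with node labels."""

    z: np.ndarray
    node_ids: list[str] | None = None
    network_labels: list[str] | None = None
    session_id: str = ""
    n_frames_used: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValidationError("z must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-12, rtol=0):
            raise ValidationError("z must be symmetric to 1e-12")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class EdgeVector:
    """Upper-triangle vectorization of a connectivity matrix.

    Edge k corresponds to node pair (i, j), i < j, in row-major order over
    the strict upper triangle; the index map is available via
    :func:`edge_index_pairs`.
    """

    values: np.ndarray
    n_nodes: int
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if self.values.shape != (expected,):
            raise DimensionError(
                f"edge vector for {self.n_nodes} nodes must have length "
                f"{expected}, got {self.values.shape}")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]


def edge_index_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column node indices of edge k, k = 0..n(n−1)/2−1 (i < j, row-major)."""
    return np.triu_indices(n_nodes, k=1)


def _regress_out(values: np.ndarray, regressors: np.ndarray,
                 what: str) -> np.ndarray:
    """Residualize each node's timeseries on [1, regressors] via least squares."""
    n_frames = values.shape[1]
    design = np.column_stack([np.ones(n_frames), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        offending = []
        for c in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, :c + 1]) == np.linalg.matrix_rank(design[:, :c]):
                offending.append(c - 1)
        raise DegenerateDataError(
            f"rank-deficient {what} regressor matrix; degenerate columns "
            f"(0-based, excluding intercept): {offending}")
    beta, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ beta).T


def preprocess(ts: ROITimeseries,
               realignment: RealignmentSeries | None,
               cfg: RunConfig,
               do_motion_regression: bool = True,
               do_gsr: bool = True) -> ROITimeseries:
    """Clean ROI timeseries in the fixed order detrend → motion regression
    → GSR → low-pass filter.

    Motion regression uses the six realignment parameters as-is (no
    derivatives or squares).  GSR regresses the across-node mean signal
    from every node.  The low-pass filter is a zero-phase forward-backward
    4th-order Butterworth at ``cfg.lowpass_cutoff`` Hz.
    """
    values = ts.values.copy()
    # per-node demean + linear detrend
    values = sps.detrend(values, axis=1, type="linear")
    if do_motion_regression:
        if realignment is None:
            raise ValidationError("motion regression requested without a "
                                  "realignment series")
        if realignment.n_frames != ts.n_frames:
            raise DimensionError(
                f"realignment has {realignment.n_frames} frames, "
                f"timeseries has {ts.n_frames}")
        regressors = np.hstack([realignment.translations, realignment.rotations])
        values = _regress_out(values, regressors, "motion")
    if do_gsr:
        global_signal = values.mean(axis=0)
        values = _regress_out(values, global_signal[:, None], "global-signal")
    nyquist = 0.5 / ts.tr
    if cfg.lowpass_cutoff >= nyquist:
        raise ValidationError(
            f"low-pass cutoff {cfg.lowpass_cutoff} Hz is not below the "
            f"Nyquist frequency {nyquist:.4f} Hz for tr={ts.tr}")
    b, a = sps.butter(4, cfg.lowpass_cutoff, btype="low", fs=1.0 / ts.tr)
    values = sps.filtfilt(b, a, values, axis=1)
    return ROITimeseries(values=values, node_ids=ts.node_ids, tr=ts.tr,
                         scan_id=ts.scan_id, detrended=True,
                         motion_regressed=do_motion_regression, gsr=do_gsr,
                         filtered=True)


def lowpass_frequency_response(cfg: RunConfig, tr: float,
                               freqs: np.ndarray) -> np.ndarray:
    """Amplitude response of the zero-phase low-pass filter at ``freqs`` (Hz).

    Forward-backward filtering applies the filter's magnitude response
    twice, so the effective amplitude gain is |H(f)|².
    """
    b, a = sps.butter(4, cfg.lowpass_cutoff, btype="low", fs=1.0 / tr)
    _, h = sps.freqz(b, a, worN=np.asarray(freqs, dtype=float), fs=1.0 / tr)
    return np.abs(h) ** 2


def connectivity_matrix(ts: ROITimeseries,
                        mask: CensorMask | None = None,
                        frames_keep: int = 150,
                        session_id: str = "") -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity on the first surviving frames.

    Uses the first ``frames_keep`` frames that survive censoring (all
    frames survive when ``mask`` is None).  Pearson r is computed per node
    pair, |r| clipped to 1−1e-7 and Fisher-transformed (z = atanh r).  The
    diagonal is set to 0 and excluded from all downstream analyses.
    """
    if ts.n_nodes < 2:
        raise ValidationError("need at least two nodes")
    if mask is None:
        surviving = np.arange(ts.n_frames)
    else:
        if mask.n_frames != ts.n_frames:
            raise DimensionError("censor mask length does not match frames")
        surviving = np.where(mask.keep)[0]
    surviving = surviving[:frames_keep]
    if surviving.size < 3:
        raise ValidationError(
            f"need at least 3 surviving frames, got {surviving.size}")
    data = ts.values[:, surviving]
    sd = data.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        ids = ([ts.node_ids[i] for i in dead] if ts.node_ids is not None
               else dead.tolist())
        raise DegenerateDataError(
            f"zero-variance nodes on surviving frames: {ids}")
    r = np.corrcoef(data)
    np.clip(r, -FISHER_CLIP, FISHER_CLIP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z=z, node_ids=ts.node_ids,
                              session_id=session_id,
                              n_frames_used=int(surviving.size))


def average_scans(m1: ConnectivityMatrix,
                  m2: ConnectivityMatrix) -> ConnectivityMatrix:
    """Element-wise average of two scans' z-matrices (e.g. LR and RL)."""
    if m1.n_nodes != m2.n_nodes:
        raise DimensionError("node counts differ")
    if (m1.node_ids is not None and m2.node_ids is not None
            and m1.node_ids != m2.node_ids):
        raise DimensionError("node id sets differ")
    if m1.session_id and m2.session_id and m1.session_id != m2.session_id:
        raise DimensionError(
            f"sessions differ: {m1.session_id!r} vs {m2.session_id!r}")
    return ConnectivityMatrix(
        z=(m1.z + m2.z) / 2.0, node_ids=m1.node_ids,
        session_id=m1.session_id or m2.session_id,
        n_frames_used=m1.n_frames_used + m2.n_frames_used)


def edge_vectorize(m: ConnectivityMatrix, atol: float = 1e-9) -> EdgeVector:
    """Vectorize the strict upper triangle (i < j, row-major)."""
    if not np.allclose(m.z, m.z.T, atol=atol, rtol=0):
        raise ValidationError(f"matrix asymmetry exceeds {atol}")
    iu, ju = edge_index_pairs(m.n_nodes)
    return EdgeVector(values=m.z[iu, ju], n_nodes=m.n_nodes,
                      node_ids=m.node_ids)


def edge_unvectorize(v: EdgeVector,
                     node_ids: list[str] | None = None) -> ConnectivityMatrix:
    """Rebuild the symmetric matrix (zero diagonal) from an edge vector."""
    z = np.zeros((v.n_nodes, v.n_nodes))
    iu, ju = edge_index_pairs(v.n_nodes)
    z[iu, ju] = v.values
    z[ju, iu] = v.values
    return ConnectivityMatrix(z=z, node_ids=node_ids or v.node_ids)
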