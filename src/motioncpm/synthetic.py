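"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the skeleton of a multi-session fMRI cohort: each
subject carries a log-normal *motion trait* that scales a bounded random
walk (plus sparse spikes) in their rigid-body realignment parameters, and
node timeseries whose correlation structure is linearly coupled — in
Fisher-z units — to the subject's standardized motion score on a planted
set of edges.  A per-frame global artifact proportional to the
frame-to-frame displacement can be injected to mimic motion artifacts.

A second, purely geometric simulator produces *displacement* timeseries:
for each frame the rigid-body transform is applied to a voxel grid and the
per-voxel displacement magnitude is averaged within parcels.  These series
contain no BOLD component and serve as a negative control for motion
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .connectome import ROITimeseries
from .exceptions import GenerationError, ValidationError
from .motion import (CensorMask, MotionSummary, RealignmentSeries,
                     motion_trace, summarize_motion)

#: AR(1) coefficient keeping the simulated realignment walk bounded.
WALK_PHI = 0.95

#: Amplitude (signal units on a baseline of 100) of the correlated
#: "neural" component of simulated BOLD; ~1 % fluctuations.
SIGNAL_AMPLITUDE = 1.0

#: Baseline signal level, so percent-change metrics are well defined.
SIGNAL_BASELINE = 100.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror a task-fMRI protocol: 207 subjects, two
    phase-encoding scans (LR/RL) of 176 frames at TR = 0.72 s, and Shen-
    parcellation-sized connectomes are impractical for routine simulation,
    so the default parcellation has 60 nodes (1,770 edges) — large enough
    for edge-level selection statistics, small enough to simulate quickly.

    The subject motion trait m_j is log-normal (median exp(trait_log_mean));
    per-frame translations follow an AR(1)-bounded random walk with step
    scale ``walk_sd · m_j`` mm plus spikes of scale ``spike_scale · m_j``
    at rate ``spike_rate``; rotations are analogous at ``rot_scale``.
    With the defaults the median frame-to-frame displacement is ~0.035 mm,
    matching task-fMRI relative-motion magnitudes.

    ``coupling_edges`` (upper-triangle edge indices) receive a shift of
    ``coupling_strength`` Fisher-z units per SD of the cohort's motion
    score (``coupling_score``: "rms_dd" or "rms_d"); ``artifact_gain``
    adds a global per-frame component of that many percent of baseline
    signal per mm of frame-to-frame displacement.
    """

    n_subjects: int = 207
    n_nodes: int = 60
    n_frames: int = 176
    n_scans: int = 2
    tr: float = 0.72
    trait_log_mean: float = 0.0
    trait_log_sd: float = 0.5
    walk_sd: float = 0.02
    spike_rate: float = 0.02
    spike_scale: float = 0.3
    rot_scale: float = 2e-4
    coupling_edges: tuple[int, ...] = ()
    coupling_strength: float = 0.0
    coupling_score: str = "rms_dd"
    artifact_gain: float = 5.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_nodes", "n_frames", "n_scans"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.spike_rate <= 1.0):
            raise ValidationError("spike_rate must lie in [0, 1]")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        edges = np.asarray(self.coupling_edges, dtype=int)
        if edges.size and (edges.min() < 0 or edges.max() >= n_edges):
            raise ValidationError(
                f"coupling_edges must be valid upper-triangle indices "
                f"(0..{n_edges - 1})")
        if self.coupling_strength != 0.0 and edges.size == 0:
            raise ValidationError(
                "coupling_strength != 0 requires a nonempty coupling_edges set")
        if self.coupling_score not in ("rms_dd", "rms_d"):
            raise ValidationError("coupling_score must be 'rms_dd' or 'rms_d'")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def scan_ids(self) -> list[str]:
        base = ["LR", "RL"]
        if self.n_scans <= 2:
            return base[: self.n_scans]
        return base + [f"scan{i}" for i in range(2, self.n_scans)]


@dataclass
class SyntheticSubject:
    """One generated subject: realignment, timeseries, and true summaries."""

    subject_id: str
    trait: float
    realignment: list[RealignmentSeries]
    timeseries: list[ROITimeseries]
    summary: MotionSummary


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it."""

    spec: SyntheticSpec
    subjects: list[SyntheticSubject]
    base_correlation: np.ndarray
    coupling_edges: np.ndarray

    @property
    def scores_rms_dd(self) -> np.ndarray:
        return np.array([s.summary.rms_dd for s in self.subjects])

    @property
    def scores_rms_d(self) -> np.ndarray:
        return np.array([s.summary.rms_d for s in self.subjects])

    def scores(self, name: str | None = None) -> np.ndarray:
        name = name or self.spec.coupling_score
        return self.scores_rms_dd if name == "rms_dd" else self.scores_rms_d


def simulate_realignment(spec: SyntheticSpec, subject_trait: float,
                         rng: np.random.Generator,
                         scan_id: str = "LR") -> RealignmentSeries:
    """Simulate one scan's rigid-body realignment parameters.

    Translations follow a trait-scaled AR(1)-bounded random walk with
    sparse spikes; rotations are analogous at ``rot_scale``.  The first
    frame is exactly zero (displacement is measured with respect to the
    first volume).
    """
    if not subject_trait > 0:
        raise ValidationError("subject_trait must be positive")
    n = spec.n_frames

    def walk(step_sd: float, spike_sd: float) -> np.ndarray:
        steps = rng.normal(0.0, step_sd, size=(n, 3))
        if spec.spike_rate > 0 and spike_sd > 0:
            spikes = rng.random((n, 3)) < spec.spike_rate
            steps = steps + spikes * rng.normal(0.0, spike_sd, size=(n, 3))
        out = np.zeros((n, 3))
        for i in range(1, n):
            out[i] = WALK_PHI * out[i - 1] + steps[i]
        return out

    translations = walk(spec.walk_sd * subject_trait,
                        spec.spike_scale * subject_trait)
    rotations = walk(spec.rot_scale * subject_trait,
                     spec.rot_scale * subject_trait * 3.0)
    translations -= translations[0]
    rotations -= rotations[0]
    return RealignmentSeries(translations=translations, rotations=rotations,
                             tr=spec.tr, scan_id=scan_id)


def _base_correlation(n_nodes: int, rng: np.random.Generator,
                      n_factors: int = 5) -> np.ndarray:
    """A structured base correlation matrix from a low-rank factor model."""
    loadings = rng.normal(0.0, 0.4, size=(n_nodes, n_factors))
    cov = loadings @ loadings.T + np.eye(n_nodes)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to a nearby correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized
    to 1.  Raises :class:`GenerationError` if the result is not finite.
    """
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eig_floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    if not np.isfinite(fixed).all():
        raise GenerationError("correlation projection produced non-finite values")
    return (fixed + fixed.T) / 2.0


def subject_target_correlation(cohort_base: np.ndarray,
                               coupling_edges: np.ndarray,
                               coupling_strength: float,
                               score_z: float) -> np.ndarray:
    """Target correlation for one subject: base matrix with planted edges
    shifted by ``coupling_strength · score_z`` Fisher-z units, projected
    back to a valid correlation matrix."""
    n = cohort_base.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    z = np.arctanh(np.clip(cohort_base[iu, ju], -1 + 1e-7, 1 - 1e-7))
    z = z.copy()
    z[coupling_edges] += coupling_strength * score_z
    target = np.eye(n)
    target[iu, ju] = np.tanh(z)
    target[ju, iu] = target[iu, ju]
    return nearest_correlation(target)


def _sample_timeseries(spec: SyntheticSpec, corr: np.ndarray,
                       dd: np.ndarray, rng: np.random.Generator,
                       scan_id: str) -> ROITimeseries:
    """Draw node timeseries realizing ``corr`` plus artifact and noise.

    The correlated component has unit variance per node and amplitude
    ``SIGNAL_AMPLITUDE`` on a baseline of ``SIGNAL_BASELINE``; the
    artifact adds ``artifact_gain`` percent of baseline per mm of
    frame-to-frame displacement, equally to all nodes.
    """
    n_nodes, n_frames = spec.n_nodes, spec.n_frames
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    neural = factor @ rng.standard_normal((n_nodes, n_frames))
    artifact = np.where(np.isfinite(dd), dd, 0.0)
    values = (SIGNAL_BASELINE
              + SIGNAL_AMPLITUDE * neural
              + (spec.artifact_gain / 100.0) * SIGNAL_BASELINE * artifact
              + spec.noise_sd * rng.standard_normal((n_nodes, n_frames)))
    return ROITimeseries(values=values, tr=spec.tr, scan_id=scan_id)


def true_motion_summary(spec: SyntheticSpec,
                        realignment: list[RealignmentSeries],
                        subject_id: str = "") -> MotionSummary:
    """Ground-truth motion summary from the generated series themselves,
    via the same metric definitions the pipeline uses (all frames kept)."""
    traces = [motion_trace(s) for s in realignment]
    masks = [CensorMask.all_keep(s.n_frames) for s in realignment]
    return summarize_motion(traces, masks, frames_keep=spec.n_frames,
                            subject_id=subject_id)


def simulate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a full cohort: realignment, timeseries, and ground truth.

    Steps: draw log-normal traits; simulate each subject's realignment
    series; compute true motion summaries via the pipeline's own metric
    definitions; standardize the coupling score across the cohort; build
    each subject's target correlation matrix (base + planted z-shift,
    projected to a valid correlation); and draw timeseries realizing it,
    with the per-frame artifact component added.
    """
    rng = np.random.default_rng(spec.seed)
    traits = np.exp(rng.normal(spec.trait_log_mean, spec.trait_log_sd,
                               size=spec.n_subjects))
    realignments: list[list[RealignmentSeries]] = []
    summaries: list[MotionSummary] = []
    for j in range(spec.n_subjects):
        series = [simulate_realignment(spec, traits[j], rng, scan_id=sid)
                  for sid in spec.scan_ids]
        realignments.append(series)
        summaries.append(true_motion_summary(spec, series, f"sub{j:04d}"))

    scores = np.array([getattr(s, spec.coupling_score) for s in summaries])
    sd = scores.std()
    score_z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)

    base = _base_correlation(spec.n_nodes, rng)
    coupling = np.asarray(spec.coupling_edges, dtype=int)
    subjects: list[SyntheticSubject] = []
    for j in range(spec.n_subjects):
        if spec.coupling_strength != 0.0:
            try:
                corr = subject_target_correlation(base, coupling,
                                                  spec.coupling_strength,
                                                  score_z[j])
            except GenerationError as exc:
                raise GenerationError(
                    f"subject sub{j:04d}: {exc}") from exc
        else:
            corr = base
        traces = [motion_trace(s) for s in realignments[j]]
        timeseries = [_sample_timeseries(spec, corr, tr.dd, rng, s.scan_id)
                      for s, tr in zip(realignments[j], traces)]
        subjects.append(SyntheticSubject(
            subject_id=f"sub{j:04d}", trait=float(traits[j]),
            realignment=realignments[j], timeseries=timeseries,
            summary=summaries[j]))
    return SyntheticCohort(spec=spec, subjects=subjects,
                           base_correlation=base, coupling_edges=coupling)


def null_edge_cohort(n_subjects: int, n_edges: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent standard-normal edges and scores (pure null).

    Convenience for null-calibration studies: returns an
    (n_subjects, n_edges) edge matrix and an (n_subjects,) score vector,
    all i.i.d. N(0, 1) and mutually independent.
    """
    return (rng.standard_normal((n_subjects, n_edges)),
            rng.standard_normal(n_subjects))


# ---------------------------------------------------------------------------
# displacement-only datasets


@dataclass
class VoxelGrid:
    """Voxel coordinates (mm, relative to the rotation center) with parcel
    labels covering every voxel."""

    coords: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n_voxels, 3)")
        if self.labels.shape[0] != self.coords.shape[0]:
            raise ValidationError("labels must cover all voxels")

    @property
    def parcels(self) -> np.ndarray:
        return np.unique(self.labels)


def regular_grid(n_side: int = 20, pitch: float = 8.0,
                 n_parcels: int = 60) -> VoxelGrid:
    """A centered cubic voxel lattice split into equal-count parcels.

    Default: 20×20×20 voxels at 8 mm pitch spanning ±76 mm, labeled into
    ``n_parcels`` contiguous blocks of the flattened lattice.
    """
    half = pitch * (n_side - 1) / 2.0
    axis = np.linspace(-half, half, n_side)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    n_vox = coords.shape[0]
    if n_parcels > n_vox:
        raise ValidationError("more parcels than voxels")
    labels = (np.arange(n_vox) * n_parcels) // n_vox
    return VoxelGrid(coords=coords, labels=labels)


def simulate_displacement_dataset(realignment: RealignmentSeries,
                                  grid: VoxelGrid) -> ROITimeseries:
    """Displacement timeseries from applying each frame's rigid-body
    transform to a voxel grid.

    For frame i and voxel v the value is ‖(R_i·v + t_i) − v‖ with R_i the
    rotation matrix from the frame's angles (intrinsic x–y–z order) and
    t_i its translation; the ROI value is the mean displacement over the
    parcel's voxels.  The output contains no BOLD component.
    """
    parcels = grid.parcels
    if parcels.size == 0:
        raise ValidationError("grid has no parcels")
    counts = np.array([(grid.labels == p).sum() for p in parcels])
    if (counts == 0).any():
        raise ValidationError("empty parcel in grid labeling")
    n_frames = realignment.n_frames
    rot = Rotation.from_euler("xyz", realignment.rotations)
    values = np.empty((parcels.size, n_frames))
    # one-hot parcel membership for fast per-parcel means
    membership = (grid.labels[:, None] == parcels[None, :]).astype(float)
    membership /= membership.sum(axis=0)
    for i in range(n_frames):
        moved = rot[i].apply(grid.coords) + realignment.translations[i]
        disp = np.linalg.norm(moved - grid.coords, axis=1)
        values[:, i] = disp @ membership
    return ROITimeseries(values=values, tr=realignment.tr,
                         scan_id=realignment.scan_id,
                         node_ids=[f"parcel{p}" for p in parcels])
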