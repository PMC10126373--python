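"""Readers and writers for realignment files, ROI timeseries, atlas
labels, cohort manifests, serialized models, and edge matrices.

Two realignment dialects are supported:

* ``hcp`` — HCP ``Movement_Regressors.txt``: six whitespace-separated
  columns, translations x y z in mm then rotations in **degrees**;
* ``mcflirt`` — FSL MCFLIRT ``.par``: rotations in **radians** first,
  then translations in mm.

Rotations are always stored in radians internally; the hcp dialect is
converted on read.  Models and overlap networks are serialized as
self-describing JSON (units and atlas node count included), edge matrices
as HDF5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .connectome import ROITimeseries
from .cpm import CPMModel, FeatureMasks
from .exceptions import (DimensionError, FormatError, ParseError,
                         ValidationError)
from .motion import RealignmentSeries
from .networks import OverlapNetwork

_DIALECTS = ("hcp", "mcflirt")


def _parse_numeric_table(path: Path, expect_cols: int | None,
                         what: str) -> np.ndarray:
    """Parse a whitespace/comma-delimited numeric table with row-indexed
    error reporting."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ParseError(
                    f"{what} {path}: non-numeric cell at row {idx}") from exc
    if not rows:
        raise FormatError(f"{what} {path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise FormatError(f"{what} {path}: ragged rows (widths {sorted(widths)})")
    width = widths.pop()
    if expect_cols is not None and width != expect_cols:
        raise FormatError(
            f"{what} {path}: expected {expect_cols} columns, got {width}")
    return np.asarray(rows, dtype=float)


def read_realignment(path: str | Path, dialect: str = "hcp",
                     tr: float = 0.72, scan_id: str = "") -> RealignmentSeries:
    """Read a six-column realignment parameter file.

    Output translations are in mm and rotations in radians regardless of
    dialect; frame order is preserved.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"dialect must be one of {_DIALECTS}")
    table = _parse_numeric_table(Path(path), 6,
                                 f"realignment ({dialect} dialect)")
    if dialect == "hcp":
        translations = table[:, :3]
        rotations = np.deg2rad(table[:, 3:])
    else:
        rotations = table[:, :3]
        translations = table[:, 3:]
    return RealignmentSeries(translations=translations, rotations=rotations,
                             tr=tr, scan_id=scan_id)


def write_realignment(series: RealignmentSeries, path: str | Path,
                      dialect: str = "hcp") -> None:
    """Write a realignment series in the given dialect (full precision)."""
    if dialect not in _DIALECTS:
        raise ValidationError(f"dialect must be one of {_DIALECTS}")
    if dialect == "hcp":
        table = np.hstack([series.translations, np.rad2deg(series.rotations)])
    else:
        table = np.hstack([series.rotations, series.translations])
    np.savetxt(path, table, fmt="%.17g")


def read_roi_timeseries(path: str | Path, tr: float = 0.72,
                        scan_id: str = "") -> ROITimeseries:
    """Read a delimited ROI timeseries table (rows = frames, columns =
    nodes, optional header of node ids)."""
    path = Path(path)
    node_ids: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"timeseries {path}: empty file")
    first_tokens = lines[0].replace(",", " ").split()
    start = 0
    try:
        [float(t) for t in first_tokens]
    except ValueError:
        node_ids = first_tokens
        start = 1
    for idx in range(start, len(lines)):
        tokens = lines[idx].replace(",", " ").split()
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ParseError(
                f"timeseries {path}: non-numeric cell at row {idx}") from exc
    if not rows:
        raise FormatError(f"timeseries {path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise FormatError(
            f"timeseries {path}: ragged rows (widths {sorted(widths)})")
    values = np.asarray(rows, dtype=float).T  # file is frames × nodes
    if not np.isfinite(values).all():
        raise ValidationError(f"timeseries {path}: non-finite values")
    if node_ids is not None and len(node_ids) != values.shape[0]:
        raise FormatError(f"timeseries {path}: header width does not match rows")
    return ROITimeseries(values=values, node_ids=node_ids, tr=tr,
                         scan_id=scan_id)


def write_roi_timeseries(ts: ROITimeseries, path: str | Path,
                         delimiter: str = "\t") -> None:
    """Write a timeseries as frames × nodes text, header if ids exist."""
    with open(path, "w") as fh:
        if ts.node_ids is not None:
            fh.write(delimiter.join(ts.node_ids) + "\n")
        np.savetxt(fh, ts.values.T, fmt="%.17g", delimiter=delimiter)


def read_atlas_labels(path: str | Path) -> dict[str, str]:
    """Read a node_id → network_label table (TSV/CSV, optional header)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", "\t").split("\t")
            tokens = [t.strip() for t in tokens if t.strip()]
            if len(tokens) < 2:
                raise FormatError(f"atlas labels {path}: row {idx} needs "
                                  "node_id and network_label")
            if idx == 0 and tokens[0].lower() in ("node", "node_id", "id"):
                continue
            out[tokens[0]] = tokens[1]
    if not out:
        raise FormatError(f"atlas labels {path}: no rows")
    return out


# ---------------------------------------------------------------------------
# model and network serialization (self-describing JSON)

_MODEL_FORMAT = "motioncpm-model-v1"


def serialize_model(model: CPMModel, path: str | Path) -> None:
    """Write a fitted CPM model (coefficients + edge masks) as JSON.

    The atlas node count is stored so a model trained on one parcellation
    cannot silently apply to another.
    """
    if model.masks is None:
        raise ValidationError("model has no edge masks; cannot serialize")
    payload = {
        "format": _MODEL_FORMAT,
        "variant": model.variant,
        "coefficients": {"a": model.a, "b": model.b, "c": model.c},
        "units": {"a": "mm", "b": "mm per z-unit", "c": "mm per z-unit"},
        "score_name": model.score_name,
        "session_id": model.session_id,
        "n_train": model.n_train,
        "n_nodes": model.n_nodes,
        "n_edges": model.masks.n_edges,
        "selection_p": model.masks.selection_p,
        "positive_edges": np.where(model.masks.positive)[0].tolist(),
        "negative_edges": np.where(model.masks.negative)[0].tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def deserialize_model(path: str | Path) -> CPMModel:
    """Read a serialized CPM model; missing fields raise a structured
    error rather than defaulting."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"model {path}: invalid JSON") from exc
    if payload.get("format") != _MODEL_FORMAT:
        raise FormatError(f"model {path}: unknown format tag "
                          f"{payload.get('format')!r}")
    try:
        coef = payload["coefficients"]
        a, b, c = coef["a"], coef["b"], coef["c"]
        n_edges = payload["n_edges"]
        pos_idx = payload["positive_edges"]
        neg_idx = payload["negative_edges"]
        variant = payload["variant"]
    except KeyError as exc:
        raise FormatError(f"model {path}: missing field {exc}") from exc
    positive = np.zeros(n_edges, dtype=bool)
    negative = np.zeros(n_edges, dtype=bool)
    positive[pos_idx] = True
    negative[neg_idx] = True
    masks = FeatureMasks(positive=positive, negative=negative,
                         selection_p=payload.get("selection_p", float("nan")),
                         n_subjects=payload.get("n_train", 0))
    return CPMModel(variant=variant, a=float(a), b=float(b), c=float(c),
                    masks=masks, score_name=payload.get("score_name", ""),
                    session_id=payload.get("session_id", ""),
                    n_train=payload.get("n_train", 0),
                    n_nodes=payload.get("n_nodes", 0))


def serialize_overlap_network(net: OverlapNetwork, path: str | Path) -> None:
    pos_pairs = net.node_pairs("positive").tolist()
    neg_pairs = net.node_pairs("negative").tolist()
    payload = {
        "format": "motioncpm-overlap-v1",
        "n_nodes": net.n_nodes,
        "min_fraction": net.min_fraction,
        "n_mask_sets": net.n_mask_sets,
        "provenance": net.provenance,
        "positive_edges": net.positive_edges.tolist(),
        "negative_edges": net.negative_edges.tolist(),
        "positive_node_pairs": pos_pairs,
        "negative_node_pairs": neg_pairs,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def deserialize_overlap_network(path: str | Path) -> OverlapNetwork:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"overlap network {path}: invalid JSON") from exc
    try:
        return OverlapNetwork(
            positive_edges=np.asarray(payload["positive_edges"], dtype=int),
            negative_edges=np.asarray(payload["negative_edges"], dtype=int),
            n_nodes=payload["n_nodes"],
            min_fraction=payload["min_fraction"],
            n_mask_sets=payload["n_mask_sets"],
            provenance=payload.get("provenance", []))
    except KeyError as exc:
        raise FormatError(f"overlap network {path}: missing field {exc}") from exc


# ---------------------------------------------------------------------------
# edge matrices (HDF5)


def write_edge_matrix(path: str | Path, edges: np.ndarray,
                      subject_ids: list[str], n_nodes: int) -> None:
    """Write a subjects × edges matrix plus ids to HDF5."""
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 2 or edges.shape[0] != len(subject_ids):
        raise DimensionError("edges must be (n_subjects, n_edges) matching ids")
    with h5py.File(path, "w") as f:
        f.create_dataset("edges", data=edges)
        f.create_dataset("subject_ids",
                         data=np.array(subject_ids, dtype="S"))
        f.attrs["n_nodes"] = n_nodes


def read_edge_matrix(path: str | Path) -> tuple[np.ndarray, list[str], int]:
    with h5py.File(path, "r") as f:
        edges = f["edges"][()]
        ids = [s.decode() for s in f["subject_ids"][()]]
        n_nodes = int(f.attrs["n_nodes"])
    return edges, ids, n_nodes


# ---------------------------------------------------------------------------
# cohort manifest


@dataclass
class ScanEntry:
    scan_id: str
    realignment_path: str
    timeseries_path: str


@dataclass
class SessionEntry:
    session_id: str
    scans: list[ScanEntry]

    @property
    def complete(self) -> bool:
        tags = {s.scan_id for s in self.scans}
        return {"LR", "RL"} <= tags or len(self.scans) >= 2


@dataclass
class SubjectEntry:
    subject_id: str
    sessions: list[SessionEntry]


@dataclass
class CohortManifest:
    """Index of a cohort's on-disk files, one entry per subject."""

    subjects: list[SubjectEntry]
    realignment_dialect: str = "hcp"
    tr: float = 0.72
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate subject ids in manifest")

    def incomplete_subjects(self) -> list[str]:
        return [s.subject_id for s in self.subjects
                if any(not sess.complete for sess in s.sessions)]

    def to_file(self, path: str | Path) -> None:
        payload = {
            "format": "motioncpm-manifest-v1",
            "realignment_dialect": self.realignment_dialect,
            "tr": self.tr,
            "notes": self.notes,
            "subjects": [
                {"subject_id": s.subject_id,
                 "sessions": [
                     {"session_id": sess.session_id,
                      "scans": [{"scan_id": sc.scan_id,
                                 "realignment_path": sc.realignment_path,
                                 "timeseries_path": sc.timeseries_path}
                                for sc in sess.scans]}
                     for sess in s.sessions]}
                for s in self.subjects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortManifest":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"manifest {path}: invalid JSON") from exc
        try:
            subjects = [
                SubjectEntry(
                    subject_id=s["subject_id"],
                    sessions=[
                        SessionEntry(
                            session_id=sess["session_id"],
                            scans=[ScanEntry(sc["scan_id"],
                                             sc["realignment_path"],
                                             sc["timeseries_path"])
                                   for sc in sess["scans"]])
                        for sess in s["sessions"]])
                for s in payload["subjects"]]
            return cls(subjects=subjects,
                       realignment_dialect=payload["realignment_dialect"],
                       tr=payload["tr"], notes=payload.get("notes", {}))
        except KeyError as exc:
            raise FormatError(f"manifest {path}: missing field {exc}") from exc
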