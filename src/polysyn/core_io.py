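"""Domain types and I/O for volumes, synapse annotations, and connectome graphs.

Conventions used throughout the package:

* voxel indices are 0-based and ordered ``(z, y, x)``;
* distances are Euclidean in voxel units; spheres/balls are closed
  (``distance <= radius``);
* intensity is 8-bit with LOW values meaning electron-dense (dark
  membranes and presynaptic T-bars), as in EM imagery;
* segment ID 0 is reserved for "unassigned/masked" voxels;
* connectome edges with weight 0 are treated as absent everywhere.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import h5py
import numpy as np

from .errors import BoundsError, FormatError, SchemaError

DEFAULT_VOLUME_DATASET = "volume"
DEFAULT_LABELS_DATASET = "labels"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D isotropic grayscale EM volume (or phantom).

    ``data`` holds 8-bit intensities; low values are electron-dense.
    """

    data: np.ndarray
    voxel_size_nm: float = 10.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise FormatError(f"Volume data must be 3D, got shape {arr.shape}")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise FormatError("Volume intensities must lie in [0, 255]")
        if self.voxel_size_nm <= 0:
            raise FormatError("voxel_size_nm must be positive")
        self.data = arr.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """A 3D grid of non-negative integer segment (body) IDs; 0 = unassigned."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"Label data must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("Label data must be integer-typed")
        if arr.size and arr.min() < 0:
            raise FormatError("Segment IDs must be non-negative")
        self.data = arr.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def bodies(self) -> set[int]:
        """All non-zero segment IDs present in the volume."""
        ids = np.unique(self.data)
        return {int(i) for i in ids if i != 0}


def check_inside(point: "PointAnnotation", shape: tuple[int, int, int]) -> None:
    if not (0 <= point.z < shape[0] and 0 <= point.y < shape[1] and 0 <= point.x < shape[2]):
        raise BoundsError(f"point {(point.z, point.y, point.x)} outside volume of shape {shape}")


@dataclass(frozen=True)
class PointAnnotation:
    """A single point annotation: T-bar center or PSD location."""

    z: int
    y: int
    x: int
    confidence: float = 1.0
    kind: str = "tbar"

    def __post_init__(self) -> None:
        for name in ("z", "y", "x"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.kind not in ("tbar", "psd"):
            raise SchemaError(f"kind must be 'tbar' or 'psd', got {self.kind!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise SchemaError(f"confidence must lie in [0, 1], got {self.confidence}")
        object.__setattr__(self, "confidence", float(self.confidence))

    @property
    def zyx(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)

    def with_position(self, z: int, y: int, x: int) -> "PointAnnotation":
        return PointAnnotation(z, y, x, self.confidence, self.kind)


# A predicted T-bar is a point annotation of kind "tbar" whose confidence is
# the detector score.
TbarPrediction = PointAnnotation


@dataclass(frozen=True)
class PartnerEntry:
    """One postsynaptic partner of a T-bar: a body ID and/or a PSD point."""

    body_id: int
    confidence: float = 1.0
    point: PointAnnotation | None = None

    def __post_init__(self) -> None:
        if self.body_id <= 0:
            raise SchemaError(f"partner body_id must be positive, got {self.body_id}")
        if not (0.0 <= self.confidence <= 1.0):
            raise SchemaError(f"partner confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class SynapseRecord:
    """One polyadic synapse: a presynaptic T-bar plus its partner list.

    ``host_body`` (optional) is the body containing the T-bar; when given,
    the no-autapse invariant (no partner in the host body) is enforced at
    construction.  Partner body IDs are distinct within a record: multiple
    contacts from one T-bar onto the same body collapse to one connection.
    """

    tbar: PointAnnotation
    partners: tuple[PartnerEntry, ...] = ()
    host_body: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "partners", tuple(self.partners))
        ids = [p.body_id for p in self.partners]
        if len(set(ids)) != len(ids):
            raise SchemaError("partner body_ids within one record must be distinct")
        if self.host_body is not None and self.host_body in ids:
            raise SchemaError(
                f"partner body {self.host_body} equals the T-bar host body (autapse)"
            )

    def partner_bodies(self) -> set[int]:
        return {p.body_id for p in self.partners}


class ConnectomeGraph:
    """A directed weighted graph over body IDs; weight = synapse count.

    Absent edges have weight 0; edges with weight 0 are never stored.
    Self-loops (autapses) are rejected.
    """

    def __init__(self, edges: Mapping[tuple[int, int], int] | None = None):
        self._edges: dict[tuple[int, int], int] = {}
        if edges:
            for (a, b), w in edges.items():
                self.add_edge(a, b, w)

    def add_edge(self, pre: int, post: int, weight: int = 1) -> None:
        if pre == post:
            raise FormatError(f"self-loop {pre}->{post} not allowed")
        if weight < 0:
            raise FormatError(f"edge weight must be non-negative, got {weight}")
        if weight == 0:
            return
        key = (int(pre), int(post))
        self._edges[key] = self._edges.get(key, 0) + int(weight)

    def weight(self, edge: tuple[int, int]) -> int:
        return self._edges.get(edge, 0)

    @property
    def edges(self) -> dict[tuple[int, int], int]:
        return dict(self._edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self._edges)

    def total_weight(self) -> int:
        return sum(self._edges.values())

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectomeGraph):
            return NotImplemented
        return self._edges == other._edges

    def __repr__(self) -> str:
        return f"ConnectomeGraph({len(self._edges)} edges, total weight {self.total_weight()})"

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for (a, b), w in self._edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class GraphBuildResult:
    graph: ConnectomeGraph
    n_skipped_unassigned: int = 0


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------


def _read_h5_dataset(path, dataset_name: str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with h5py.File(path, "r") as f:
        if dataset_name not in f:
            raise FormatError(f"dataset {dataset_name!r} not found in {path}")
        arr = f[dataset_name][()]
    if arr.ndim != 3:
        raise FormatError(
            f"dataset {dataset_name!r} in {path} must be 3D, got {arr.ndim}D"
        )
    return arr


def read_volume(path, dataset_name: str = DEFAULT_VOLUME_DATASET) -> Volume:
    """Read an 8-bit intensity volume; values are clamped to [0, 255]."""
    arr = _read_h5_dataset(path, dataset_name)
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"dataset {dataset_name!r} must be numeric")
    arr = np.clip(arr, 0, 255).astype(np.uint8)
    return Volume(arr)


def write_volume(volume: Volume, path, dataset_name: str = DEFAULT_VOLUME_DATASET) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(dataset_name, data=volume.data)


def read_labels(path, dataset_name: str = DEFAULT_LABELS_DATASET) -> LabelVolume:
    arr = _read_h5_dataset(path, dataset_name)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"dataset {dataset_name!r} must be integer-typed")
    return LabelVolume(arr)


def write_labels(labels: LabelVolume, path, dataset_name: str = DEFAULT_LABELS_DATASET) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(dataset_name, data=labels.data)


# ---------------------------------------------------------------------------
# synapse JSON I/O
#
# Schema (documented, bespoke): a top-level JSON list; each element is
#   {"tbar": {"z": int, "y": int, "x": int, "confidence": float},
#    "host_body": int or null,
#    "partners": [{"body_id": int, "confidence": float,
#                  "point": {"z","y","x","confidence"} or null}, ...]}
# ---------------------------------------------------------------------------


def _require(cond: bool, json_path: str, msg: str) -> None:
    if not cond:
        raise SchemaError(f"{json_path}: {msg}")


def _point_from_json(obj, json_path: str, kind: str) -> PointAnnotation:
    _require(isinstance(obj, dict), json_path, "expected an object")
    for key in ("z", "y", "x"):
        _require(key in obj, f"{json_path}.{key}", "missing coordinate")
        _require(
            isinstance(obj[key], int) and not isinstance(obj[key], bool),
            f"{json_path}.{key}",
            "coordinate must be an integer",
        )
    conf = obj.get("confidence", 1.0)
    _require(
        isinstance(conf, (int, float)) and 0.0 <= conf <= 1.0,
        f"{json_path}.confidence",
        f"confidence must lie in [0, 1], got {conf!r}",
    )
    return PointAnnotation(obj["z"], obj["y"], obj["x"], float(conf), kind)


def _point_to_json(p: PointAnnotation) -> dict:
    return {"z": p.z, "y": p.y, "x": p.x, "confidence": p.confidence}


def read_synapses(path) -> list[SynapseRecord]:
    """Read a list of synapse records from JSON (schema in the module docs)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path) as f:
        doc = json.load(f)
    _require(isinstance(doc, list), "$", "top level must be a list")
    records = []
    for i, rec in enumerate(doc):
        jp = f"$[{i}]"
        _require(isinstance(rec, dict), jp, "record must be an object")
        _require("tbar" in rec, f"{jp}.tbar", "missing T-bar")
        tbar = _point_from_json(rec["tbar"], f"{jp}.tbar", "tbar")
        partners = []
        for j, pe in enumerate(rec.get("partners", [])):
            pjp = f"{jp}.partners[{j}]"
            _require(isinstance(pe, dict), pjp, "partner must be an object")
            _require("body_id" in pe, f"{pjp}.body_id", "missing body_id")
            body = pe["body_id"]
            _require(
                isinstance(body, int) and not isinstance(body, bool) and body > 0,
                f"{pjp}.body_id",
                f"body_id must be a positive integer, got {body!r}",
            )
            conf = pe.get("confidence", 1.0)
            _require(
                isinstance(conf, (int, float)) and 0.0 <= conf <= 1.0,
                f"{pjp}.confidence",
                f"confidence must lie in [0, 1], got {conf!r}",
            )
            point = None
            if pe.get("point") is not None:
                point = _point_from_json(pe["point"], f"{pjp}.point", "psd")
            partners.append(PartnerEntry(body, float(conf), point))
        host = rec.get("host_body")
        if host is not None:
            _require(
                isinstance(host, int) and not isinstance(host, bool) and host > 0,
                f"{jp}.host_body",
                f"host_body must be a positive integer, got {host!r}",
            )
        try:
            records.append(SynapseRecord(tbar, tuple(partners), host))
        except SchemaError as e:
            raise SchemaError(f"{jp}: {e}") from e
    return records


def write_synapses(records: Iterable[SynapseRecord], path) -> None:
    doc = []
    for rec in records:
        entry: dict = {"tbar": _point_to_json(rec.tbar), "partners": []}
        if rec.host_body is not None:
            entry["host_body"] = rec.host_body
        for p in rec.partners:
            pe: dict = {"body_id": p.body_id, "confidence": p.confidence}
            if p.point is not None:
                pe["point"] = _point_to_json(p.point)
            entry["partners"].append(pe)
        doc.append(entry)
    with open(path, "w") as f:
        json.dump(doc, f, indent=1, sort_keys=True)
        f.write("\n")


# ---------------------------------------------------------------------------
# graph construction and CSV I/O
# ---------------------------------------------------------------------------


def build_graph(records: Iterable[SynapseRecord], labels: LabelVolume) -> GraphBuildResult:
    """Accumulate synapse records into a directed weighted connectome graph.

    The presynaptic (host) body is the label at each record's T-bar
    coordinate (or the record's ``host_body`` when set).  Records whose host
    resolves to 0 (unassigned) are skipped and counted in the diagnostic.
    Each (record, partner) pair contributes weight exactly 1.
    """
    graph = ConnectomeGraph()
    skipped = 0
    for rec in records:
        check_inside(rec.tbar, labels.shape)
        host = rec.host_body
        if host is None:
            host = int(labels.data[rec.tbar.z, rec.tbar.y, rec.tbar.x])
        if host == 0:
            skipped += 1
            continue
        for p in rec.partners:
            if p.body_id == host:
                continue  # defensive: autapses carry no edge
            graph.add_edge(host, p.body_id, 1)
    return GraphBuildResult(graph, skipped)


def write_graph_csv(graph: ConnectomeGraph, path) -> None:
    """Write edges as CSV with columns pre_body,post_body,weight (weight-0 rows omitted)."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["pre_body", "post_body", "weight"])
        for (a, b) in sorted(graph.edge_set()):
            w.writerow([a, b, graph.weight((a, b))])


def read_graph_csv(path) -> ConnectomeGraph:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    graph = ConnectomeGraph()
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        expected = {"pre_body", "post_body", "weight"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: expected columns pre_body,post_body,weight, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader):
            try:
                a, b, w = int(row["pre_body"]), int(row["post_body"]), int(row["weight"])
            except (TypeError, ValueError) as e:
                raise FormatError(f"{path} row {i}: non-integer field ({e})") from e
            if w < 0:
                raise FormatError(f"{path} row {i}: negative weight {w}")
            graph.add_edge(a, b, w)
    return graph
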