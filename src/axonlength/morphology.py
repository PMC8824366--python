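"""SWC morphology I/O and ground-truth path-length geometry.

Digital neuron reconstructions (e.g. from NeuroMorpho.Org) are stored as SWC
files: one point per line, ``id type x y z radius parent``, with ``#`` comment
lines and parent ``-1`` marking a root.  Coordinates are micrometres.  The total
Euclidean path length of the axonal edges of such a reconstruction is the
"true value" against which indirect length-estimation methods are benchmarked.

Structure-type code 2 denotes axon (NeuroMorpho convention); radius is parsed
but plays no role in length computations, which treat the axon as a space curve.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MorphPoint",
    "NeuronMorphology",
    "SegmentSet",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "extract_segments",
    "bounding_box",
    "read_class_labels",
    "AXON",
    "SOMA",
    "BASAL_DENDRITE",
]

#: SWC structure-type codes (standard dialect).
SOMA = 1
AXON = 2
BASAL_DENDRITE = 3

ROOT_PARENT = -1


class SWCParseError(ValueError):
    """Raised for malformed SWC content; message names the offending line."""


@dataclass(frozen=True)
class MorphPoint:
    """One SWC sample point (coordinates and radius in µm)."""

    id: int
    struct_type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuronMorphology:
    """A reconstructed neuron: an ordered forest of sample points.

    Parameters
    ----------
    points
        Sample points in file order.  Ids must be unique, every non-root
        parent must reference an existing id, and the parent relation must be
        acyclic (a forest; multi-root files are valid).
    name
        Identifier of the source file or generator.
    class_label
        Optional qualitative axonal-architecture class (1 focal, 2 multi-focal,
        3 disperse, 4 local).
    """

    points: list[MorphPoint]
    name: str = ""
    class_label: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [p.id for p in self.points]
        id_set = set(ids)
        if len(id_set) != len(ids):
            seen: set[int] = set()
            for p in self.points:
                if p.id in seen:
                    raise SWCParseError(f"duplicate point id {p.id}")
                seen.add(p.id)
        parent_of: dict[int, int] = {}
        for p in self.points:
            if p.parent != ROOT_PARENT and p.parent not in id_set:
                raise SWCParseError(
                    f"point {p.id} references missing parent {p.parent}"
                )
            parent_of[p.id] = p.parent
        # cycle check by path compression walk
        state: dict[int, int] = {}  # 0 in-progress, 1 done
        for start in parent_of:
            node, trail = start, []
            while node != ROOT_PARENT and state.get(node) != 1:
                if state.get(node) == 0:
                    raise SWCParseError(f"cycle in parent links at point {node}")
                state[node] = 0
                trail.append(node)
                node = parent_of[node]
            for n in trail:
                state[n] = 1
        if self.class_label is not None and self.class_label not in (1, 2, 3, 4):
            raise ValueError(f"class_label must be 1-4, got {self.class_label}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def roots(self) -> list[MorphPoint]:
        return [p for p in self.points if p.parent == ROOT_PARENT]


@dataclass
class SegmentSet:
    """A bag of straight 3D line segments with its total Euclidean length.

    ``p0`` and ``p1`` are ``(n, 3)`` float arrays of endpoints in µm.  The
    ground-truth length of an arbor is the sum of its edge lengths.
    """

    p0: np.ndarray
    p1: np.ndarray
    _lengths: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float).reshape(-1, 3)
        self.p1 = np.asarray(self.p1, dtype=float).reshape(-1, 3)
        if self.p0.shape != self.p1.shape:
            raise ValueError("p0 and p1 must have matching shapes")
        self._lengths = np.linalg.norm(self.p1 - self.p0, axis=1)

    def __len__(self) -> int:
        return self.p0.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        """Per-segment Euclidean lengths (µm)."""
        return self._lengths

    @property
    def total_length(self) -> float:
        """Total path length (µm): sum of per-segment endpoint distances."""
        return float(self._lengths.sum())

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "SegmentSet":
        """Rigidly transform all endpoints (rotation matrix then translation)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SegmentSet(self.p0 @ R.T + t, self.p1 @ R.T + t)

    @staticmethod
    def concatenate(parts: Iterable["SegmentSet"]) -> "SegmentSet":
        parts = list(parts)
        if not parts:
            return SegmentSet(np.empty((0, 3)), np.empty((0, 3)))
        return SegmentSet(
            np.vstack([s.p0 for s in parts]), np.vstack([s.p1 for s in parts])
        )


def _parse_line(raw: str, lineno: int) -> MorphPoint | None:
    line = raw.split("#", 1)[0].strip()
    if not line:
        return None
    cols = line.split()
    if len(cols) != 7:
        raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
    try:
        pid = int(cols[0])
        stype = int(cols[1])
        x, y, z, radius = (float(c) for c in cols[2:6])
        parent = int(cols[6])
    except ValueError as exc:
        raise SWCParseError(f"line {lineno}: non-numeric field ({exc})") from None
    return MorphPoint(pid, stype, x, y, z, radius, parent)


def read_swc(path: str | Path, class_label: int | None = None) -> NeuronMorphology:
    """Parse an SWC file into a :class:`NeuronMorphology`.

    Accepts the 7-column whitespace dialect with ``#`` comments and parent
    sentinel ``-1``; point order is preserved.  Malformed lines, duplicate ids,
    and dangling parents raise :class:`SWCParseError` naming the line / point.
    """
    path = Path(path)
    points: list[MorphPoint] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            p = _parse_line(raw, lineno)
            if p is not None:
                points.append(p)
    if not points:
        raise SWCParseError(f"{path}: no data lines")
    return NeuronMorphology(points, name=path.stem, class_label=class_label)


def write_swc(m: NeuronMorphology, path: str | Path) -> None:
    """Write a morphology as standard 7-column SWC (repr-exact coordinates)."""
    buf = io.StringIO()
    buf.write(f"# SWC export of {m.name or 'morphology'}\n")
    buf.write("# id type x y z radius parent\n")
    for p in m.points:
        buf.write(
            f"{p.id} {p.struct_type} {p.x!r} {p.y!r} {p.z!r} {p.radius!r} {p.parent}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def extract_segments(
    m: NeuronMorphology, struct_codes: set[int] | Sequence[int] = (AXON,)
) -> SegmentSet:
    """Collect the (child, parent) edges whose child structure code is selected.

    Default selects the axon (code 2).  An empty selection yields an empty
    :class:`SegmentSet` with ``total_length`` 0.
    """
    codes = set(struct_codes)
    coords = {p.id: (p.x, p.y, p.z) for p in m.points}
    p0, p1 = [], []
    for p in m.points:
        if p.parent != ROOT_PARENT and p.struct_type in codes:
            p0.append(coords[p.parent])
            p1.append((p.x, p.y, p.z))
    if not p0:
        return SegmentSet(np.empty((0, 3)), np.empty((0, 3)))
    return SegmentSet(np.array(p0, dtype=float), np.array(p1, dtype=float))


def bounding_box(s: SegmentSet) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box (min corner, max corner) of all endpoints."""
    if len(s) == 0:
        raise ValueError("no geometry: SegmentSet is empty")
    pts = np.vstack([s.p0, s.p1])
    return pts.min(axis=0), pts.max(axis=0)


def read_class_labels(path: str | Path) -> dict[str, int]:
    """Read a ``neuron_id,class_label`` CSV into a mapping."""
    df = pd.read_csv(path, dtype={"neuron_id": str, "class_label": int})
    if not {"neuron_id", "class_label"} <= set(df.columns):
        raise ValueError("class-label CSV needs columns neuron_id,class_label")
    return dict(zip(df["neuron_id"], df["class_label"]))
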