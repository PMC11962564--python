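"""Landmark digitization files, study datasets, and mesh fixtures.

The package works with repeated manual digitizations of the three ISB
scapula landmarks -- acromial angle (AA), inferior angle (IA) and trigonum
spinae (TS) -- stored as 3D points in millimetres.  Internally all
coordinates are right-handed LPS (x left, y posterior, z superior), the
native convention of CT imaging; 3D Slicer fiducial files declaring RAS are
converted on read.

A reliability study is a fully *balanced* grid: every scapula is digitized
by every observer the same number of times.  :class:`StudyDataset` holds
exactly one :class:`MeasurementRecord` per (scapula, observer, measure)
cell; :func:`validate_dataset` checks this and the per-record geometry.
"""

from __future__ import annotations

import csv
import io
import struct
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ParseError, ValidationError

LANDMARK_NAMES = ("AA", "IA", "TS")

PLAIN_CSV_COLUMNS = ("scapula_id", "observer_id", "measure_idx", "landmark", "x", "y", "z")


def as_point(p, name: str = "point") -> np.ndarray:
    """Coerce to a finite float64 array of shape (3,)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


class CoordinateSpace(str, Enum):
    IMAGING = "imaging"
    AVERAGE_SCAPULA = "average_scapula"
    THORAX = "thorax"


class Side(str, Enum):
    RIGHT = "right"
    LEFT = "left"


@dataclass(frozen=True)
class LandmarkTriplet:
    """The three ISB scapula landmarks as 3D points (mm)."""

    AA: np.ndarray
    IA: np.ndarray
    TS: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, as_point(getattr(self, name), name))

    def triangle_area(self) -> float:
        """Area (mm^2) of the AA-IA-TS triangle; collinearity diagnostic."""
        return 0.5 * float(np.linalg.norm(np.cross(self.IA - self.AA, self.TS - self.AA)))

    def is_collinear(self, area_epsilon: float = 1.0) -> bool:
        return self.triangle_area() <= area_epsilon

    def as_array(self) -> np.ndarray:
        """Rows AA, IA, TS."""
        return np.stack([self.AA, self.IA, self.TS])

    def transformed(self, fn) -> "LandmarkTriplet":
        return LandmarkTriplet(fn(self.AA), fn(self.IA), fn(self.TS))


@dataclass(frozen=True)
class MeasurementRecord:
    """One digitization of one scapula by one observer."""

    scapula_id: str
    observer_id: str
    measure_idx: int
    landmarks: LandmarkTriplet
    coordinate_space: CoordinateSpace = CoordinateSpace.IMAGING

    def __post_init__(self) -> None:
        if self.measure_idx < 1:
            raise ValueError(f"measure_idx must be >= 1, got {self.measure_idx}")
        object.__setattr__(self, "coordinate_space", CoordinateSpace(self.coordinate_space))


@dataclass
class StudyDataset:
    """Balanced grid of measurement records.

    The grid dimensions are derived from the distinct ids present; balance
    is asserted by :func:`validate_dataset`, not silently assumed here.
    """

    records: list[MeasurementRecord]
    sides: dict[str, Side] = field(default_factory=dict)

    @property
    def scapula_ids(self) -> list[str]:
        return sorted({r.scapula_id for r in self.records})

    @property
    def observer_ids(self) -> list[str]:
        return sorted({r.observer_id for r in self.records})

    @property
    def measure_idxs(self) -> list[int]:
        return sorted({r.measure_idx for r in self.records})

    @property
    def n_scapulae(self) -> int:
        return len(self.scapula_ids)

    @property
    def n_observers(self) -> int:
        return len(self.observer_ids)

    @property
    def n_measures(self) -> int:
        return len(self.measure_idxs)

    def get(self, scapula_id: str, observer_id: str, measure_idx: int) -> MeasurementRecord:
        for r in self.records:
            if (r.scapula_id, r.observer_id, r.measure_idx) == (scapula_id, observer_id, measure_idx):
                return r
        raise KeyError((scapula_id, observer_id, measure_idx))

    def records_for_scapula(self, scapula_id: str) -> list[MeasurementRecord]:
        return [r for r in self.records if r.scapula_id == scapula_id]

    def side_of(self, scapula_id: str) -> Side:
        return self.sides.get(scapula_id, Side.RIGHT)


@dataclass(frozen=True)
class RandomizedList:
    """Blinded measurement order: one opaque id per (scapula, measure)."""

    entries: tuple[tuple[str, str, int], ...]  # (blinded_id, scapula_id, measure_idx)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ValidationReport:
    balanced: bool
    missing_cells: list[tuple[str, str, int]]
    duplicate_cells: list[tuple[str, str, int]]
    collinear_records: list[tuple[str, str, int]]
    side_issues: list[str]
    usable: bool

    def summary(self) -> str:
        lines = [f"balanced: {'yes' if self.balanced else 'no'}"]
        for cell in self.missing_cells:
            lines.append(f"missing cell: scapula={cell[0]} observer={cell[1]} measure={cell[2]}")
        for cell in self.duplicate_cells:
            lines.append(f"duplicate cell: scapula={cell[0]} observer={cell[1]} measure={cell[2]}")
        for cell in self.collinear_records:
            lines.append(f"collinear landmarks: scapula={cell[0]} observer={cell[1]} measure={cell[2]}")
        lines.extend(self.side_issues)
        lines.append(f"usable for reliability analysis: {'yes' if self.usable else 'no'}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# plain CSV dialect (canonical interchange format)

def read_landmark_csv(path, dialect: str = "plain", **fcsv_keys) -> StudyDataset:
    """Read landmark digitizations.

    ``plain`` dialect: header ``scapula_id,observer_id,measure_idx,landmark,x,y,z``,
    one row per landmark, '#'-prefixed comment lines ignored.  ``slicer_fcsv``:
    a single 3D Slicer fiducial markup file holding one AA/IA/TS triplet;
    ``scapula_id`` / ``observer_id`` / ``measure_idx`` are taken from keyword
    arguments (scapula_id defaults to the file stem).
    """
    path = Path(path)
    if dialect == "plain":
        return _read_plain_csv(path)
    if dialect == "slicer_fcsv":
        return _read_fcsv(path, **fcsv_keys)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_plain_csv(path: Path) -> StudyDataset:
    cells: dict[tuple[str, str, int], dict[str, np.ndarray]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = set(PLAIN_CSV_COLUMNS) - set(header)
                if missing:
                    raise ParseError(f"{path}:{lineno}: missing columns {sorted(missing)}")
                continue
            rec = dict(zip(header, (c.strip() for c in row)))
            try:
                sid, oid = rec["scapula_id"], rec["observer_id"]
                midx = int(rec["measure_idx"])
                lm = rec["landmark"]
                xyz = np.array([float(rec["x"]), float(rec["y"]), float(rec["z"])])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad row ({exc})") from exc
            if lm not in LANDMARK_NAMES:
                raise ParseError(f"{path}:{lineno}: unknown landmark label {lm!r}")
            cell = cells.setdefault((sid, oid, midx), {})
            if lm in cell:
                raise ParseError(
                    f"{path}:{lineno}: duplicate landmark {lm} for "
                    f"(scapula={sid}, observer={oid}, measure={midx})"
                )
            cell[lm] = xyz
    records = []
    for (sid, oid, midx), lms in sorted(cells.items()):
        absent = [n for n in LANDMARK_NAMES if n not in lms]
        if absent:
            raise ParseError(
                f"{path}: missing landmark(s) {absent} for "
                f"(scapula={sid}, observer={oid}, measure={midx})"
            )
        records.append(
            MeasurementRecord(sid, oid, midx, LandmarkTriplet(lms["AA"], lms["IA"], lms["TS"]))
        )
    return StudyDataset(records)


def write_landmark_csv(dataset: StudyDataset, path, header_comments: Sequence[str] = ()) -> None:
    """Write the plain dialect; inverse of ``read_landmark_csv`` to 1e-9 mm."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh)
        writer.writerow(PLAIN_CSV_COLUMNS)
        for r in sorted(dataset.records, key=lambda r: (r.scapula_id, r.observer_id, r.measure_idx)):
            for lm in LANDMARK_NAMES:
                p = getattr(r.landmarks, lm)
                writer.writerow(
                    [r.scapula_id, r.observer_id, r.measure_idx, lm,
                     repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))]
                )


# ---------------------------------------------------------------------------
# 3D Slicer fiducial markup (.fcsv), read-only

_FCSV_LABEL_COL = 11


def ras_to_lps(p: np.ndarray) -> np.ndarray:
    """RAS <-> LPS axis flip (an involution): (x, y, z) -> (-x, -y, z)."""
    return np.array([-p[0], -p[1], p[2]])


def _read_fcsv(path: Path, scapula_id: str | None = None, observer_id: str = "obs1",
               measure_idx: int = 1) -> StudyDataset:
    if scapula_id is None:
        scapula_id = path.stem
    coordinate_system = "LPS"
    points: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    value = body.split("=", 1)[1].strip()
                    coordinate_system = {"0": "RAS", "1": "LPS"}.get(value, value.upper())
                continue
            fields = line.split(",")
            if len(fields) <= _FCSV_LABEL_COL:
                raise ParseError(f"{path}:{lineno}: too few columns for fcsv")
            label = fields[_FCSV_LABEL_COL].strip()
            if label not in LANDMARK_NAMES:
                raise ParseError(f"{path}:{lineno}: fiducial label {label!r} is not AA/IA/TS")
            try:
                xyz = np.array([float(fields[1]), float(fields[2]), float(fields[3])])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if label in points:
                raise ParseError(f"{path}:{lineno}: duplicate fiducial label {label}")
            points[label] = xyz
    absent = [n for n in LANDMARK_NAMES if n not in points]
    if absent:
        raise ParseError(f"{path}: missing landmark(s) {absent}")
    if coordinate_system == "RAS":
        points = {k: ras_to_lps(v) for k, v in points.items()}
    elif coordinate_system != "LPS":
        raise ParseError(f"{path}: unsupported coordinate system {coordinate_system!r}")
    record = MeasurementRecord(
        scapula_id, observer_id, measure_idx,
        LandmarkTriplet(points["AA"], points["IA"], points["TS"]),
    )
    return StudyDataset([record])


# ---------------------------------------------------------------------------
# STL fixture meshes

@dataclass(frozen=True)
class TriangleMesh:
    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray     # (m, 3) int
    degenerate_faces: np.ndarray  # (m,) bool


def read_stl_mesh(path) -> TriangleMesh:
    """Read a binary or ASCII STL surface model (fixtures/tests only).

    Truncated binary files raise :class:`ParseError` rather than yielding a
    partial mesh; zero-area faces are flagged, not dropped.
    """
    import trimesh

    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise ParseError(f"{path}: too short to be an STL file")
    is_ascii = raw.lstrip()[:5] == b"solid" and b"facet" in raw
    if not is_ascii:
        if len(raw) < 84:
            raise ParseError(f"{path}: truncated binary STL header")
        (n_faces,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * n_faces
        if len(raw) < expected:
            raise ParseError(
                f"{path}: truncated binary STL ({len(raw)} bytes, expected {expected})"
            )
    try:
        mesh = trimesh.load(io.BytesIO(raw), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a mix of types on malformed input
        raise ParseError(f"{path}: malformed STL ({exc})") from exc
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    tri = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return TriangleMesh(vertices, faces, areas <= 1e-12)


# ---------------------------------------------------------------------------
# dataset-level operations

def validate_dataset(dataset: StudyDataset, area_epsilon: float = 1.0) -> ValidationReport:
    """Check balance, duplicates, degenerate triplets and side labels."""
    seen: dict[tuple[str, str, int], int] = {}
    for r in dataset.records:
        key = (r.scapula_id, r.observer_id, r.measure_idx)
        seen[key] = seen.get(key, 0) + 1
    duplicates = sorted(k for k, v in seen.items() if v > 1)
    grid = [
        (s, o, m)
        for s in dataset.scapula_ids
        for o in dataset.observer_ids
        for m in dataset.measure_idxs
    ]
    missing = sorted(set(grid) - set(seen))
    collinear = sorted(
        (r.scapula_id, r.observer_id, r.measure_idx)
        for r in dataset.records
        if r.landmarks.is_collinear(area_epsilon)
    )
    side_issues = [
        f"unknown side for scapula {s}"
        for s in dataset.scapula_ids
        if s in dataset.sides and not isinstance(dataset.sides[s], Side)
    ]
    balanced = not missing and not duplicates and len(dataset.records) == len(grid)
    usable = (
        balanced
        and not collinear
        and not side_issues
        and dataset.n_observers >= 2
        and dataset.n_measures >= 2
    )
    return ValidationReport(balanced, missing, duplicates, collinear, side_issues, usable)


def generate_randomized_list(
    scapula_ids: Sequence[str], n_measures: int, seed: int
) -> RandomizedList:
    """Blinded, seeded measurement order over the (scapula, measure) grid.

    Blinded ids are opaque zero-padded integers assigned *after* shuffling so
    the label order carries no information about scapula identity.
    """
    ids = list(scapula_ids)
    if not ids:
        raise ValueError("scapula_ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scapula_ids")
    if n_measures < 1:
        raise ValueError("n_measures must be >= 1")
    grid = [(s, m) for s in ids for m in range(1, n_measures + 1)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(grid))
    width = max(3, len(str(len(grid))))
    entries = tuple(
        (f"M{rank + 1:0{width}d}", grid[i][0], grid[i][1]) for rank, i in enumerate(order)
    )
    return RandomizedList(entries)


def mirror_to_right(record: MeasurementRecord, side: Side | str) -> MeasurementRecord:
    """Reflect a left-side record across the sagittal plane (x -> -x in LPS).

    Right-side records are returned unchanged, so downstream frames can use
    the right-side axis convention uniformly.  The reflection is an
    involution: mirroring twice restores the original coordinates.
    """
    side = Side(side)
    if record.coordinate_space != CoordinateSpace.IMAGING:
        raise ValidationError("mirror_to_right expects imaging-space records")
    if side == Side.RIGHT:
        return record
    flipped = record.landmarks.transformed(lambda p: np.array([-p[0], p[1], p[2]]))
    return replace(record, landmarks=flipped)
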