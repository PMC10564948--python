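"""Particle pose tables and tomogram metadata.

Poses come from subtomogram-averaging refinements as tables of centre
coordinates (pixels or Å) and three Euler angles (degrees).  Everything is
normalised at this boundary into the internal model: centres in Å,
orientations as proper rotation matrices mapping the reference nucleosome
frame into the tomogram frame.  Two table dialects are supported, a
single-block STAR loop and CSV with a header line; tomogram metadata comes
from an MRC2014 header or a JSON/YAML sidecar.
"""

from __future__ import annotations

import csv
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

#: Euler-angle conventions accepted at the I/O boundary. Angles are intrinsic
#: and in degrees; internally only rotation matrices are used.
EULER_CONVENTIONS = ("ZYZ", "ZXZ")

_ROTATION_TOL = 1e-6


class ParticleTableError(ValueError):
    """Malformed particle table (missing column, non-numeric cell, ...)."""


@dataclass(frozen=True)
class ParticlePose:
    """One refined nucleosome pose.

    Parameters
    ----------
    particle_id:
        Unique integer id within a :class:`ParticleSet`.
    tomo_id:
        Tomogram the particle belongs to; neighbour statistics never cross
        tomogram boundaries.
    center:
        Centre coordinates in Å (tomogram frame).
    rotation:
        3x3 proper rotation matrix, reference frame -> tomogram frame.
    class_label:
        Optional pass-through class index (e.g. 1 = H1-bound with linker
        DNA density, 2 = without); never interpreted beyond grouping.
    """

    particle_id: int
    tomo_id: str
    center: np.ndarray
    rotation: np.ndarray
    class_label: int | None = None

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(center)):
            raise ValueError(f"particle {self.particle_id}: non-finite center {center}")
        if not np.all(np.isfinite(rotation)):
            raise ValueError(f"particle {self.particle_id}: non-finite rotation")
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=_ROTATION_TOL):
            raise ValueError(f"particle {self.particle_id}: rotation not orthonormal")
        if abs(np.linalg.det(rotation) - 1.0) > _ROTATION_TOL:
            raise ValueError(f"particle {self.particle_id}: rotation determinant != +1")
        center.setflags(write=False)
        rotation.setflags(write=False)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "rotation", rotation)


class ParticleSet:
    """A collection of poses with provenance and per-tomogram grouping.

    Stores the poses column-wise (``centers`` ``(n, 3)``, ``rotations``
    ``(n, 3, 3)``) so neighbour searches and angle computations can be
    vectorised; :meth:`particles` rebuilds :class:`ParticlePose` views.
    """

    def __init__(
        self,
        particles: Iterable[ParticlePose],
        pixel_size_A: float = 1.0,
        source: str = "",
    ) -> None:
        particles = list(particles)
        if pixel_size_A <= 0:
            raise ValueError(f"pixel_size_A must be > 0, got {pixel_size_A}")
        ids = [p.particle_id for p in particles]
        if len(set(ids)) != len(ids):
            raise ValueError("particle_id values must be unique within a set")
        self.pixel_size_A = float(pixel_size_A)
        self.source = source
        n = len(particles)
        self.particle_ids = np.array(ids, dtype=np.int64)
        self.tomo_ids = np.array([p.tomo_id for p in particles], dtype=object)
        self.centers = np.array([p.center for p in particles], dtype=float).reshape(n, 3)
        self.rotations = np.array([p.rotation for p in particles], dtype=float).reshape(n, 3, 3)
        labels = [p.class_label for p in particles]
        self.class_labels: np.ndarray | None
        if any(l is not None for l in labels):
            self.class_labels = np.array([-1 if l is None else int(l) for l in labels])
        else:
            self.class_labels = None

    def __len__(self) -> int:
        return len(self.particle_ids)

    def __iter__(self) -> Iterator[ParticlePose]:
        return iter(self.particles())

    def __getitem__(self, i: int) -> ParticlePose:
        label = None
        if self.class_labels is not None and self.class_labels[i] >= 0:
            label = int(self.class_labels[i])
        return ParticlePose(
            particle_id=int(self.particle_ids[i]),
            tomo_id=str(self.tomo_ids[i]),
            center=self.centers[i].copy(),
            rotation=self.rotations[i].copy(),
            class_label=label,
        )

    def particles(self) -> list[ParticlePose]:
        return [self[i] for i in range(len(self))]

    def subset(self, mask: np.ndarray) -> "ParticleSet":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        sub = ParticleSet.__new__(ParticleSet)
        sub.pixel_size_A = self.pixel_size_A
        sub.source = self.source
        sub.particle_ids = self.particle_ids[idx]
        sub.tomo_ids = self.tomo_ids[idx]
        sub.centers = self.centers[idx]
        sub.rotations = self.rotations[idx]
        sub.class_labels = None if self.class_labels is None else self.class_labels[idx]
        return sub

    def by_tomogram(self) -> dict[str, np.ndarray]:
        """Map tomo_id -> integer row indices, in stable order."""
        groups: dict[str, list[int]] = {}
        for i, t in enumerate(self.tomo_ids):
            groups.setdefault(str(t), []).append(i)
        return {t: np.array(ix, dtype=np.int64) for t, ix in groups.items()}


@dataclass(frozen=True)
class TomoMeta:
    """Tomogram dimensions and voxel size, enough to compute its volume."""

    tomo_id: str
    dims_voxels: tuple[int, int, int]
    voxel_size_A: float

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims_voxels):
            raise ValueError(f"dims_voxels must be positive, got {self.dims_voxels}")
        if self.voxel_size_A <= 0:
            raise ValueError(f"voxel_size_A must be > 0, got {self.voxel_size_A}")

    @property
    def volume_A3(self) -> float:
        nx, ny, nz = self.dims_voxels
        return float(nx) * ny * nz * self.voxel_size_A**3


# ---------------------------------------------------------------------------
# Euler angle conversion (I/O boundary only)

def euler_to_matrix(angles_deg: np.ndarray, convention: str = "ZYZ") -> np.ndarray:
    """Intrinsic Euler angles (degrees) -> rotation matrices, vectorised."""
    if convention not in EULER_CONVENTIONS:
        raise ValueError(f"unknown Euler convention {convention!r}; use one of {EULER_CONVENTIONS}")
    return Rotation.from_euler(convention, np.atleast_2d(angles_deg), degrees=True).as_matrix()


def matrix_to_euler(matrices: np.ndarray, convention: str = "ZYZ") -> np.ndarray:
    if convention not in EULER_CONVENTIONS:
        raise ValueError(f"unknown Euler convention {convention!r}; use one of {EULER_CONVENTIONS}")
    import warnings

    with warnings.catch_warnings():
        # gimbal-lock warning: the angle split is then non-unique but the
        # recovered matrix is still exact, which is all round-trips need
        warnings.simplefilter("ignore", UserWarning)
        return Rotation.from_matrix(np.atleast_3d(matrices).reshape(-1, 3, 3)).as_euler(
            convention, degrees=True
        )


# ---------------------------------------------------------------------------
# Particle tables

# STAR column names (RELION-style); CSV uses the short names in _CSV_COLUMNS.
_STAR_COORD = ("rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ")
_STAR_ANGLE = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
_STAR_ORIGIN = ("rlnOriginX", "rlnOriginY", "rlnOriginZ")
_STAR_TOMO = "rlnMicrographName"
_STAR_CLASS = "rlnClassNumber"
_STAR_ID = "rlnImageName"

_CSV_COORD = ("x", "y", "z")
_CSV_ANGLE = ("rot", "tilt", "psi")
_CSV_ORIGIN = ("origin_x", "origin_y", "origin_z")
_CSV_TOMO = "tomo"
_CSV_CLASS = "class"
_CSV_ID = "particle_id"


def _parse_star_table(path: Path) -> tuple[list[str], list[list[str]]]:
    """Parse the first loop block of a single-data-block STAR file."""
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                continue
            if in_loop and line.startswith("_"):
                columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop:
                fields = line.split()
                if len(fields) != len(columns):
                    raise ParticleTableError(
                        f"{path}: row {len(rows)} has {len(fields)} fields, expected {len(columns)}"
                    )
                rows.append(fields)
    if not columns:
        raise ParticleTableError(f"{path}: no loop_ block found")
    return columns, rows


def _parse_csv_table(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            columns = [c.strip() for c in next(reader)]
        except StopIteration:
            raise ParticleTableError(f"{path}: empty file") from None
        rows = [row for row in reader if row]
    return columns, rows


def _require(columns: Sequence[str], required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in columns:
            raise ParticleTableError(f"{path}: missing required column '{col}'")


def _to_float(cell: str, row_index: int, column: str, path: Path) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParticleTableError(
            f"{path}: non-numeric value {cell!r} in column '{column}', data row {row_index}"
        ) from None


def read_particle_table(
    path: str | Path,
    dialect: str = "star",
    pixel_size_A: float = 1.0,
    euler_convention: str = "ZYZ",
    coords_in_pixels: bool = True,
) -> ParticleSet:
    """Read a particle pose table into a :class:`ParticleSet`.

    Coordinates are converted to Å as ``(coordinate - origin_offset) *
    pixel_size_A`` when stored in pixels (``coords_in_pixels=True``,
    the default for refinement tables), otherwise taken as Å directly.
    Angles are intrinsic Euler angles in degrees.
    """
    path = Path(path)
    if dialect == "star":
        columns, rows = _parse_star_table(path)
        coord_cols, angle_cols, origin_cols = _STAR_COORD, _STAR_ANGLE, _STAR_ORIGIN
        tomo_col, class_col, id_col = _STAR_TOMO, _STAR_CLASS, _STAR_ID
    elif dialect == "csv":
        columns, rows = _parse_csv_table(path)
        coord_cols, angle_cols, origin_cols = _CSV_COORD, _CSV_ANGLE, _CSV_ORIGIN
        tomo_col, class_col, id_col = _CSV_TOMO, _CSV_CLASS, _CSV_ID
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'star' or 'csv'")

    _require(columns, list(coord_cols) + list(angle_cols), path)
    col_index = {c: i for i, c in enumerate(columns)}
    have_origin = all(c in col_index for c in origin_cols)

    poses: list[ParticlePose] = []
    scale = float(pixel_size_A) if coords_in_pixels else 1.0
    for r, row in enumerate(rows):
        coords = np.array([_to_float(row[col_index[c]], r, c, path) for c in coord_cols])
        if have_origin:
            coords = coords - np.array(
                [_to_float(row[col_index[c]], r, c, path) for c in origin_cols]
            )
        angles = [_to_float(row[col_index[c]], r, c, path) for c in angle_cols]
        rotation = euler_to_matrix(np.array(angles), euler_convention)[0]
        tomo = str(row[col_index[tomo_col]]) if tomo_col in col_index else "tomo_0"
        label = None
        if class_col in col_index:
            label = int(_to_float(row[col_index[class_col]], r, class_col, path))
        if id_col in col_index and dialect == "csv":
            pid = int(_to_float(row[col_index[id_col]], r, id_col, path))
        else:
            pid = r
        poses.append(
            ParticlePose(
                particle_id=pid,
                tomo_id=tomo,
                center=coords * scale,
                rotation=rotation,
                class_label=label,
            )
        )
    return ParticleSet(poses, pixel_size_A=pixel_size_A, source=str(path))


def write_particle_table(
    pset: ParticleSet,
    path: str | Path,
    dialect: str = "star",
    euler_convention: str = "ZYZ",
) -> None:
    """Write a :class:`ParticleSet` back to a table.

    Coordinates are emitted in pixels (centre / pixel size) with no origin
    columns, angles in degrees; output is bit-stable for identical input.
    """
    if len(pset) == 0:
        raise ValueError("refusing to write an empty particle set")
    path = Path(path)
    coords_px = pset.centers / pset.pixel_size_A
    angles = matrix_to_euler(pset.rotations, euler_convention)

    if dialect == "star":
        cols = [_STAR_TOMO, *_STAR_COORD, *_STAR_ANGLE]
        if pset.class_labels is not None:
            cols.append(_STAR_CLASS)
        with open(path, "w") as fh:
            fh.write("data_particles\n\nloop_\n")
            for i, c in enumerate(cols, start=1):
                fh.write(f"_{c} #{i}\n")
            for i in range(len(pset)):
                fields = [str(pset.tomo_ids[i])]
                fields += [f"{v:.8f}" for v in coords_px[i]]
                fields += [f"{v:.10f}" for v in angles[i]]
                if pset.class_labels is not None:
                    fields.append(str(int(pset.class_labels[i])))
                fh.write(" ".join(fields) + "\n")
    elif dialect == "csv":
        cols = [_CSV_ID, _CSV_TOMO, *_CSV_COORD, *_CSV_ANGLE]
        if pset.class_labels is not None:
            cols.append(_CSV_CLASS)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for i in range(len(pset)):
                row: list[str] = [str(int(pset.particle_ids[i])), str(pset.tomo_ids[i])]
                row += [f"{v:.8f}" for v in coords_px[i]]
                row += [f"{v:.10f}" for v in angles[i]]
                if pset.class_labels is not None:
                    row.append(str(int(pset.class_labels[i])))
                writer.writerow(row)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'star' or 'csv'")


# ---------------------------------------------------------------------------
# Tomogram metadata

_MRC_HEADER_SIZE = 1024


def _read_mrc_header(path: Path) -> tuple[tuple[int, int, int], float]:
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_SIZE)
    if len(header) < _MRC_HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header ({len(header)} bytes)")
    if header[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ValueError(f"{path}: not an MRC2014 file (missing MAP magic)")
    nx, ny, nz = struct.unpack("<3i", header[0:12])
    mx, my, mz = struct.unpack("<3i", header[28:40])
    xlen, ylen, zlen = struct.unpack("<3f", header[40:52])
    if min(nx, ny, nz) <= 0:
        raise ValueError(f"{path}: invalid MRC dimensions ({nx}, {ny}, {nz})")
    voxel = xlen / mx if mx > 0 else 0.0
    return (nx, ny, nz), float(voxel)


def read_tomo_meta(
    path: str | Path,
    tomo_id: str | None = None,
    voxel_size_A: float | None = None,
    sidecar: str | Path | None = None,
) -> TomoMeta:
    """Read tomogram dimensions and voxel size.

    ``path`` is an MRC2014 file or a JSON/YAML sidecar (keys ``tomo_id``,
    ``dims_voxels``, ``voxel_size_A``).  A sidecar passed alongside an MRC
    file, or an explicit ``voxel_size_A``, overrides the header value.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".yaml", ".yml"):
        data = _load_sidecar(path)
        dims = tuple(int(d) for d in data["dims_voxels"])
        voxel = float(data["voxel_size_A"])
        name = str(data.get("tomo_id", path.stem))
    else:
        dims, voxel = _read_mrc_header(path)
        name = path.stem
        if sidecar is not None:
            data = _load_sidecar(Path(sidecar))
            if "voxel_size_A" in data:
                logger.info(
                    "sidecar %s overrides header voxel size %.4f -> %s",
                    sidecar, voxel, data["voxel_size_A"],
                )
                voxel = float(data["voxel_size_A"])
            if "dims_voxels" in data:
                dims = tuple(int(d) for d in data["dims_voxels"])
            name = str(data.get("tomo_id", name))
    if voxel_size_A is not None:
        logger.info("explicit voxel size %.4f overrides %s", voxel_size_A, voxel)
        voxel = float(voxel_size_A)
    if voxel <= 0:
        raise ValueError(
            f"{path}: voxel size absent or non-positive ({voxel}); pass voxel_size_A explicitly"
        )
    return TomoMeta(tomo_id=tomo_id or name, dims_voxels=dims, voxel_size_A=voxel)


def _load_sidecar(path: Path) -> dict:
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
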