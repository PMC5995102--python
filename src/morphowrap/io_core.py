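"""Readers and writers for external formats, configuration and logging.

Formats handled here:

* multi-page grayscale TIFF intensity stacks (µm voxel spacing supplied
  by the caller or recovered from TIFF/ImageJ metadata — an explicit
  spacing always wins, since microscope metadata is often unreliable);
* cast files: OBJ vertex lists plus a CSV sidecar mapping grid-point ids
  to vertex lines (OBJ has no vertex naming, and invalid points are
  omitted from the vertex list, so the sidecar is what keeps ids stable
  across specimens);
* surface meshes as OBJ (v/f lines, via trimesh);
* point tables (CSV/TSV) for downstream CAD / FEA / streamline tools;
* coloured point clouds as ASCII PLY;
* the YAML study configuration.

All coordinates are micrometres throughout; nothing here rescales.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

from .surface import IntensityVolume, TriangleMesh
from .wrap import Cast, LandmarkPairSet

__all__ = [
    "SpecimenRecord",
    "StudyConfig",
    "read_stack",
    "write_cast",
    "read_cast",
    "sidecar_path",
    "export_point_table",
    "read_mesh",
    "write_mesh",
    "write_ply",
    "read_landmarks",
    "write_landmarks",
]

logger = logging.getLogger("morphowrap")

_COORD_FMT = "%.8f"


@dataclass
class SpecimenRecord:
    """One specimen of a study: identity, treatment group and input files.

    Exactly one of ``stack_path`` (intensity stack, needs the extract
    stage) or ``mesh_path`` (pre-extracted surface) must be present.
    """

    specimen_id: str
    group_label: str
    stack_path: str | None = None
    mesh_path: str | None = None
    landmarks_path: str | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if (self.stack_path is None) == (self.mesh_path is None):
            raise ValueError(
                f"specimen {self.specimen_id!r}: exactly one of stack_path/mesh_path required"
            )


@dataclass
class StudyConfig:
    """Tunable parameters of a study, with the workflow's defaults.

    Lengths in µm.  ``grid_rows * grid_cols`` defaults to 128,000 points;
    ``p_threshold`` / ``q_threshold`` are the display cut-offs for the
    significance heat maps; ``allow_scaling`` switches the Procrustes fit
    from the size-retaining (form) to the size-adjusted (shape) variant.
    """

    blur_sigma_um: float = 5.0
    cube_size_um: float = 15.0
    smoothing_passes: int = 2
    grid_rows: int = 400
    grid_cols: int = 320
    p_threshold: float = 0.01
    q_threshold: float = 0.005
    ci_level: float = 0.95
    allow_scaling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("blur_sigma_um", "cube_size_um", "p_threshold", "q_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smoothing_passes < 0:
            raise ValueError("smoothing_passes must be non-negative")
        if self.smoothing_passes > 3:
            warnings.warn("more than 3 smoothing passes shrinks the mesh", stacklevel=2)
        if self.grid_rows < 2 or self.grid_cols < 2 or self.grid_rows * self.grid_cols < 4:
            raise ValueError("grid must contain at least 2x2 points")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _metadata_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort (dz, dy, dx) in µm from ImageJ metadata / TIFF tags."""
    dz = dy = dx = None
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        dz = float(meta["spacing"])
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags and "YResolution" in tags:
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
        if xres[0] and yres[0]:
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
    if dz is None or dy is None or dx is None:
        return None
    return (dz, dy, dx)


def read_stack(
    path: str | Path, spacing: tuple[float, float, float] | None = None
) -> IntensityVolume:
    """Read a multi-page grayscale TIFF stack as an intensity volume.

    ``spacing`` is (dz, dy, dx) in µm and overrides any TIFF metadata
    (mismatches are logged); without either, a ``ValueError`` is raised.
    Single-slice files are accepted with a warning.  RGB / multi-sample
    files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel and page.samplesperpixel > 1:
            raise ValueError(f"{path.name}: not grayscale ({page.samplesperpixel} samples/pixel)")
        arr = tif.asarray()
        meta_spacing = _metadata_spacing(tif)
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: single-slice stack", stacklevel=2)
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a grayscale page stack, got shape {arr.shape}")
    if spacing is not None:
        if meta_spacing is not None and not np.allclose(spacing, meta_spacing, rtol=1e-3):
            logger.warning(
                "%s: supplied spacing %s overrides TIFF metadata %s",
                path.name,
                spacing,
                meta_spacing,
            )
        use = spacing
    elif meta_spacing is not None:
        use = meta_spacing
    else:
        raise ValueError(f"{path.name}: voxel spacing not supplied and not in metadata")
    if any(s <= 0 for s in use):
        raise ValueError(f"{path.name}: non-positive voxel spacing {use}")
    return IntensityVolume(arr, tuple(float(s) for s in use))


def sidecar_path(path: str | Path) -> Path:
    """The id-map sidecar accompanying a cast OBJ file."""
    path = Path(path)
    return path.with_name(path.name + ".index.csv")


def write_cast(cast: Cast, path: str | Path) -> None:
    """Write a cast as an OBJ vertex list plus an id sidecar.

    Only valid points appear as ``v`` lines (casts are point sets, not
    meshes, so no faces are written).  The sidecar records, for each
    valid grid id, the 1-based vertex line it maps to, plus the grid
    shape, so ids survive the round trip exactly.
    """
    if cast.n_valid == 0:
        raise ValueError("cast has no valid points")
    path = Path(path)
    ids = cast.valid_ids()
    with open(path, "w") as fh:
        fh.write("# morphowrap cast (vertices only; ids in sidecar)\n")
        for x, y, z in cast.coords[ids]:
            fh.write(f"v {_COORD_FMT % x} {_COORD_FMT % y} {_COORD_FMT % z}\n")
    with open(sidecar_path(path), "w") as fh:
        fh.write(f"# rows={cast.n_rows} cols={cast.n_cols}\n")
        fh.write("id,vertex\n")
        for line_no, i in enumerate(ids, start=1):
            fh.write(f"{i},{line_no}\n")


def read_cast(path: str | Path) -> Cast:
    """Read a cast written by :func:`write_cast` (OBJ + sidecar)."""
    path = Path(path)
    verts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("v "):
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path.name}: malformed vertex line {line!r}")
                verts.append([float(p) for p in parts[1:]])
    verts = np.asarray(verts, dtype=float)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing cast sidecar {side}")
    with open(side) as fh:
        header = fh.readline()
        if not header.startswith("# rows="):
            raise ValueError(f"{side.name}: missing grid-shape header")
        tokens = dict(tok.split("=") for tok in header[2:].split())
        n_rows, n_cols = int(tokens["rows"]), int(tokens["cols"])
        table = pd.read_csv(fh)
    ids = table["id"].to_numpy()
    lines = table["vertex"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{side.name}: duplicate ids in sidecar")
    if len(verts) == 0 or lines.min() < 1 or lines.max() > len(verts):
        raise ValueError(f"{side.name}: sidecar references a missing vertex line")
    n = n_rows * n_cols
    if ids.min() < 0 or ids.max() >= n:
        raise ValueError(f"{side.name}: id outside grid of {n} points")
    coords = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    coords[ids] = verts[lines - 1]
    valid[ids] = True
    return Cast(n_rows, n_cols, coords, valid)


def export_point_table(model, path: str | Path, dialect: str = "csv") -> None:
    """Write a model or cast as an id,x,y,z table (µm) for downstream tools."""
    if dialect not in ("csv", "tsv"):
        raise ValueError("dialect must be 'csv' or 'tsv'")
    coords = np.asarray(model.coords, dtype=float)
    valid = np.asarray(model.valid, dtype=bool)
    if not valid.any():
        raise ValueError("empty model: no valid points to export")
    ids = np.flatnonzero(valid)
    frame = pd.DataFrame(
        {"id": ids, "x": coords[ids, 0], "y": coords[ids, 1], "z": coords[ids, 2]}
    )
    frame.to_csv(path, sep="," if dialect == "csv" else "\t", index=False)


def read_mesh(path: str | Path) -> TriangleMesh:
    """Load a triangulated OBJ surface mesh (vertices in µm)."""
    loaded = trimesh.load(str(path), file_type="obj", process=False)
    if isinstance(loaded, trimesh.Scene):  # pragma: no cover - single-mesh files expected
        loaded = loaded.to_geometry()
    return TriangleMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))


def write_ply(
    points: np.ndarray, colors: np.ndarray, path: str | Path, comment: str = ""
) -> None:
    """ASCII PLY point cloud with per-vertex uchar colours (deterministic)."""
    points = np.asarray(points, dtype=float)
    colors = np.asarray(colors)
    if colors.dtype.kind == "f":
        colors = np.clip(np.rint(colors * 255), 0, 255).astype(np.uint8)
    if points.shape[0] != colors.shape[0]:
        raise ValueError("point and colour counts differ")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        if comment:
            fh.write(f"comment {comment}\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        for (x, y, z), (r, g, b) in zip(points, colors):
            fh.write(f"{_COORD_FMT % x} {_COORD_FMT % y} {_COORD_FMT % z} {r} {g} {b}\n")


def read_landmarks(path: str | Path) -> LandmarkPairSet:
    """Landmark CSV: columns name,u_template,v_template,u_specimen,v_specimen."""
    table = pd.read_csv(path)
    required = {"name", "u_template", "v_template", "u_specimen", "v_specimen"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"landmark file missing columns {sorted(missing)}")
    return LandmarkPairSet(
        table[["u_template", "v_template"]].to_numpy(float),
        table[["u_specimen", "v_specimen"]].to_numpy(float),
        names=list(table["name"]),
    )


def write_landmarks(pairs: LandmarkPairSet, path: str | Path) -> None:
    names = pairs.names or [f"lm{i}" for i in range(len(pairs))]
    frame = pd.DataFrame(
        {
            "name": names,
            "u_template": pairs.source[:, 0],
            "v_template": pairs.source[:, 1],
            "u_specimen": pairs.target[:, 0],
            "v_specimen": pairs.target[:, 1],
        }
    )
    frame.to_csv(path, index=False)
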