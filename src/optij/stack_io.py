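"""Projection-stack I/O: TIFF reading/writing plus a sidecar text manifest.

Conventions
-----------
* Arrays are indexed ``(angle, row, column)``; 0-based, row 0 / column 0 at
  the top-left pixel, pixel centers at integer coordinates.
* The detector center column is ``(n_columns - 1) / 2`` (a float), so even
  and odd widths both have a symmetric center.
* The rotation axis is nominally vertical (along the row index); one
  sinogram is extracted per image row.
* Metadata (angles, pixel size, modality, processing stage) travels in a
  YAML ``key: value`` manifest written next to the TIFF, because plain TIFF
  tags vary by dialect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import FormatError, GeometryError

__all__ = [
    "AcquisitionGeometry",
    "ProjectionStack",
    "detector_center_col",
    "read_stack",
    "write_stack",
    "read_manifest",
    "write_manifest",
    "manifest_path",
]

#: Degrees per step of the rotation stage at its maximum of 1024 steps per
#: revolution; exposed as the default smallest realizable angular increment.
DEFAULT_MIN_STEP_DEG = 360.0 / 1024.0

MODALITIES = ("tOPT", "eOPT")
STAGES = ("raw", "flatfield_corrected", "attenuation", "shifted")


def detector_center_col(n_columns: int) -> float:
    """Center column of an ``n_columns``-wide detector (symmetric float)."""
    return (n_columns - 1) / 2.0


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Equiangular acquisition over (a fraction of) a revolution.

    Parameters
    ----------
    n_projections : int
        Number of angles acquired (>= 2).
    angular_range_deg : float
        Degrees covered by the scan, in ``(0, 360]``.
    start_angle_deg : float
        Angle of the first projection.
    pixel_size_um : float
        Object-space pixel pitch (camera pitch / magnification), > 0.
    min_step_deg : float
        Smallest realizable angular step of the rotation stage.
    modality : str
        ``"tOPT"`` (transmission) or ``"eOPT"`` (emission).
    """

    n_projections: int
    angular_range_deg: float = 360.0
    start_angle_deg: float = 0.0
    pixel_size_um: float = 1.0
    min_step_deg: float = DEFAULT_MIN_STEP_DEG
    modality: str = "tOPT"

    def __post_init__(self):
        if self.n_projections < 2:
            raise GeometryError(
                f"n_projections must be >= 2, got {self.n_projections}")
        if not 0.0 < self.angular_range_deg <= 360.0:
            raise GeometryError(
                f"angular_range_deg must be in (0, 360], got {self.angular_range_deg}")
        if self.pixel_size_um <= 0:
            raise GeometryError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.modality not in MODALITIES:
            raise GeometryError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def step_deg(self) -> float:
        """Angular increment between consecutive projections."""
        return self.angular_range_deg / self.n_projections

    @property
    def angles_deg(self) -> np.ndarray:
        """Angle of projection ``i``: ``start + i * range / n`` (never repeats)."""
        return (self.start_angle_deg
                + np.arange(self.n_projections) * self.step_deg)

    def to_dict(self) -> dict:
        return {
            "n_projections": int(self.n_projections),
            "angular_range_deg": float(self.angular_range_deg),
            "start_angle_deg": float(self.start_angle_deg),
            "pixel_size_um": float(self.pixel_size_um),
            "min_step_deg": float(self.min_step_deg),
            "modality": self.modality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            n_projections=int(d["n_projections"]),
            angular_range_deg=float(d.get("angular_range_deg", 360.0)),
            start_angle_deg=float(d.get("start_angle_deg", 0.0)),
            pixel_size_um=float(d.get("pixel_size_um", 1.0)),
            min_step_deg=float(d.get("min_step_deg", DEFAULT_MIN_STEP_DEG)),
            modality=d.get("modality", "tOPT"),
        )


@dataclass
class ProjectionStack:
    """Angle-indexed image cube plus acquisition metadata.

    ``data`` is ``(angle, row, column)`` float; ``stage`` records where in
    the pipeline the values sit (camera counts vs. attenuation).
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    stage: str = "raw"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"stack data must be 3-D (angle, row, column), got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if self.data.shape[0] != self.geometry.n_projections:
            raise GeometryError(
                f"stack has {self.data.shape[0]} angle planes but geometry "
                f"declares n_projections={self.geometry.n_projections}")
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "attenuation" and not np.all(np.isfinite(self.data)):
            raise FormatError("attenuation-stage stack contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def n_columns(self) -> int:
        return self.data.shape[2]

    @property
    def center_col(self) -> float:
        return detector_center_col(self.n_columns)

    @property
    def angles_deg(self) -> np.ndarray:
        return self.geometry.angles_deg

    def with_data(self, data: np.ndarray, stage: str | None = None) -> "ProjectionStack":
        return ProjectionStack(data=data, geometry=self.geometry,
                               stage=stage if stage is not None else self.stage,
                               extras=dict(self.extras))


def manifest_path(path: str | os.PathLike) -> Path:
    """Sidecar manifest location for a TIFF path or stack directory."""
    p = Path(path)
    if p.is_dir():
        return p / "manifest.yaml"
    return p.with_suffix(p.suffix + ".manifest.yaml")


def write_manifest(path: str | os.PathLike, payload: dict) -> Path:
    mp = manifest_path(path)
    with open(mp, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return mp


def read_manifest(path: str | os.PathLike) -> dict | None:
    mp = manifest_path(path)
    if not mp.exists():
        return None
    with open(mp) as fh:
        return yaml.safe_load(fh)


def _list_tiff_pages(directory: Path) -> list[Path]:
    exts = {".tif", ".tiff"}
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in exts)
    if not files:
        raise FormatError(f"no TIFF files found in directory {directory}")
    return files


def _read_pages(path: Path) -> np.ndarray:
    if path.is_dir():
        pages = []
        for f in _list_tiff_pages(path):
            img = tifffile.imread(f)
            if img.ndim == 3:  # multi-page file inside a directory
                pages.extend(img)
            elif img.ndim == 2:
                pages.append(img)
            else:
                raise FormatError(f"{f}: expected 2-D page, got shape {img.shape}")
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise FormatError(
                f"inconsistent page shapes in {path}: {sorted(shapes)}")
        return np.stack(pages)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2-D pages, got shape {data.shape}")
    return data


def read_stack(path: str | os.PathLike,
               geometry: AcquisitionGeometry | None = None) -> ProjectionStack:
    """Read a projection stack from a multi-page TIFF or a directory of TIFFs.

    Lexicographic file order defines angular order for directories; a sidecar
    manifest, when present, supplies (or overrides) geometry and stage.
    Values are converted to floating point with the original dynamic range
    preserved (no rescaling).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file or directory: {path}")
    data = _read_pages(path)

    manifest = read_manifest(path)
    stage = "raw"
    extras: dict = {}
    if manifest is not None:
        if geometry is None and "geometry" in manifest:
            geometry = AcquisitionGeometry.from_dict(manifest["geometry"])
        stage = manifest.get("stage", stage)
        extras = manifest.get("extras", {}) or {}
        scaling = manifest.get("uint16_scaling")
        if scaling is not None:
            lo, hi = float(scaling["min"]), float(scaling["max"])
            data = data.astype(np.float64) / 65535.0 * (hi - lo) + lo
    if geometry is None:
        raise GeometryError(
            f"no geometry given and no manifest found next to {path}")
    if data.shape[0] != geometry.n_projections:
        raise GeometryError(
            f"{path} holds {data.shape[0]} pages but geometry declares "
            f"n_projections={geometry.n_projections}")
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    return ProjectionStack(data=data, geometry=geometry, stage=stage, extras=extras)


def write_stack(stack, path: str | os.PathLike,
                dtype_policy: str = "float32") -> Path:
    """Write a stack (or any leading-index-paged cube) as a multi-page TIFF.

    ``float32`` is a bit-exact round trip; ``uint16-scaled`` linearly maps
    ``[min, max]`` onto ``[0, 65535]`` and records the scaling in the
    manifest so :func:`read_stack` can undo it.
    """
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory does not exist: {path.parent}")

    data = np.asarray(getattr(stack, "data", getattr(stack, "voxels", stack)))
    payload: dict = {}
    geometry = getattr(stack, "geometry", None)
    if geometry is not None:
        payload["geometry"] = geometry.to_dict()
        payload["angles_deg"] = [float(a) for a in geometry.angles_deg]
    stage = getattr(stack, "stage", None)
    if stage is not None:
        payload["stage"] = stage
    extras = getattr(stack, "extras", None)
    if extras:
        payload["extras"] = extras

    if dtype_policy == "float32":
        tifffile.imwrite(path, data.astype(np.float32),
                         photometric="minisblack")
    elif dtype_policy == "uint16-scaled":
        if not np.all(np.isfinite(data)):
            raise ValueError("uint16-scaled policy requires finite values")
        lo, hi = float(data.min()), float(data.max())
        scale = (hi - lo) or 1.0
        q = np.round((data - lo) / scale * 65535.0).astype(np.uint16)
        tifffile.imwrite(path, q, photometric="minisblack")
        payload["uint16_scaling"] = {"min": lo, "max": hi}
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")

    write_manifest(path, payload)
    return path
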