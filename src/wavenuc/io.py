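"""Readers and writers for volumes, labels, tables and run configuration.

On-disk formats: multi-page grayscale TIFF for image and label volumes, CSV
for centroid/truth/feature tables (0-based voxel coordinates, declared in
the headers), JSON for run manifests, YAML or JSON for configuration.

Coordinate convention throughout the package: 0-based ``(x, y, z)`` with
``z`` the TIFF page index; in-memory volumes are numpy arrays indexed
``[z, y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageVolume",
    "RunConfig",
    "read_volume",
    "write_volume",
    "write_labels",
    "read_truth_csv",
    "write_truth_csv",
]

MAX_LABELS = 65535  # 16-bit label TIFF


@dataclass
class ImageVolume:
    """A 3D intensity grid with optional physical voxel size.

    ``voxels`` is indexed ``[z, y, x]``; ``voxel_size`` is (x, y, z) in
    micrometres when known.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None, ...]
        if self.voxels.ndim != 3 or any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to/from YAML or JSON."""

    radius: float = 9.0
    scales: list[float] | None = None  # default: radius -1 / radius / radius +1
    similarity_tol: float = 0.10
    overlap_thresh: float = 0.80
    intensity_floor: float = 0.20
    shift_frac: float = 1.0 / 3.0
    min_size_frac: float = 0.20
    colocation_tol: float = 2.0
    h_frac: float = 0.02
    max_dist: float | None = None  # matching cap; default: radius
    density_radius: float = 30.0
    h_sorting_bin: int = 500
    sphericity_thresh: float = 0.90
    aspect_thresh: float = 0.70
    voxel_size: tuple[float, float, float] | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.radius < 2:
            raise ValueError("radius must be >= 2 px")
        for name in ("overlap_thresh", "intensity_floor", "shift_frac",
                     "min_size_frac", "similarity_tol"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.voxel_size is not None:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["voxel_size"] is not None:
            d["voxel_size"] = list(d["voxel_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def read_volume(
    path: str | Path, voxel_size: tuple[float, float, float] | None = None
) -> ImageVolume:
    """Load a multi-page grayscale TIFF z-stack (page index = z).

    Preserves the stored dtype.  RGB/multichannel pages are rejected: the
    pipeline operates on single-channel nuclear stains.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale z-stack, got shape {arr.shape}")
    with tifffile.TiffFile(path) as tf:
        photometric = tf.pages[0].photometric
    if photometric not in (
        tifffile.PHOTOMETRIC.MINISBLACK,
        tifffile.PHOTOMETRIC.MINISWHITE,
    ):
        raise ValueError(f"{path}: unsupported photometric layout {photometric!r}")
    return ImageVolume(voxels=arr, voxel_size=voxel_size)


def write_volume(volume: ImageVolume | np.ndarray, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, one page per z slice."""
    arr = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume)
    tifffile.imwrite(Path(path), arr)


def _centroid_frame(result) -> pd.DataFrame:
    rows = []
    for n in result.nuclei:
        cx, cy, cz = n.centroid
        z0, z1 = n.z_range
        rows.append(
            {
                "id": n.id,
                "x": cx,
                "y": cy,
                "z": cz,
                "volume_voxels": n.volume,
                "center_intensity": n.center_intensity,
                "z_min": z0,
                "z_max": z1,
            }
        )
    cols = ["id", "x", "y", "z", "volume_voxels", "center_intensity", "z_min", "z_max"]
    return pd.DataFrame(rows, columns=cols)


def write_labels(result, path: str | Path) -> None:
    """Write a segmentation result: label TIFF + centroid CSV + manifest.

    ``<path>`` gets the 16-bit label volume (0 = background); alongside it,
    ``<stem>_centroids.csv`` (0-based voxel coordinates) and
    ``<stem>_manifest.json`` recording the parameters used.
    """
    path = Path(path)
    if len(result.nuclei) > MAX_LABELS:
        raise ValueError(f"{len(result.nuclei)} labels exceed 16-bit capacity")
    tifffile.imwrite(path, result.label_volume.astype(np.uint16))
    _centroid_frame(result).to_csv(path.with_name(path.stem + "_centroids.csv"), index=False)
    manifest = {"n_nuclei": len(result.nuclei), "params": _jsonable(result.params)}
    path.with_name(path.stem + "_manifest.json").write_text(json.dumps(manifest, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_truth_csv(truth, path: str | Path) -> None:
    """Ground truth table: id, x, y, z (0-based voxels), radius, intensity."""
    df = pd.DataFrame(
        {
            "id": np.arange(1, len(truth.centers) + 1),
            "x": truth.centers[:, 0],
            "y": truth.centers[:, 1],
            "z": truth.centers[:, 2],
            "radius": truth.radii,
            "intensity": truth.intensities,
        }
    )
    df.to_csv(Path(path), index=False)


def read_truth_csv(path: str | Path):
    """Read a ground-truth/annotation CSV (columns id,x,y,z[,radius[,intensity]])."""
    from .synthetic import GroundTruth

    df = pd.read_csv(Path(path))
    required = {"x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    n = len(df)
    radii = df["radius"].to_numpy(float) if "radius" in df else np.full(n, np.nan)
    inten = df["intensity"].to_numpy(float) if "intensity" in df else np.full(n, np.nan)
    return GroundTruth(
        centers=df[["x", "y", "z"]].to_numpy(float), radii=radii, intensities=inten
    )
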