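"""Reading and writing image/mask volumes and Dice evaluation reports.

Volumes are ordered stacks of 2D grayscale slices stored either as a
multi-page TIFF or as a directory of numbered PNG/TIFF slices. Intensities
are rescaled to [0, 1] at load time regardless of the source bit depth;
binary masks are stored on disk as 8-bit {0, 255} so they can be inspected
in any image viewer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

_SLICE_EXTENSIONS = {".png", ".tif", ".tiff"}


@dataclass
class ImageVolume:
    """Z-ordered stack of grayscale slices with intensities in [0, 1]."""

    voxels: np.ndarray  # (Z, H, W) float
    source_dtype: str = "float64"
    voxel_size_nm: Optional[float] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D (Z,H,W), got {self.voxels.ndim}D")
        if self.voxels.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class MaskVolume:
    """Binary labels for one structure, possibly annotated on a slice subset.

    ``annotated_slices`` lists the z-indices where labels are defined; code
    consuming sparse masks must go through :meth:`slice_labels`, which
    refuses access to unannotated slices.
    """

    labels: np.ndarray  # (Z, H, W) in {0, 1}
    annotated_slices: tuple[int, ...] = ()

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3D (Z,H,W)")
        if self.labels.shape[0] < 1:
            raise ValueError("mask must contain at least one slice")
        uniq = np.unique(self.labels)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"mask values must be binary, found {uniq[:5]}")
        self.labels = self.labels.astype(np.uint8)
        if not self.annotated_slices:
            self.annotated_slices = tuple(range(self.labels.shape[0]))
        self.annotated_slices = tuple(sorted(int(z) for z in self.annotated_slices))
        z = self.labels.shape[0]
        if any(i < 0 or i >= z for i in self.annotated_slices):
            raise ValueError("annotated_slices out of range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def is_annotated(self, z: int) -> bool:
        return z in set(self.annotated_slices)

    def slice_labels(self, z: int) -> np.ndarray:
        """Labels of slice ``z``; raises on unannotated slices of a sparse mask."""
        if not self.is_annotated(z):
            raise KeyError(f"slice {z} is not annotated")
        return self.labels[z]


@dataclass
class DiceReport:
    """Per-slice Dice values plus the two volume-level aggregates."""

    per_slice: list[tuple[int, float]]
    average_dice: float
    dice_3d: float
    structure_name: str = ""

    def validate(self):
        vals = [v for _, v in self.per_slice]
        if any(not (0.0 <= v <= 1.0) for v in vals + [self.average_dice, self.dice_3d]):
            raise ValueError("Dice values must lie in [0, 1]")
        if vals and abs(self.average_dice - float(np.mean(vals))) > 1e-9:
            raise ValueError("average_dice does not equal the mean of per-slice values")


# ---------------------------------------------------------------------------

def _natural_key(name: str):
    """Sort key using the numeric components of a filename (robust to padding)."""
    parts = re.split(r"(\d+)", name)
    return [int(p) if p.isdigit() else p for p in parts]


def _rescale(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError(f"float data outside [0,1] in {source}")
        return arr
    raise ValueError(f"unsupported dtype {arr.dtype} in {source}")


def _list_slice_files(path: Path) -> list[Path]:
    files = [p for p in path.iterdir()
             if p.is_file() and p.suffix.lower() in _SLICE_EXTENSIONS]
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF slices found in {path}")
    return sorted(files, key=lambda p: _natural_key(p.name))


def read_volume(path, layout: str = "tiff_stack") -> ImageVolume:
    """Read an :class:`ImageVolume` from a multi-page TIFF or a slice directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if layout == "tiff_stack":
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise ValueError(f"expected single-channel pages in {path}, got shape {raw.shape}")
        src = str(raw.dtype)
        return ImageVolume(_rescale(raw, str(path)), source_dtype=src)
    if layout == "slice_dir":
        files = _list_slice_files(path)
        slices, shape = [], None
        for f in files:
            arr = iio.imread(f)
            if arr.ndim == 3:  # drop trivial channel axes from grayscale PNGs
                if arr.shape[2] in (3, 4) and np.all(arr[..., :1] == arr[..., 1:3]):
                    arr = arr[..., 0]
                else:
                    raise ValueError(f"multi-channel slice not supported: {f.name}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"slice shape mismatch: {f.name} has {arr.shape}, expected {shape}")
            slices.append(_rescale(arr, f.name))
        src = str(iio.imread(files[0]).dtype)
        return ImageVolume(np.stack(slices), source_dtype=src)
    raise ValueError(f"unknown layout {layout!r}")


def read_mask(path, layout: str = "tiff_stack") -> MaskVolume:
    """Read a binary mask stack; on-disk values >50% intensity map to 1."""
    vol = read_volume(path, layout)
    return MaskVolume((vol.voxels > 0.5).astype(np.uint8))


def write_volume(v, path, layout: str = "tiff_stack") -> None:
    """Write a volume as 8-bit; masks become {0, 255}."""
    path = Path(path)
    if isinstance(v, MaskVolume):
        data = (v.labels.astype(np.uint8)) * 255
    elif isinstance(v, ImageVolume):
        data = np.clip(np.round(v.voxels * 255.0), 0, 255).astype(np.uint8)
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")
    if data.shape[0] < 1:
        raise ValueError("refusing to write an empty volume")
    if layout == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
    elif layout == "slice_dir":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(data.shape[0] - 1)))
        for z in range(data.shape[0]):
            iio.imwrite(path / f"s{z:0{width}d}.png", data[z])
    else:
        raise ValueError(f"unknown layout {layout!r}")


def write_report(r: DiceReport, path, format: str = "csv") -> None:
    """Serialize a validated :class:`DiceReport` to CSV or JSON."""
    r.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        rows = [{"slice_index": int(z), "dice": float(d)} for z, d in r.per_slice]
        rows.append({"slice_index": "average_dice", "dice": float(r.average_dice)})
        rows.append({"slice_index": "dice_3d", "dice": float(r.dice_3d)})
        pd.DataFrame(rows, columns=["slice_index", "dice"]).to_csv(path, index=False)
    elif format == "json":
        payload = {
            "structure_name": r.structure_name,
            "per_slice": [[int(z), float(d)] for z, d in r.per_slice],
            "average_dice": float(r.average_dice),
            "dice_3d": float(r.dice_3d),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path, format: str = "json") -> DiceReport:
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        return DiceReport(
            per_slice=[(int(z), float(d)) for z, d in payload["per_slice"]],
            average_dice=float(payload["average_dice"]),
            dice_3d=float(payload["dice_3d"]),
            structure_name=payload.get("structure_name", ""),
        )
    if format == "csv":
        df = pd.read_csv(path)
        per, avg, d3 = [], None, None
        for _, row in df.iterrows():
            key = str(row["slice_index"])
            if key == "average_dice":
                avg = float(row["dice"])
            elif key == "dice_3d":
                d3 = float(row["dice"])
            else:
                per.append((int(key), float(row["dice"])))
        return DiceReport(per_slice=per, average_dice=avg, dice_3d=d3)
    raise ValueError(f"unknown report format {format!r}")
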