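"""Per-slice histogram equalization and the context-tiling/stitching scheme.

Training and inference both operate on square tiles: a large context window
(default 2048 px) is cut from the slice and downsampled (default to 512 px)
so the network sees more surrounding anatomy at a reduced resolution.
At inference time overlapping windows cover the slice and the per-tile
confidence maps are upsampled, placed back, and averaged where they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .volume_io import ImageVolume


@dataclass
class TilingPlan:
    context_size: int = 2048   # side of the source window, px
    out_size: int = 512        # side after downsampling, px
    stride: int | None = None  # window step for inference; default context/2
    pad_mode: str = "reflect"

    def __post_init__(self):
        if self.context_size < self.out_size:
            raise ValueError("context_size must be >= out_size")
        if self.stride is None:
            self.stride = max(1, self.context_size // 2)
        if self.stride > self.context_size:
            raise ValueError("stride must be <= context_size")
        if self.pad_mode not in ("reflect", "zero"):
            raise ValueError("pad_mode must be 'reflect' or 'zero'")


# ---------------------------------------------------------------------------

def equalize_slice(img: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Histogram-equalize one slice with a monotone CDF remap.

    Constant slices are returned unchanged (equalization is undefined on
    zero-variance input).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    img = np.asarray(img, dtype=np.float64)
    if img.max() == img.min():
        return img.copy()
    hist, edges = np.histogram(img, bins=n_bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist).astype(np.float64) / img.size
    idx = np.minimum((img * n_bins).astype(np.intp), n_bins - 1)
    return cdf[idx]


def equalize_volume(v: ImageVolume, n_bins: int = 256) -> ImageVolume:
    """Equalize every slice independently (slices in EM stacks drift in brightness)."""
    out = np.stack([equalize_slice(sl, n_bins) for sl in v.voxels])
    return ImageVolume(out, source_dtype=v.source_dtype, voxel_size_nm=v.voxel_size_nm)


# ---------------------------------------------------------------------------

def _pad_to(img: np.ndarray, height: int, width: int, mode: str) -> np.ndarray:
    """Pad bottom/right to at least (height, width).

    Reflect padding is applied iteratively because numpy caps a single
    reflect pad at dim-1.
    """
    while img.shape[0] < height or img.shape[1] < width:
        ph = min(height - img.shape[0], img.shape[0] - 1) if img.shape[0] < height else 0
        pw = min(width - img.shape[1], img.shape[1] - 1) if img.shape[1] < width else 0
        if mode == "zero":
            ph, pw = height - img.shape[0], width - img.shape[1]
            return np.pad(img, ((0, ph), (0, pw)), mode="constant")
        if ph == 0 and pw == 0:  # 1xN edge case: cannot reflect, fall back to edge
            return np.pad(img, ((0, height - img.shape[0]), (0, width - img.shape[1])),
                          mode="edge")
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img


def _downsample(window: np.ndarray, out_size: int, is_mask: bool) -> np.ndarray:
    c = window.shape[0]
    if c == out_size:
        return window.astype(np.float64).copy()
    if is_mask:
        small = resize(window.astype(np.float64), (out_size, out_size), order=0,
                       anti_aliasing=False, preserve_range=True)
        return (small >= 0.5).astype(np.float64)
    factor = c / out_size
    if factor == int(factor):
        f = int(factor)
        return window.reshape(out_size, f, out_size, f).mean(axis=(1, 3))
    return resize(window.astype(np.float64), (out_size, out_size), order=1,
                  anti_aliasing=True, preserve_range=True)


def extract_tiles(slice2d: np.ndarray, plan: TilingPlan,
                  origins: list[tuple[int, int]], is_mask: bool = False) -> list[np.ndarray]:
    """Cut context windows at ``origins`` and downsample each to ``out_size``.

    Images are downsampled by area averaging; masks by nearest neighbour and
    re-binarized at 0.5 so labels never bleed across the boundary.
    """
    slice2d = np.asarray(slice2d)
    H, W = slice2d.shape
    c = plan.context_size
    tiles = []
    for (r, col) in origins:
        if r < 0 or col < 0 or r >= H + c or col >= W + c:
            raise ValueError(f"origin {(r, col)} outside padded bounds of {slice2d.shape}")
        padded = _pad_to(slice2d, r + c, col + c, plan.pad_mode)
        window = padded[r:r + c, col:col + c]
        tiles.append(_downsample(window, plan.out_size, is_mask))
    return tiles


def plan_inference_origins(slice_shape: tuple[int, int], plan: TilingPlan) -> list[tuple[int, int]]:
    """Window origins covering every pixel at least once."""
    H, W = slice_shape
    if H < 1 or W < 1:
        raise ValueError("slice must be at least 1x1")
    c, s = plan.context_size, plan.stride

    def starts(n: int) -> list[int]:
        if n <= c:
            return [0]
        pos = list(range(0, n - c + 1, s))
        if pos[-1] + c < n:
            pos.append(n - c)
        return pos

    return [(r, col) for r in starts(H) for col in starts(W)]


def stitch_predictions(tiles: list[np.ndarray], origins: list[tuple[int, int]],
                       slice_shape: tuple[int, int], plan: TilingPlan) -> np.ndarray:
    """Upsample tiles back to context resolution, place, and average overlaps."""
    if len(tiles) != len(origins):
        raise ValueError("tiles and origins must have the same length")
    H, W = slice_shape
    c = plan.context_size
    ph = max(H, max(r for r, _ in origins) + c)
    pw = max(W, max(col for _, col in origins) + c)
    acc = np.zeros((ph, pw), dtype=np.float64)
    weight = np.zeros((ph, pw), dtype=np.float64)
    for tile, (r, col) in zip(tiles, origins):
        if tile.shape[0] != c:
            up = resize(tile.astype(np.float64), (c, c), order=1,
                        anti_aliasing=False, preserve_range=True)
        else:
            up = tile.astype(np.float64)
        acc[r:r + c, col:col + c] += up
        weight[r:r + c, col:col + c] += 1.0
    if np.any(weight[:H, :W] == 0):
        raise ValueError("stitching left uncovered pixels; check origins")
    return (acc[:H, :W] / weight[:H, :W])
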