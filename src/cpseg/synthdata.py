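"""Synthetic EM-like volumes with nested nucleus/nucleolus structures.

The generator emulates the data regime that drives the toolkit's design,
not EM appearance: large dark nuclei with a bright membrane rim, small
dense nucleoli strictly inside them occupying a fraction of a percent of
slice area (so uniform crops are mostly empty), smooth background texture,
per-slice brightness drift along Z, and Gaussian noise. Structures are
generated prolate along Z: at near-isotropic FIB-SEM resolution organelles
persist across far more slices than the annotation spacing, and desk-scale
volumes compress Z, so elongated ellipsoids preserve that slice-to-slice
persistence. Masks mark the generated geometry exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .volume_io import ImageVolume, MaskVolume

# intensity palette (before drift/noise)
_BACKGROUND = 0.62
_NUCLEUS_INTERIOR = 0.42
_RIM = 0.88
_NUCLEOLUS = 0.12


@dataclass
class SynthConfig:
    z: int = 64
    h: int = 512
    w: int = 512
    n_cells: int = 4
    nucleus_radius_range: tuple[float, float] = (60.0, 90.0)
    nucleolus_radius_range: tuple[float, float] = (5.0, 8.0)
    nucleolus_fg_target: float = 0.001   # fraction of total voxels
    noise_sigma: float = 0.04
    brightness_drift_amplitude: float = 0.15
    texture_scale: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if min(self.z, self.h, self.w) < 1:
            raise ValueError("volume dimensions must be positive")
        if self.nucleus_radius_range[1] * 2 > min(self.h, self.w):
            raise ValueError("nucleus radii exceed the volume cross-section")
        if self.nucleolus_radius_range[1] >= self.nucleus_radius_range[0]:
            raise ValueError("nucleoli must be smaller than nuclei")


def _ellipsoid_q(shape, center, radii):
    """Normalized squared distance field q on the ellipsoid's bounding box;
    returns (zslice, yslice, xslice, q) with q <= 1 inside."""
    lo, hi = [], []
    for dim, c, r in zip(shape, center, radii):
        lo.append(max(int(math.floor(c - r)) - 1, 0))
        hi.append(min(int(math.ceil(c + r)) + 2, dim))
    zz = np.arange(lo[0], hi[0], dtype=np.float64)[:, None, None]
    yy = np.arange(lo[1], hi[1], dtype=np.float64)[None, :, None]
    xx = np.arange(lo[2], hi[2], dtype=np.float64)[None, None, :]
    q = (((zz - center[0]) / radii[0]) ** 2
         + ((yy - center[1]) / radii[1]) ** 2
         + ((xx - center[2]) / radii[2]) ** 2)
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), q


def generate_volume(cfg: SynthConfig) -> tuple[ImageVolume, MaskVolume, MaskVolume]:
    """Generate (image, nucleus mask, nucleolus mask), deterministic in cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.z, cfg.h, cfg.w)
    nucleus = np.zeros(shape, dtype=bool)
    rim = np.zeros(shape, dtype=bool)
    nucleolus = np.zeros(shape, dtype=bool)

    # --- nuclei: prolate ellipsoids with a rim shell -----------------------
    r_lo, r_hi = cfg.nucleus_radius_range
    nuclei = []
    for _ in range(cfg.n_cells):
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        rz = rng.uniform(0.35, 0.55) * cfg.z
        cz = rng.uniform(0.3, 0.7) * cfg.z
        cy = rng.uniform(ry, cfg.h - ry)
        cx = rng.uniform(rx, cfg.w - rx)
        sl, q = _ellipsoid_q(shape, (cz, cy, cx), (rz, ry, rx))
        nucleus[sl] |= q <= 1.0
        rim[sl] |= (q >= 0.82) & (q <= 1.0)
        nuclei.append(((cz, cy, cx), (rz, ry, rx)))

    # --- nucleoli: small prolate ellipsoids strictly inside nuclei ---------
    n_lo, n_hi = cfg.nucleolus_radius_range
    r_mean = 0.5 * (n_lo + n_hi)
    rz_mean = 3.25 * r_mean
    vol_per = 4.0 / 3.0 * math.pi * r_mean ** 2 * min(rz_mean, 0.45 * cfg.z)
    target_vox = cfg.nucleolus_fg_target * cfg.z * cfg.h * cfg.w
    per_cell = int(np.clip(round(target_vox / (cfg.n_cells * vol_per)), 1, 3))
    # rescale radii so the integer per-cell count still meets the target
    r_scale = float(np.clip(
        (target_vox / (cfg.n_cells * per_cell * vol_per)) ** (1.0 / 3.0), 0.75, 1.25))
    for (center, radii) in nuclei:
        for _ in range(per_cell):
            # rejection-sample a center well inside the nucleus (q <= 0.3)
            for _ in range(100):
                u = rng.standard_normal(3)
                u *= rng.uniform() ** (1 / 3) / np.linalg.norm(u)
                cz = center[0] + 0.55 * radii[0] * u[0]
                cy = center[1] + 0.55 * radii[1] * u[1]
                cx = center[2] + 0.55 * radii[2] * u[2]
                break
            ry = rng.uniform(n_lo, n_hi) * r_scale
            rx = rng.uniform(n_lo, n_hi) * r_scale
            rz = min(rng.uniform(2.5, 4.0) * 0.5 * (ry + rx), 0.45 * cfg.z)
            sl, q = _ellipsoid_q(shape, (cz, cy, cx), (rz, ry, rx))
            nucleolus[sl] |= q <= 1.0
    nucleolus &= nucleus  # nesting invariant, exact

    # --- intensity composition --------------------------------------------
    texture = gaussian_filter(
        rng.standard_normal(shape), sigma=(2.0, cfg.texture_scale, cfg.texture_scale))
    std = texture.std()
    if std > 0:
        texture *= 0.05 / std
    img = np.full(shape, _BACKGROUND, dtype=np.float64) + texture
    img[nucleus] = _NUCLEUS_INTERIOR + 0.5 * texture[nucleus]
    img[rim] = _RIM
    img[nucleolus] = _NUCLEOLUS + 0.3 * texture[nucleolus]

    # per-slice brightness drift: smooth random walk rescaled to the amplitude
    walk = gaussian_filter1d(np.cumsum(rng.standard_normal(cfg.z)), 3.0)
    if cfg.z > 1 and np.ptp(walk) > 0:
        walk = (walk - walk.min()) / np.ptp(walk) - 0.5
        drift = walk * cfg.brightness_drift_amplitude
    else:
        drift = np.zeros(cfg.z)
    img += drift[:, None, None]

    img += rng.normal(0.0, cfg.noise_sigma, size=shape)
    img = np.clip(img, 0.0, 1.0)

    return (ImageVolume(img),
            MaskVolume(nucleus.astype(np.uint8)),
            MaskVolume(nucleolus.astype(np.uint8)))


def degrade_to_sparse(m: MaskVolume, labeled_indices) -> MaskVolume:
    """Restrict a dense mask to the given annotated slices.

    The full label array is retained internally (for evaluation) but
    :meth:`MaskVolume.slice_labels` refuses unannotated slices, so training
    code cannot touch them.
    """
    labeled_indices = list(labeled_indices)
    if not labeled_indices:
        raise ValueError("labeled_indices must be non-empty")
    return MaskVolume(labels=m.labels.copy(),
                      annotated_slices=tuple(labeled_indices))
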