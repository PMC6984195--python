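"""Pipeline head: intensity window/level rescaling to [0, 255] and Gaussian smoothing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Volume3D

__all__ = ["WindowLevel", "window_level_rescale", "gaussian_smooth", "preprocess_pair"]

#: Kernel support in units of sigma; renormalized discrete kernel.
GAUSS_TRUNCATE = 3.0

#: Per-axis smoothing scale in mm equals one voxel spacing (sigma, not variance).
SIGMA_PER_SPACING = 1.0


@dataclass(frozen=True)
class WindowLevel:
    """Intensity window [wmin, wmax] that maps affinely onto [0, 255]."""

    wmin: float
    wmax: float

    def __post_init__(self) -> None:
        if not self.wmax > self.wmin:
            raise ValueError(f"degenerate window: wmax={self.wmax} <= wmin={self.wmin}")


def window_level_rescale(vol: Volume3D, wl: WindowLevel) -> Volume3D:
    """Clamp to [wmin, wmax] and rescale so wmin -> 0 and wmax -> 255."""
    if not wl.wmax > wl.wmin:  # guards windows deserialized without validation
        raise ValueError(f"degenerate window: [{wl.wmin}, {wl.wmax}]")
    clipped = np.clip(vol.data.astype(np.float64), wl.wmin, wl.wmax)
    out = (clipped - wl.wmin) * (255.0 / (wl.wmax - wl.wmin))
    return vol.copy_with(np.clip(out, 0.0, 255.0))  # guard fp overshoot at the top end


def gaussian_smooth(vol: Volume3D, enabled: bool = True) -> Volume3D:
    """Separable Gaussian smoothing, sigma per axis = one voxel spacing (in mm).

    In voxel units every axis therefore has sigma = SIGMA_PER_SPACING voxels.
    Boundaries are edge-replicated so the field-of-view border is not darkened.
    """
    if not enabled:
        return vol.copy_with(vol.data.astype(np.float64))
    sigma_vox = SIGMA_PER_SPACING * vol.spacing / vol.spacing  # = 1 voxel per axis
    out = gaussian_filter(
        vol.data.astype(np.float64), sigma=sigma_vox, mode="nearest", truncate=GAUSS_TRUNCATE
    )
    return vol.copy_with(out)


def preprocess_pair(
    ref: Volume3D,
    flt: Volume3D,
    ref_wl: WindowLevel,
    flt_wl: WindowLevel,
    smooth: bool = True,
) -> tuple[Volume3D, Volume3D]:
    """Window/level rescale then smooth both images (each with its own window)."""
    ref_p = gaussian_smooth(window_level_rescale(ref, ref_wl), enabled=smooth)
    flt_p = gaussian_smooth(window_level_rescale(flt, flt_wl), enabled=smooth)
    return ref_p, flt_p
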