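"""Similarity measures: joint-histogram mutual information and 3D SSIM.

MI (in bits) drives the optimizer at every subdivision level; SSIM is an
evaluation-only metric combining luminance, contrast, and structure terms over
a Gaussian-weighted sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Volume3D

__all__ = [
    "JointHistogram",
    "SSIMParams",
    "build_joint_histogram",
    "mutual_information",
    "mi_from_samples",
    "ssim3d",
]

#: Default bin counts (not stated by the method's description; configurable).
N_BINS_GLOBAL = 64
N_BINS_SUBVOLUME = 32
#: Regions smaller than this many voxels use the reduced bin count.
SMALL_REGION_VOXELS = 4096


@dataclass
class JointHistogram:
    """Co-occurrence counts of paired intensity samples, plus bin bookkeeping."""

    counts: np.ndarray
    n_bins_ref: int
    n_bins_flt: int

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def marginal_ref(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_flt(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    # b = floor(v * n_bins / 256), with v = 255 clamped into the top bin
    b = np.floor(values * (n_bins / 256.0)).astype(np.intp)
    return np.clip(b, 0, n_bins - 1)


def build_joint_histogram(
    ref_samples: np.ndarray, flt_samples: np.ndarray, n_bins: int = N_BINS_GLOBAL
) -> JointHistogram:
    """Bin paired [0, 255] intensity samples into an n_bins x n_bins joint histogram."""
    ref_samples = np.asarray(ref_samples, dtype=float).ravel()
    flt_samples = np.asarray(flt_samples, dtype=float).ravel()
    if ref_samples.size != flt_samples.size:
        raise ValueError(
            f"sample lists differ in length: {ref_samples.size} vs {flt_samples.size}"
        )
    if ref_samples.size == 0:
        raise ValueError("empty sample lists: mutual information undefined")
    bi = _bin_indices(ref_samples, n_bins)
    bj = _bin_indices(flt_samples, n_bins)
    counts = np.bincount(bi * n_bins + bj, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    return JointHistogram(counts=counts.astype(np.float64), n_bins_ref=n_bins, n_bins_flt=n_bins)


def mutual_information(h: JointHistogram) -> float:
    """MI in bits: sum over nonzero cells of p_ij * log2(p_ij / (p_i * p_j))."""
    total = h.total
    if total <= 0:
        raise ValueError("joint histogram is empty")
    p = h.counts / total
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    outer = pi[:, None] * pj[None, :]
    mi = float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))
    return max(mi, 0.0)  # clip -0.0 / rounding noise


def mi_from_samples(ref_samples: np.ndarray, flt_samples: np.ndarray, n_bins: int) -> float:
    return mutual_information(build_joint_histogram(ref_samples, flt_samples, n_bins))


# ---------------------------------------------------------------------------
# 3D SSIM


@dataclass(frozen=True)
class SSIMParams:
    """Constants of the luminance/contrast/structure decomposition.

    Defaults assume a [0, 255] dynamic range (post window/level): C1 = (0.01 L)^2,
    C2 = (0.03 L)^2, C3 = C2 / 2, Gaussian window sigma 1.5 voxels, radius 5.
    """

    dynamic_range: float = 255.0
    c1: float = field(default=(0.01 * 255.0) ** 2)
    c2: float = field(default=(0.03 * 255.0) ** 2)
    c3: float = field(default=(0.03 * 255.0) ** 2 / 2.0)
    window_radius: int = 5
    window_sigma: float = 1.5

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.c3) <= 0:
            raise ValueError("SSIM stabilizers C1, C2, C3 must be positive")


def _local_mean(x: np.ndarray, params: SSIMParams) -> np.ndarray:
    truncate = params.window_radius / params.window_sigma
    return gaussian_filter(x, sigma=params.window_sigma, mode="reflect", truncate=truncate)


def ssim3d(
    a: Volume3D,
    b: Volume3D,
    mask: np.ndarray | None = None,
    params: SSIMParams | None = None,
    return_map: bool = False,
):
    """Mean SSIM of two volumes on a shared grid, averaged over ``mask``.

    Per-voxel index = luminance * contrast * structure with stabilizers C1/C2/C3;
    local statistics use a Gaussian-weighted window. Returns a value in [-1, 1].
    """
    params = params or SSIMParams()
    if a.dims != b.dims:
        raise ValueError(f"grid mismatch: {a.dims} vs {b.dims}")
    if mask is None:
        mask = np.ones(a.dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.dims:
        raise ValueError(f"mask shape {mask.shape} does not match volume {a.dims}")
    if not mask.any():
        raise ValueError("empty SSIM mask")

    x = a.data.astype(np.float64)
    y = b.data.astype(np.float64)
    mu_x = _local_mean(x, params)
    mu_y = _local_mean(y, params)
    var_x = np.maximum(_local_mean(x * x, params) - mu_x * mu_x, 0.0)
    var_y = np.maximum(_local_mean(y * y, params) - mu_y * mu_y, 0.0)
    cov = _local_mean(x * y, params) - mu_x * mu_y
    sd_x = np.sqrt(var_x)
    sd_y = np.sqrt(var_y)

    luminance = (2 * mu_x * mu_y + params.c1) / (mu_x**2 + mu_y**2 + params.c1)
    contrast = (2 * sd_x * sd_y + params.c2) / (var_x + var_y + params.c2)
    structure = (cov + params.c3) / (sd_x * sd_y + params.c3)
    ssim_map = luminance * contrast * structure
    mean = float(ssim_map[mask].mean())
    if return_map:
        return mean, ssim_map
    return mean
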