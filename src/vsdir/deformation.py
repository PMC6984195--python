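"""Dense deformation fields from grids of rigid transforms.

The finest-level transforms are blended per voxel by separable Catmull-Rom
cubic weights: unit quaternions are sign-aligned, weight-averaged, and
renormalized; the affine offsets are blended with the same weights. The result
is a smooth displacement field u(x) in mm on the reference grid, plus warping
and Jacobian utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .subdivision import LeafTransformGrid
from .volume_io import PointMM, Volume3D

__all__ = [
    "DeformationField",
    "interpolate_field",
    "warp",
    "jacobian_min",
    "transform_point",
]


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm) on the reference grid.

    Maps a reference physical point p to the floating-image point p + u(p).
    """

    displacement: np.ndarray  # dims + (3,)
    grid: Volume3D

    def __post_init__(self) -> None:
        if self.displacement.shape != self.grid.dims + (3,):
            raise ValueError(
                f"displacement shape {self.displacement.shape} does not match grid {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("deformation field contains non-finite displacements")

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=-1).max())


def catmull_rom_weights(t: np.ndarray) -> np.ndarray:
    """Weights for control points at offsets (-1, 0, 1, 2); rows sum to 1."""
    t = np.asarray(t, dtype=float)
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            0.5 * (-t3 + 2 * t2 - t),
            0.5 * (3 * t3 - 5 * t2 + 2),
            0.5 * (-3 * t3 + 4 * t2 + t),
            0.5 * (t3 - t2),
        ],
        axis=-1,
    )


def _control_arrays(leaf_grid: LeafTransformGrid) -> tuple[np.ndarray, np.ndarray]:
    """Quaternions (sign-aligned) and affine offsets b with T(x) = R x + b."""
    shape = leaf_grid.shape
    quats = np.zeros(shape + (4,))
    offsets = np.zeros(shape + (3,))
    it = np.ndindex(shape)
    q_ref = None
    for index in it:
        T = leaf_grid.transforms[index]
        if T is None:
            raise ValueError(f"leaf transform grid incomplete at {index}")
        R, b = T.as_affine()
        q = T.quaternion
        if q_ref is None:
            # canonical hemisphere; valid while rotations stay well under 180 deg apart
            q_ref = -q if q[0] < 0 else q
        if np.dot(q, q_ref) < 0:
            q = -q
        quats[index] = q
        offsets[index] = b
    return quats, offsets


def interpolate_field(leaf_grid: LeafTransformGrid, ref_geometry: Volume3D) -> DeformationField:
    """Blend the regular grid of rigid transforms into a dense displacement field.

    For each reference voxel the 4x4x4 neighborhood of control transforms around
    its position (in control-cell coordinates, border replicated) is combined
    with separable Catmull-Rom weights. Quaternions are renormalized after
    blending; u(x) = R_blend x + b_blend - x.
    """
    quats, offsets = _control_arrays(leaf_grid)
    shape = leaf_grid.shape
    dims = ref_geometry.dims

    # Control-point physical positions form a regular lattice; recover per-axis
    # coordinates from the centers array.
    axis_coords = [
        leaf_grid.centers[(slice(None),) + (0,) * 2 + (ax,)] if ax == 0
        else leaf_grid.centers[(0,) * ax + (slice(None),) + (0,) * (2 - ax) + (ax,)]
        for ax in range(3)
    ]

    vox = [np.arange(dims[ax]) * ref_geometry.spacing[ax] + ref_geometry.origin[ax] for ax in range(3)]

    base_idx = []
    weights = []
    for ax in range(3):
        coords = axis_coords[ax]
        if shape[ax] == 1:
            s = np.zeros(dims[ax])
        else:
            step = coords[1] - coords[0]
            s = (vox[ax] - coords[0]) / step
        i0 = np.floor(s).astype(int)
        t = s - i0
        base_idx.append(i0)
        weights.append(catmull_rom_weights(t))  # (dims[ax], 4)

    X = np.stack(
        np.meshgrid(vox[0], vox[1], vox[2], indexing="ij"), axis=-1
    )  # dims + (3,)

    q_acc = np.zeros(dims + (4,))
    b_acc = np.zeros(dims + (3,))
    for di in range(4):
        ix = np.clip(base_idx[0] + di - 1, 0, shape[0] - 1)
        wx = weights[0][:, di]
        for dj in range(4):
            iy = np.clip(base_idx[1] + dj - 1, 0, shape[1] - 1)
            wy = weights[1][:, dj]
            wxy = wx[:, None] * wy[None, :]
            for dk in range(4):
                iz = np.clip(base_idx[2] + dk - 1, 0, shape[2] - 1)
                wz = weights[2][:, dk]
                w = wxy[:, :, None] * wz[None, None, :]
                gi = ix[:, None, None]
                gj = iy[None, :, None]
                gk = iz[None, None, :]
                q_acc += w[..., None] * quats[gi, gj, gk]
                b_acc += w[..., None] * offsets[gi, gj, gk]

    norm = np.linalg.norm(q_acc, axis=-1, keepdims=True)
    q_unit = q_acc / np.where(norm > 0, norm, 1.0)

    # Rotate X by the blended quaternions: scipy expects (x, y, z, w) order.
    flat_q = q_unit.reshape(-1, 4)[:, [1, 2, 3, 0]]
    flat_x = X.reshape(-1, 3)
    rotated = Rotation.from_quat(flat_q).apply(flat_x)
    u = rotated.reshape(dims + (3,)) + b_acc - X
    return DeformationField(displacement=u, grid=ref_geometry)


def warp(flt: Volume3D, field: DeformationField, fill: float = 0.0) -> Volume3D:
    """Backward-warp the floating image onto the reference grid.

    Output intensity at reference voxel x is the trilinear sample of ``flt`` at
    the physical point x + u(x); samples outside the floating volume get ``fill``.
    """
    g = field.grid
    idx = np.indices(g.dims, dtype=float)
    phys = g.origin[:, None, None, None] + idx * g.spacing[:, None, None, None]
    mapped = phys + np.moveaxis(field.displacement, -1, 0)
    vox = (mapped - flt.origin[:, None, None, None]) / flt.spacing[:, None, None, None]
    out = map_coordinates(
        flt.data.astype(np.float64), vox, order=1, mode="constant", cval=fill, prefilter=False
    )
    return Volume3D(data=out, spacing=g.spacing.copy(), origin=g.origin.copy())


def jacobian_min(field: DeformationField) -> float:
    """Minimum over interior voxels of det(I + grad u); > 0 means no folding."""
    u = field.displacement
    sp = field.grid.spacing
    J = np.empty(field.grid.dims + (3, 3))
    for comp in range(3):
        for ax in range(3):
            J[..., comp, ax] = np.gradient(u[..., comp], sp[ax], axis=ax)
    J += np.eye(3)
    interior = (slice(1, -1),) * 3
    det = np.linalg.det(J[interior])
    return float(det.min())


def transform_point(field: DeformationField, p: PointMM) -> PointMM:
    """p + u(p) with trilinear interpolation of the stored displacements."""
    p = np.asarray(p, dtype=float)
    g = field.grid
    vox = (p - g.origin) / g.spacing
    if np.any(vox < 0) or np.any(vox > np.array(g.dims) - 1):
        raise ValueError(f"point {p} mm lies outside the field extent")
    u = np.array(
        [
            map_coordinates(
                field.displacement[..., c], vox[:, None], order=1, mode="nearest", prefilter=False
            )[0]
            for c in range(3)
        ]
    )
    return p + u
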