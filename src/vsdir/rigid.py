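"""Rigid transforms, their algebra, downhill simplex, and MI-driven rigid registration.

The same machinery serves the one global rigid stage and every per-subvolume
refinement: 6 degrees of freedom (Euler angles + translation) optimized by a
bounded Nelder-Mead simplex on negative mutual information, with quaternion
storage for downstream interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from . import similarity
from .volume_io import PointMM, Volume3D

__all__ = [
    "RigidTransform",
    "SimplexSettings",
    "RegistrationResult",
    "identity_transform",
    "apply_transform",
    "compose",
    "invert",
    "downhill_simplex",
    "rigid_register",
]

#: Minimum fraction of region samples that must land inside the floating volume
#: at the initial transform for refinement to proceed.
MIN_VALID_FRACTION = 0.25

_EULER_ORDER = "xyz"


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (unit quaternion, w-first) about ``center`` plus translation, all in mm.

    apply(p) = center + R (p - center) + translation
    """

    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        c = np.asarray(self.center, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components (w, x, y, z)")
        norm = np.linalg.norm(q)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("quaternion must be nonzero and finite")
        object.__setattr__(self, "quaternion", q / norm)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "center", c)

    @property
    def matrix(self) -> np.ndarray:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (R, b) with apply(p) = R p + b."""
        R = self.matrix
        b = self.center + self.translation - R @ self.center
        return R, b


def identity_transform(center: Sequence[float] | None = None) -> RigidTransform:
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    return RigidTransform(center=c)


def quaternion_from_matrix(R: np.ndarray) -> np.ndarray:
    x, y, z, w = Rotation.from_matrix(R).as_quat()
    q = np.array([w, x, y, z])
    return q if q[0] >= 0 else -q


def apply_transform(T: RigidTransform, p: PointMM | np.ndarray) -> np.ndarray:
    """Map point(s) of shape (3,) or (N, 3) through the rigid transform."""
    p = np.asarray(p, dtype=float)
    R, b = T.as_affine()
    return p @ R.T + b


def compose(T2: RigidTransform, T1: RigidTransform) -> RigidTransform:
    """Transform equal to applying T1 first, then T2."""
    R2, b2 = T2.as_affine()
    R1, b1 = T1.as_affine()
    R = R2 @ R1
    b = R2 @ b1 + b2
    return RigidTransform(quaternion=quaternion_from_matrix(R), translation=b, center=np.zeros(3))


def invert(T: RigidTransform) -> RigidTransform:
    R, b = T.as_affine()
    Rinv = R.T
    return RigidTransform(
        quaternion=quaternion_from_matrix(Rinv), translation=-Rinv @ b, center=np.zeros(3)
    )


def rebase_center(T: RigidTransform, center: Sequence[float]) -> RigidTransform:
    """Same mapping expressed with rotation about a different center."""
    center = np.asarray(center, dtype=float)
    R, b = T.as_affine()
    t = R @ center + b - center
    return RigidTransform(quaternion=quaternion_from_matrix(R), translation=t, center=center)


# ---------------------------------------------------------------------------
# Downhill simplex (Nelder-Mead) with projection into parameter bounds.


@dataclass
class SimplexSettings:
    initial_step: np.ndarray | float = 1.0
    tolerance: float = 1e-4
    max_iterations: int = 150
    lower_bounds: np.ndarray | None = None
    upper_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _make_projector(
    settings: SimplexSettings, extra: Callable[[np.ndarray], np.ndarray] | None
) -> Callable[[np.ndarray], np.ndarray]:
    lo, hi = settings.lower_bounds, settings.upper_bounds

    def project(x: np.ndarray) -> np.ndarray:
        if lo is not None or hi is not None:
            x = np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
        if extra is not None:
            x = extra(x)
        return x

    return project


def downhill_simplex(
    cost: Callable[[np.ndarray], float],
    x0: Sequence[float],
    settings: SimplexSettings,
    project: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Nelder-Mead minimization; every candidate is projected into bounds before
    evaluation. Returns the best point ever evaluated (never worse than x0).

    Standard coefficients: reflection 1, expansion 2, contraction 0.5, shrink 0.5.
    Terminates when the relative cost spread across the simplex falls below the
    tolerance or the iteration cap is reached.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    proj = _make_projector(settings, project)

    step = np.asarray(settings.initial_step, dtype=float)
    if step.ndim == 0:
        step = np.full(n, float(step))

    pts = [proj(x0.copy())]
    for i in range(n):
        x = x0.copy()
        x[i] += step[i] if step[i] != 0 else 1.0
        pts.append(proj(x))
    fvals = np.array([cost(p) for p in pts])
    if not np.isfinite(fvals[0]):
        raise ValueError("cost is non-finite at the initial point")
    pts = np.array(pts)

    best_x = pts[np.argmin(fvals)].copy()
    best_f = float(np.min(fvals))

    def track(x: np.ndarray, f: float) -> None:
        nonlocal best_x, best_f
        if f < best_f:
            best_f, best_x = float(f), x.copy()

    for _ in range(settings.max_iterations):
        order = np.argsort(fvals, kind="stable")
        pts, fvals = pts[order], fvals[order]
        spread = abs(fvals[-1] - fvals[0])
        scale = max(abs(fvals[-1]), abs(fvals[0]), 1e-30)
        if spread <= settings.tolerance * scale:
            break
        centroid = pts[:-1].mean(axis=0)

        xr = proj(centroid + 1.0 * (centroid - pts[-1]))
        fr = cost(xr)
        track(xr, fr)
        if fr < fvals[0]:
            xe = proj(centroid + 2.0 * (centroid - pts[-1]))
            fe = cost(xe)
            track(xe, fe)
            pts[-1], fvals[-1] = (xe, fe) if fe < fr else (xr, fr)
        elif fr < fvals[-2]:
            pts[-1], fvals[-1] = xr, fr
        else:
            xc = proj(centroid + 0.5 * (pts[-1] - centroid))
            fc = cost(xc)
            track(xc, fc)
            if fc < fvals[-1]:
                pts[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                for i in range(1, len(pts)):
                    pts[i] = proj(pts[0] + 0.5 * (pts[i] - pts[0]))
                    fvals[i] = cost(pts[i])
                    track(pts[i], fvals[i])
    return best_x, best_f


# ---------------------------------------------------------------------------
# MI-driven rigid registration of a region.


@dataclass
class RegistrationResult:
    transform: RigidTransform
    refined: bool
    mi_initial: float
    mi_final: float
    note: str = ""


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> RigidTransform:
    t = params[:3]
    rot = Rotation.from_euler(_EULER_ORDER, params[3:6], degrees=True)
    x, y, z, w = rot.as_quat()
    return RigidTransform(quaternion=np.array([w, x, y, z]), translation=t, center=center)


def _transform_to_params(T: RigidTransform, center: np.ndarray) -> np.ndarray:
    Tc = rebase_center(T, center)
    w, x, y, z = Tc.quaternion
    angles = Rotation.from_quat([x, y, z, w]).as_euler(_EULER_ORDER, degrees=True)
    return np.concatenate([Tc.translation, angles])


def region_center(vol: Volume3D, region: tuple[slice, slice, slice]) -> np.ndarray:
    lo = np.array([s.start for s in region], dtype=float)
    hi = np.array([s.stop for s in region], dtype=float)
    return vol.origin + (lo + hi - 1.0) / 2.0 * vol.spacing


def _region_samples(
    ref: Volume3D, region: tuple[slice, slice, slice], stride: int
) -> tuple[np.ndarray, np.ndarray]:
    sl = tuple(slice(s.start, s.stop, stride) for s in region)
    grids = np.meshgrid(
        *[np.arange(s.start, s.stop, stride) for s in region], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    phys = ref.origin + idx * ref.spacing
    intens = ref.data[sl].astype(np.float64).ravel()
    return phys, intens


def _sample_floating(flt: Volume3D, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vox = (points - flt.origin) / flt.spacing
    valid = np.all((vox >= 0) & (vox <= np.array(flt.dims) - 1), axis=1)
    vals = map_coordinates(
        flt.data.astype(np.float64), vox.T, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return vals, valid


def rigid_register(
    ref: Volume3D,
    flt: Volume3D,
    region: tuple[slice, slice, slice],
    init: RigidTransform,
    max_disp: float,
    settings: SimplexSettings | None = None,
    n_bins: int | None = None,
    stride: int = 1,
    max_rotation_deg: float = 20.0,
) -> RegistrationResult:
    """Refine a rigid transform over ``region`` by maximizing MI of reference
    intensities against trilinearly interpolated floating intensities.

    The displacement of the region center relative to ``init`` is capped at
    ``max_disp`` mm (enforced by projection at every simplex evaluation). When
    fewer than MIN_VALID_FRACTION of the region's samples map inside the
    floating volume at ``init``, the initial transform is returned unrefined.
    """
    settings = settings or SimplexSettings()
    n_vox = int(np.prod([s.stop - s.start for s in region]))
    if n_vox <= 0:
        raise ValueError("empty region")
    if n_bins is None:
        n_bins = (
            similarity.N_BINS_SUBVOLUME
            if n_vox < similarity.SMALL_REGION_VOXELS
            else similarity.N_BINS_GLOBAL
        )

    center = region_center(ref, region)
    ref_pts, ref_vals = _region_samples(ref, region, stride)

    def mi_at(params: np.ndarray) -> tuple[float, float]:
        T = _params_to_transform(params, center)
        mapped = apply_transform(T, ref_pts)
        flt_vals, valid = _sample_floating(flt, mapped)
        frac = valid.mean() if valid.size else 0.0
        if valid.sum() < 8:
            return -np.inf, frac
        return similarity.mi_from_samples(ref_vals[valid], flt_vals[valid], n_bins), frac

    p0 = _transform_to_params(init, center)
    mi0, frac0 = mi_at(p0)
    if frac0 < MIN_VALID_FRACTION or not np.isfinite(mi0):
        return RegistrationResult(
            transform=init,
            refined=False,
            mi_initial=mi0 if np.isfinite(mi0) else 0.0,
            mi_final=mi0 if np.isfinite(mi0) else 0.0,
            note=f"insufficient overlap ({frac0:.0%} valid); kept initial transform",
        )

    t0 = p0[:3]
    lo = np.concatenate([t0 - max_disp, p0[3:6] - max_rotation_deg])
    hi = np.concatenate([t0 + max_disp, p0[3:6] + max_rotation_deg])
    settings = replace(settings, lower_bounds=lo, upper_bounds=hi)

    def radial_cap(x: np.ndarray) -> np.ndarray:
        d = x[:3] - t0
        norm = np.linalg.norm(d)
        if norm > max_disp:
            x = x.copy()
            x[:3] = t0 + d * (max_disp / norm)
        return x

    def cost(params: np.ndarray) -> float:
        mi, _ = mi_at(params)
        return -mi if np.isfinite(mi) else 1e6

    best, best_cost = downhill_simplex(cost, p0, settings, project=radial_cap)
    if -best_cost < mi0:  # never return worse than the initial transform
        return RegistrationResult(init, refined=True, mi_initial=mi0, mi_final=mi0)
    T = _params_to_transform(best, center)
    return RegistrationResult(T, refined=True, mi_initial=mi0, mi_final=-best_cost)
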