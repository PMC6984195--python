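"""Synthetic CT-like / CBCT-like pairs with known ground-truth deformation.

The generator stands in for clinical data: a CT phantom with air/soft-tissue/
bone contrast, a CBCT simulator that applies a monotone nonlinear intensity
remap (so intensity-difference costs fail but MI succeeds), z-dependent
shading and noise, and smooth ground-truth deformation fields that never fold.
Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .deformation import DeformationField, jacobian_min, transform_point, warp
from .volume_io import Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "make_ct_phantom",
    "simulate_cbct",
    "make_ground_truth_field",
    "make_pair",
    "landmark_errors",
]

AIR_HU = -1000.0
SOFT_TISSUE_HU = 0.0
BONE_HU = 700.0
BLOB_HU = 60.0

#: Ground-truth fields are rescaled until their Jacobian clears this floor.
MIN_TRUTH_JACOBIAN = 0.2


@dataclass(frozen=True)
class PhantomSpec:
    dims: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    seed: int = 0
    n_structures: int = 8
    deform_amplitude: float = 6.0
    rigid_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rigid_rotation_deg: float = 0.0
    noise_sigma_frac: float = 0.03
    shading_frac: float = 0.08

    def grid(self) -> Volume3D:
        return Volume3D(
            data=np.zeros(self.dims, dtype=np.uint8),
            spacing=np.array(self.spacing, dtype=float),
            origin=np.zeros(3),
        )


@dataclass
class PhantomPair:
    reference: Volume3D  # CBCT-like, the registration reference
    floating: Volume3D  # CT-like, the registration floating image
    truth: DeformationField  # maps reference points to floating points
    landmarks: list[tuple[np.ndarray, np.ndarray]]  # (p_ref, p_flt) mm pairs
    spec: PhantomSpec


def _physical_axes(spec: PhantomSpec) -> list[np.ndarray]:
    return [np.arange(spec.dims[i]) * spec.spacing[i] for i in range(3)]


def make_ct_phantom(spec: PhantomSpec) -> tuple[Volume3D, list[np.ndarray]]:
    """CT-like volume: air background, body ellipsoid, bone/soft inclusions.

    Landmarks (mm) sit at inclusion centroids; the layout is seeded. Texture is
    added inside the body so local MI is informative everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    dims = np.array(spec.dims)
    axes = _physical_axes(spec)
    X = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    extent = (dims - 1) * np.array(spec.spacing)
    center = extent / 2.0
    semi = extent * np.array([0.42, 0.40, 0.55])

    body = np.sum(((X - center) / semi) ** 2, axis=-1) <= 1.0
    data = np.full(spec.dims, AIR_HU)
    texture = gaussian_filter(rng.standard_normal(spec.dims), sigma=2.0)
    texture *= 40.0 / max(texture.std(), 1e-9)
    data[body] = SOFT_TISSUE_HU + texture[body]

    landmarks: list[np.ndarray] = []
    for i in range(spec.n_structures):
        c = center + (rng.uniform(-0.55, 0.55, size=3)) * semi * 0.8
        radius = rng.uniform(4.0, 9.0, size=3) + np.array([0, 0, 2.0])
        inside = np.sum(((X - c) / radius) ** 2, axis=-1) <= 1.0
        value = BONE_HU if i % 2 == 0 else BLOB_HU
        data[inside & body] = value
        landmarks.append(c.copy())
    vol = Volume3D(data=data, spacing=np.array(spec.spacing, float), origin=np.zeros(3))
    return vol, landmarks


def simulate_cbct(
    ct: Volume3D,
    seed: int,
    noise_sigma_frac: float = 0.03,
    shading_frac: float = 0.08,
) -> Volume3D:
    """CBCT-like image: monotone nonlinear remap + linear z shading + noise.

    The remap keeps tissue rank order but destroys any affine intensity
    relationship with the CT, mimicking CBCT's inconsistent tissue values; the
    shading grows linearly with distance from the central slice.
    """
    rng = np.random.default_rng(seed)
    lo, hi = -1000.0, 1000.0
    x = np.clip((ct.data.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)
    out = 1000.0 * x**0.6  # monotone, strongly non-affine
    rng_range = 1000.0
    if shading_frac > 0:
        k = np.arange(ct.dims[2], dtype=float)
        zc = (ct.dims[2] - 1) / 2.0
        ramp = np.abs(k - zc) / max(zc, 1.0)
        out = out - shading_frac * rng_range * ramp[None, None, :]
    if noise_sigma_frac > 0:
        out = out + rng.normal(0.0, noise_sigma_frac * rng_range, size=ct.dims)
    return ct.copy_with(out)


def _rigid_displacement(spec: PhantomSpec, X: np.ndarray, center: np.ndarray) -> np.ndarray:
    theta = np.deg2rad(spec.rigid_rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    d = (X - center) @ R.T + center - X
    return d + np.asarray(spec.rigid_translation, dtype=float)


def make_ground_truth_field(spec: PhantomSpec) -> DeformationField:
    """Global rigid motion plus 2-4 seeded Gaussian-bump displacements.

    The bump part is normalized so its peak magnitude equals deform_amplitude,
    then the whole field is rescaled (bumps only) until jacobian_min exceeds
    MIN_TRUTH_JACOBIAN.
    """
    rng = np.random.default_rng(spec.seed + 104729)
    grid = spec.grid()
    axes = _physical_axes(spec)
    X = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    extent = (np.array(spec.dims) - 1) * np.array(spec.spacing)
    center = extent / 2.0

    bumps = np.zeros(spec.dims + (3,))
    if spec.deform_amplitude > 0:
        n_bumps = int(rng.integers(2, 5))
        for _ in range(n_bumps):
            c = center + rng.uniform(-0.3, 0.3, size=3) * extent
            sigma = rng.uniform(15.0, 25.0)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r2 = np.sum((X - c) ** 2, axis=-1)
            bumps += np.exp(-r2 / (2 * sigma**2))[..., None] * direction
        peak = np.linalg.norm(bumps, axis=-1).max()
        # (1 - 1e-9) keeps the delivered peak at or below the request despite fp rounding
        bumps *= spec.deform_amplitude * (1.0 - 1e-9) / max(peak, 1e-12)

    rigid_part = _rigid_displacement(spec, X, center)
    u = rigid_part + bumps
    fld = DeformationField(displacement=u, grid=grid)
    scale = 1.0
    while jacobian_min(fld) <= MIN_TRUTH_JACOBIAN and scale > 1e-3:
        scale *= 0.8
        fld = DeformationField(displacement=rigid_part + bumps * scale, grid=grid)
    return fld


def _invert_point(field: DeformationField, p_flt: np.ndarray, iters: int = 25) -> np.ndarray | None:
    """Fixed-point inversion: find p_ref with p_ref + u(p_ref) = p_flt."""
    g = field.grid
    hi = g.origin + (np.array(g.dims) - 1) * g.spacing
    p = p_flt.copy()
    for _ in range(iters):
        if np.any(p < g.origin) or np.any(p > hi):
            return None
        p_new = p_flt - (transform_point(field, p) - p)
        if np.linalg.norm(p_new - p) < 1e-9:
            p = p_new
            break
        p = p_new
    if np.any(p < g.origin) or np.any(p > hi):
        return None
    return p


def make_pair(spec: PhantomSpec) -> PhantomPair:
    """Build a registration problem: floating CT, reference CBCT-like image
    (the CT warped by the ground-truth field, then degraded), and landmark
    correspondences (p_ref, p_flt) with p_flt = p_ref + u_truth(p_ref)."""
    ct, ct_landmarks = make_ct_phantom(spec)
    truth = make_ground_truth_field(spec)
    warped = warp(ct, truth, fill=AIR_HU)
    reference = simulate_cbct(
        warped, spec.seed + 7919, noise_sigma_frac=spec.noise_sigma_frac,
        shading_frac=spec.shading_frac,
    )
    pairs = []
    for p_flt in ct_landmarks:
        p_ref = _invert_point(truth, p_flt)
        if p_ref is None:
            continue
        pairs.append((p_ref, transform_point(truth, p_ref)))
    return PhantomPair(reference=reference, floating=ct, truth=truth, landmarks=pairs, spec=spec)


def landmark_errors(
    pair: PhantomPair, estimated: DeformationField | None = None
) -> np.ndarray:
    """Per-landmark error in mm; without a field this is the baseline error."""
    errs = []
    for p_ref, p_flt in pair.landmarks:
        if estimated is None:
            errs.append(np.linalg.norm(p_flt - p_ref))
        else:
            errs.append(np.linalg.norm(transform_point(estimated, p_ref) - p_flt))
    return np.array(errs)
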