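import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vsdir.phantom import PhantomSpec, make_pair
from vsdir.preprocess import WindowLevel, preprocess_pair
from vsdir.rigid import (
    RigidTransform,
    SimplexSettings,
    apply_transform,
    compose,
    downhill_simplex,
    identity_transform,
    invert,
    rigid_register,
)


def random_transform(rng, max_angle_deg=30.0, max_shift=10.0):
    rot = Rotation.from_euler("xyz", rng.uniform(-max_angle_deg, max_angle_deg, 3), degrees=True)
    x, y, z, w = rot.as_quat()
    return RigidTransform(
        quaternion=np.array([w, x, y, z]),
        translation=rng.uniform(-max_shift, max_shift, 3),
        center=rng.uniform(-20, 20, 3),
    )


class TestRigidTransform:
    def test_identity_fixes_points(self, rng):
        T = identity_transform()
        for p in rng.uniform(-100, 100, size=(10, 3)):
            np.testing.assert_allclose(apply_transform(T, p), p, atol=1e-12)

    def test_pure_translation(self):
        T = RigidTransform(translation=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(apply_transform(T, np.zeros(3)), [1, 2, 3], atol=1e-12)

    def test_90deg_rotation_about_z(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        x, y, z, w = rot.as_quat()
        T = RigidTransform(quaternion=np.array([w, x, y, z]))
        np.testing.assert_allclose(apply_transform(T, np.array([1.0, 0, 0])), [0, 1, 0], atol=1e-9)

    def test_quaternion_normalized_on_construction(self):
        T = RigidTransform(quaternion=np.array([2.0, 0, 0, 0]))
        assert abs(np.linalg.norm(T.quaternion) - 1.0) < 1e-9

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(quaternion=np.zeros(4))


class TestComposeInvert:
    def test_compose_with_identity(self, rng):
        T = random_transform(rng)
        pts = rng.uniform(-50, 50, size=(20, 3))
        np.testing.assert_allclose(
            apply_transform(compose(identity_transform(), T), pts),
            apply_transform(T, pts),
            atol=1e-9,
        )

    def test_invert_translation(self):
        T = RigidTransform(translation=np.array([4.0, -5.0, 6.0]))
        Ti = invert(T)
        np.testing.assert_allclose(Ti.translation, [-4, 5, -6], atol=1e-12)

    def test_compose_matches_sequential_application(self, rng):
        for _ in range(200):
            T1, T2 = random_transform(rng), random_transform(rng)
            p = rng.uniform(-50, 50, 3)
            np.testing.assert_allclose(
                apply_transform(compose(T2, T1), p),
                apply_transform(T2, apply_transform(T1, p)),
                atol=1e-9,
            )

    def test_compose_associative(self, rng):
        for _ in range(50):
            A, B, C = (random_transform(rng) for _ in range(3))
            p = rng.uniform(-50, 50, 3)
            np.testing.assert_allclose(
                apply_transform(compose(compose(A, B), C), p),
                apply_transform(compose(A, compose(B, C)), p),
                atol=1e-9,
            )

    def test_invert_round_trip(self, rng):
        for _ in range(50):
            T = random_transform(rng)
            p = rng.uniform(-50, 50, 3)
            np.testing.assert_allclose(
                apply_transform(compose(T, invert(T)), p), p, atol=1e-9
            )


class TestDownhillSimplex:
    def test_1d_quadratic(self):
        x, f = downhill_simplex(
            lambda v: (v[0] - 3.0) ** 2, [0.0], SimplexSettings(tolerance=1e-10, max_iterations=200)
        )
        assert abs(x[0] - 3.0) < 1e-4

    def test_bound_active_optimum(self):
        settings = SimplexSettings(
            tolerance=1e-10,
            max_iterations=300,
            lower_bounds=np.array([1.0, -5.0]),
            upper_bounds=np.array([5.0, 5.0]),
        )
        x, f = downhill_simplex(lambda v: v[0] ** 2 + v[1] ** 2, [3.0, 3.0], settings)
        assert abs(x[0] - 1.0) < 1e-6  # clamped at the lower bound
        assert abs(x[1]) < 1e-3

    def test_3d_bowl_from_multiple_starts_matches_grid_oracle(self):
        def cost(v):
            x, y, z = v
            return (x - 1) ** 2 + 2 * (y + 0.5) ** 2 + 0.5 * (z - 2) ** 2 + 0.3 * x * y

        # dense grid-search oracle
        g = np.linspace(-4, 4, 81)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        vals = cost([X, Y, Z])
        best = np.unravel_index(np.argmin(vals), vals.shape)
        oracle = np.array([g[best[0]], g[best[1]], g[best[2]]])

        settings = SimplexSettings(tolerance=1e-12, max_iterations=500)
        for start in [(0, 0, 0), (3, 3, 3), (-2, 1, 0), (2, -2, 4), (-3, -3, -3)]:
            x, _ = downhill_simplex(cost, np.array(start, float), settings)
            assert np.linalg.norm(x - oracle) < 0.1 + 1e-2

    def test_nonfinite_initial_cost_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            downhill_simplex(lambda v: np.nan, [0.0], SimplexSettings())

    def test_never_worse_than_start(self, rng):
        # noisy multimodal cost: returned best must not exceed cost at x0
        def cost(v):
            return float(np.sin(3 * v[0]) + 0.1 * v[0] ** 2 + np.cos(2 * v[1]))

        for _ in range(10):
            x0 = rng.uniform(-3, 3, 2)
            x, f = downhill_simplex(cost, x0, SimplexSettings(max_iterations=40))
            assert f <= cost(x0) + 1e-12

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SimplexSettings(tolerance=0.0)
        with pytest.raises(ValueError):
            SimplexSettings(max_iterations=0)


def _preprocessed_pair(spec):
    pair = make_pair(spec)
    ref_p, flt_p = preprocess_pair(
        pair.reference, pair.floating, WindowLevel(0, 1000), WindowLevel(-1000, 1000)
    )
    return pair, ref_p, flt_p


class TestRigidRegister:
    def test_self_registration_near_identity(self):
        spec = PhantomSpec(dims=(32, 32, 16), spacing=(2.0, 2.0, 2.0), seed=5,
                           deform_amplitude=0.0, n_structures=6)
        _, ref_p, _ = _preprocessed_pair(spec)
        whole = tuple(slice(0, d) for d in ref_p.dims)
        res = rigid_register(ref_p, ref_p, whole, identity_transform(), max_disp=20.0)
        assert res.refined
        assert np.linalg.norm(res.transform.translation) < 0.2 * 2.0  # < 0.2 voxel
        angle = 2 * np.degrees(np.arccos(np.clip(abs(res.transform.quaternion[0]), -1, 1)))
        assert angle < 0.2

    def test_recovers_known_shift(self):
        spec = PhantomSpec(dims=(48, 48, 24), spacing=(2.0, 2.0, 2.0), seed=2,
                           deform_amplitude=0.0, rigid_translation=(4.0, 0.0, 0.0),
                           n_structures=6, noise_sigma_frac=0.02)
        pair, ref_p, flt_p = _preprocessed_pair(spec)
        whole = tuple(slice(0, d) for d in ref_p.dims)
        res = rigid_register(ref_p, flt_p, whole, identity_transform(), max_disp=20.0)
        # truth: reference point x corresponds to floating point x + (4, 0, 0)
        center = np.array(ref_p.dims) / 2 * ref_p.spacing
        mapped = apply_transform(res.transform, center)
        np.testing.assert_allclose(mapped - center, [4.0, 0, 0], atol=0.5 * 2.0)

    def test_recovers_known_rotation(self):
        spec = PhantomSpec(dims=(48, 48, 24), spacing=(2.0, 2.0, 2.0), seed=4,
                           deform_amplitude=0.0, rigid_rotation_deg=5.0,
                           n_structures=6, noise_sigma_frac=0.02)
        pair, ref_p, flt_p = _preprocessed_pair(spec)
        whole = tuple(slice(0, d) for d in ref_p.dims)
        res = rigid_register(ref_p, flt_p, whole, identity_transform(), max_disp=20.0)
        w = np.clip(abs(res.transform.quaternion[0]), -1, 1)
        angle = 2 * np.degrees(np.arccos(w))
        assert abs(angle - 5.0) < 1.0

    def test_insufficient_overlap_keeps_init(self):
        spec = PhantomSpec(dims=(24, 24, 12), spacing=(2.0, 2.0, 2.0), seed=6,
                           deform_amplitude=0.0, n_structures=4)
        _, ref_p, flt_p = _preprocessed_pair(spec)
        whole = tuple(slice(0, d) for d in ref_p.dims)
        far = RigidTransform(translation=np.array([500.0, 0.0, 0.0]))
        res = rigid_register(ref_p, flt_p, whole, far, max_disp=5.0)
        assert not res.refined
        assert res.transform is far
        assert "overlap" in res.note

    def test_max_disp_respected(self, rng):
        spec = PhantomSpec(dims=(24, 24, 12), spacing=(2.0, 2.0, 2.0), seed=7,
                           deform_amplitude=0.0, rigid_translation=(6.0, 0.0, 0.0),
                           n_structures=4)
        _, ref_p, flt_p = _preprocessed_pair(spec)
        whole = tuple(slice(0, d) for d in ref_p.dims)
        for max_disp in [1.0, 2.0, 3.0]:
            res = rigid_register(ref_p, flt_p, whole, identity_transform(), max_disp=max_disp)
            c = res.transform.center  # the region center, where the cap is defined
            disp = np.linalg.norm(apply_transform(res.transform, c) - c)
            assert disp <= max_disp + 1e-6

    def test_optimizer_never_worse_than_initial_mi(self):
        spec = PhantomSpec(dims=(24, 24, 12), spacing=(2.0, 2.0, 2.0), seed=8,
                           deform_amplitude=0.0, n_structures=4)
        _, ref_p, flt_p = _preprocessed_pair(spec)
        whole = tuple(slice(0, d) for d in ref_p.dims)
        res = rigid_register(ref_p, flt_p, whole, identity_transform(), max_disp=10.0)
        assert res.mi_final >= res.mi_initial - 1e-12
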