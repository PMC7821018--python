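"""Diffusion tensor fit, fiber angle mapping and mask erosion."""

import numpy as np
import pytest

from mworient import DiffusionScheme, DiffusionTensorModel, angle_to_b0, erode_mask, fit_tensor
from mworient.phantom import fibonacci_directions


def make_scheme(n_dirs=30, bval=700.0):
    dirs = fibonacci_directions(n_dirs)
    bvecs = np.vstack([np.zeros(3), dirs])
    bvals = np.concatenate([[0.0], np.full(n_dirs, bval)])
    return DiffusionScheme(bvecs=bvecs, bvals=bvals)


def tensor_signal(scheme, evals, axis, s0=1.0):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    # complete an orthonormal frame around the principal axis
    tmp = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(axis, tmp)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)
    R = np.column_stack([axis, e2, e3])
    D = R @ np.diag(evals) @ R.T
    quad = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


class TestTensorFit:
    def test_noiseless_principal_axis_recovery(self):
        scheme = make_scheme()
        sig = tensor_signal(scheme, (1.7e-3, 0.3e-3, 0.3e-3), (1.0, 0.0, 0.0))
        model = fit_tensor(sig[None, :], scheme)
        v = model.evecs_[0][:, 0]
        assert abs(v @ np.array([1.0, 0.0, 0.0])) >= 0.999
        assert np.all(np.diff(model.evals_[0]) <= 0)  # descending
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_eigenvalues_recovered_exactly_noiseless(self):
        scheme = make_scheme()
        evals = (1.5e-3, 0.5e-3, 0.2e-3)
        sig = tensor_signal(scheme, evals, (0.3, -0.5, 0.8))
        model = fit_tensor(sig[None, :], scheme)
        assert np.allclose(model.evals_[0], sorted(evals, reverse=True), rtol=1e-8)

    def test_isotropic_voxel_has_undefined_orientation(self):
        scheme = make_scheme()
        sig = tensor_signal(scheme, (0.8e-3, 0.8e-3, 0.8e-3), (1.0, 0.0, 0.0))
        model = fit_tensor(sig[None, :], scheme)
        assert model.fa_[0] == pytest.approx(0.0, abs=1e-6)
        assert not model.valid_mask_[0]
        assert np.isnan(model.theta_deg_[0])

    def test_too_few_directions_rejected(self):
        dirs = fibonacci_directions(5)
        with pytest.raises(ValueError, match="6"):
            DiffusionScheme(
                bvecs=np.vstack([np.zeros(3), dirs]),
                bvals=np.concatenate([[0.0], np.full(5, 700.0)]),
            )

    def test_no_b0_rejected(self):
        dirs = fibonacci_directions(10)
        with pytest.raises(ValueError, match="b=0"):
            DiffusionScheme(bvecs=dirs, bvals=np.full(10, 700.0))

    def test_nonpositive_signal_flags_voxel(self):
        scheme = make_scheme()
        good = tensor_signal(scheme, (1.7e-3, 0.3e-3, 0.3e-3), (0.0, 0.0, 1.0))
        bad = good.copy()
        bad[3] = 0.0
        model = fit_tensor(np.vstack([good, bad]), scheme)
        assert model.valid_mask_[0]
        assert not model.valid_mask_[1]

    def test_fsl_table_roundtrip(self, tmp_path):
        scheme = make_scheme(12)
        scheme.to_fsl(tmp_path / "bvecs", tmp_path / "bvals")
        back = DiffusionScheme.from_fsl(tmp_path / "bvecs", tmp_path / "bvals")
        assert np.allclose(back.bvecs, scheme.bvecs, atol=1e-7)
        assert np.allclose(back.bvals, scheme.bvals)


class TestAngleToB0:
    z = np.array([0.0, 0.0, 1.0])

    def test_parallel_is_zero(self):
        assert angle_to_b0(np.array([0.0, 0.0, 1.0]), self.z) == pytest.approx(0.0)

    def test_perpendicular_is_ninety(self):
        assert angle_to_b0(np.array([1.0, 0.0, 0.0]), self.z) == pytest.approx(90.0)

    def test_oblique_and_antipodal(self):
        v = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        assert angle_to_b0(v, self.z) == pytest.approx(45.0)
        assert angle_to_b0(np.array([0.0, 0.0, -1.0]), self.z) == pytest.approx(0.0)

    def test_negation_invariance_random(self, rng):
        v = rng.normal(size=(50, 3))
        assert np.allclose(angle_to_b0(v, self.z), angle_to_b0(-v, self.z))
        assert np.all((angle_to_b0(v, self.z) >= 0) & (angle_to_b0(v, self.z) <= 90))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_to_b0(np.zeros(3), self.z)


class TestErodeMask:
    def test_solid_cube_loses_boundary(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True  # 5x5x5 cube
        eroded = erode_mask(mask)
        expected = np.zeros_like(mask)
        expected[2:5, 2:5, 2:5] = True  # 3x3x3 interior
        assert np.array_equal(eroded, expected)

    def test_empty_and_single_voxel(self):
        assert not erode_mask(np.zeros((5, 5, 5), dtype=bool)).any()
        single = np.zeros((5, 5, 5), dtype=bool)
        single[2, 2, 2] = True
        assert not erode_mask(single).any()

    def test_erosion_is_subset(self, rng):
        mask = rng.random((10, 10, 10)) > 0.3
        eroded = erode_mask(mask)
        assert np.all(mask[eroded])
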