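"""Signal model, velocity/sigma reconstruction, and corrections."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowtke as ft
from flowtke.phantom import encode_signals, wrap_phase
from flowtke.recon import (
    RHO_BLOOD,
    VelocityField,
    compute_tke,
    compute_velocity,
    correct_background,
    estimate_sigma,
    normalized_coords,
    polynomial_design_matrix,
    unwrap_velocity,
)

VENC = 120.0  # cm/s
VENC_MS = 1.2
KV = np.pi / VENC_MS


class TestEncoding:
    def test_no_turbulence_identity(self, uniform_acq):
        acq = uniform_acq(sigma=0.0, u=0.5)
        assert np.array_equal(acq.s_enc, np.broadcast_to(acq.s_ref[..., None], acq.s_enc.shape))
        assert np.allclose(acq.phase_diff, KV * 0.5)

    def test_attenuation_closed_form(self, uniform_acq):
        # sigma = VENC/pi makes kv*sigma = 1, hence S_i/S = exp(-1/2)
        acq = uniform_acq(sigma=VENC_MS / np.pi)
        ratio = acq.s_enc / acq.s_ref[..., None]
        assert np.allclose(ratio, np.exp(-0.5), atol=1e-12)

    def test_wrap_arithmetic(self, uniform_acq):
        u = 1.5 * VENC_MS
        acq = uniform_acq(u=u)
        assert np.allclose(acq.phase_diff, KV * u - 2 * np.pi)

    def test_negative_sigma_rejected(self):
        shape = (4, 4, 4, 2)
        with pytest.raises(ValueError, match="sigma"):
            encode_signals(
                np.zeros(shape + (3,)), np.full(shape + (3,), -0.1), VENC,
                np.ones(shape), voxel_size=2.8,
            )

    def test_wrap_phase_range(self):
        phi = np.linspace(-4 * np.pi, 4 * np.pi, 1001)
        w = wrap_phase(phi)
        assert (w > -np.pi).all() and (w <= np.pi).all()
        assert np.allclose(np.exp(1j * w), np.exp(1j * phi))


class TestModelProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(sigma=st.floats(0.0, 0.7), u=st.floats(-1.1, 1.1))
    def test_encode_estimate_identity(self, sigma, u):
        """estimate_sigma inverts encode_signals for any sigma*kv <= 2."""
        shape = (2, 2, 2, 1)
        acq = encode_signals(
            np.full(shape + (3,), u), np.full(shape + (3,), sigma), VENC,
            np.ones(shape), voxel_size=2.8,
        )
        tm = estimate_sigma(acq)
        assert np.abs(tm.sigma - sigma).max() <= 1e-10
        vf = compute_velocity(acq)
        assert np.abs(vf.u - u).max() <= 1e-10  # |u| < VENC: no wrap

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(phi=st.floats(-20.0, 20.0))
    def test_wrap_phase_preserves_complex_phase(self, phi):
        w = float(wrap_phase(np.array(phi)))
        assert -np.pi < w <= np.pi
        assert abs(np.exp(1j * w) - np.exp(1j * phi)) < 1e-9


class TestVelocity:
    def test_closed_form(self, uniform_acq):
        acq = uniform_acq(u=0.0)
        acq.phase_diff[:] = np.pi / 2
        vf = compute_velocity(acq)
        assert np.allclose(vf.u, 0.6)

    def test_zero_phase(self, uniform_acq):
        vf = compute_velocity(uniform_acq(u=0.0))
        assert np.all(vf.u == 0) and np.all(vf.speed == 0)

    def test_speed_norm(self):
        u = np.zeros((2, 2, 2, 2, 3))
        u[..., 0], u[..., 1] = 0.3, 0.4
        assert np.allclose(VelocityField(u=u).speed, 0.5)


class TestSigmaEstimation:
    def test_closed_form_inversion(self, uniform_acq):
        acq = uniform_acq(sigma=0.0)
        acq.s_enc[:] = np.exp(-0.5)
        tm = estimate_sigma(acq)
        assert np.allclose(tm.sigma, VENC_MS / np.pi, atol=1e-12)

    def test_no_attenuation_gives_zero(self, uniform_acq):
        tm = estimate_sigma(uniform_acq(sigma=0.0))
        assert np.all(tm.sigma == 0) and np.all(tm.tke == 0)

    def test_clamped_when_ratio_below_one(self, uniform_acq):
        acq = uniform_acq(sigma=0.0)
        acq.s_enc[:] = 1.5  # noise pushed encoded magnitude above reference
        tm = estimate_sigma(acq)
        assert np.all(tm.sigma == 0)

    def test_cap_and_unreliable_flag(self, uniform_acq):
        acq = uniform_acq(sigma=0.0)
        acq.s_enc[:] = np.exp(-3.0)  # would imply sigma*kv = sqrt(6) > 2
        tm = estimate_sigma(acq)
        assert np.allclose(tm.sigma, 2.0 / KV)
        assert tm.unreliable.all()

    def test_monotone_in_attenuation(self, uniform_acq):
        acq = uniform_acq(sigma=0.0)
        ratios = np.linspace(0.2, 1.0, acq.s_enc.size).reshape(acq.s_enc.shape)
        acq.s_enc[:] = ratios
        sig = estimate_sigma(acq).sigma
        flat_r, flat_s = ratios.ravel(), sig.ravel()
        order = np.argsort(flat_r)
        assert (np.diff(flat_s[order]) <= 1e-15).all()


class TestTKE:
    def test_isotropic_closed_form(self):
        sigma = np.full((1, 1, 1, 1, 3), VENC_MS / np.pi)
        tke = compute_tke(sigma)
        expected = 0.5 * RHO_BLOOD * 3 * (VENC_MS / np.pi) ** 2
        assert np.allclose(tke, expected)
        assert abs(expected - 232.0) < 0.1

    def test_single_component(self):
        sigma = np.zeros((1, 1, 1, 1, 3))
        sigma[..., 0] = 0.1
        assert np.allclose(compute_tke(sigma), 5.30)

    def test_quadratic_scaling_and_permutation(self):
        rng = np.random.default_rng(3)
        sigma = rng.uniform(0, 0.4, (4, 4, 4, 2, 3))
        tke = compute_tke(sigma)
        assert np.allclose(compute_tke(2 * sigma), 4 * tke)
        for perm in itertools.permutations(range(3)):
            assert np.allclose(compute_tke(sigma[..., perm]), tke)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_tke(np.full((2, 2, 2, 1, 3), -0.1))


class TestUnwrap:
    def test_idempotent_on_wrap_free(self, small_phantom):
        acq, seg, truth = small_phantom
        vf = compute_velocity(acq)
        out = unwrap_velocity(vf, acq.venc)
        assert np.array_equal(out.u, vf.u)

    def test_single_wrapped_voxel_restored(self):
        # true u = 1.5*VENC in one voxel among 1.4*VENC neighbors; the
        # stored (wrapped) value is u - 2*VENC
        u = np.full((5, 5, 5, 4, 3), 1.4 * VENC_MS)
        u[2, 2, 2, 1, 0] = 1.5 * VENC_MS - 2 * VENC_MS  # = -0.9 m/s wrapped
        out = unwrap_velocity(VelocityField(u=u.copy()), VENC)
        assert np.isclose(out.u[2, 2, 2, 1, 0], 1.5 * VENC_MS)
        # brute-force candidate check on that voxel
        cands = u[2, 2, 2, 1, 0] + 2 * VENC_MS * np.array([-1, 0, 1])
        costs = [3 * abs(c - 1.4 * VENC_MS) for c in cands]
        assert np.isclose(cands[int(np.argmin(costs))], 1.5 * VENC_MS)

    def test_wrapped_value_arithmetic(self):
        # 1.5*VENC = 1.8 m/s aliases to 1.8 - 2*1.2 = -0.6 m/s
        assert np.isclose(1.5 * VENC_MS - 2 * VENC_MS, -0.6)


class TestBackgroundCorrection:
    @staticmethod
    def _field_with_offset(coeffs, order, shape=(12, 12, 12), nt=4):
        basis = polynomial_design_matrix(normalized_coords(shape), order)
        offset = basis @ coeffs
        u = np.zeros(shape + (nt, 3))
        u += offset[..., None, None]
        return VelocityField(u=u), offset

    def test_zero_offset_identity(self):
        vf, _ = self._field_with_offset(np.zeros(10), 2)
        static = np.ones((12, 12, 12), bool)
        out = correct_background(vf, static)
        assert np.abs(out.u - vf.u).max() <= 1e-12

    def test_constant_offset_exact(self):
        vf, _ = self._field_with_offset(np.array([0.07]), 0)
        static = np.zeros((12, 12, 12), bool)
        static[2:10, 2:10, 2:10] = True
        out = correct_background(vf, static, order=0)
        assert np.abs(out.u).max() < 1e-12

    def test_linear_ramp_removed(self):
        coeffs = np.array([0.02, 0.05, -0.03, 0.04])
        vf, _ = self._field_with_offset(coeffs, 1)
        static = np.zeros((12, 12, 12), bool)
        static[1:6, 2:11, 3:9] = True
        out = correct_background(vf, static, order=1)
        rms = np.sqrt((out.u.mean(axis=3)[static] ** 2).mean())
        assert rms <= 1e-3

    def test_small_static_mask_rejected(self):
        vf, _ = self._field_with_offset(np.zeros(10), 2)
        static = np.zeros((12, 12, 12), bool)
        static[0, 0, :10] = True
        with pytest.raises(ValueError, match="static mask"):
            correct_background(vf, static)
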