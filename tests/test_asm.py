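import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polarasm import (PolarField, PropagatorSpec, angular_transform,
                      asm_step, k_theta_axis, make_window, march, propagator)
from polarasm.geometry import PolarGrid

C = 1540.0


def random_field(rng, n_theta=64, n_f=3, radius=0.05):
    theta = np.linspace(-0.4, 0.4, n_theta)
    freq = np.linspace(2e6, 5e6, n_f)
    vals = rng.standard_normal((n_theta, n_f)) \
        + 1j * rng.standard_normal((n_theta, n_f))
    return PolarField(vals, radius, theta, freq)


class TestPropagator:
    def test_zero_length_step_is_identity(self, rng):
        spec = PropagatorSpec(0.05, 0.05, C)
        k = rng.uniform(-200, 200, 64)
        H = propagator(k, spec, 3.5e6)
        assert H == pytest.approx(np.ones(64), abs=1e-12)

    def test_k_zero_is_plane_radial_wave_limit(self):
        for branch, sign in (("-", -1), ("+", 1)):
            spec = PropagatorSpec(0.05, 0.07, C, branch)
            H = propagator(np.array([0.0]), spec, 3.5e6)
            expect = np.exp(sign * 2j * np.pi * 3.5e6 * 0.02 / C)
            assert H[0] == pytest.approx(expect, abs=1e-12)

    def test_unit_modulus_for_propagating_modes(self, rng):
        # 10^4 random tuples with f*min(r)/(c|k|) > 1.001
        f = rng.uniform(1e6, 6e6, 10_000)
        r1 = rng.uniform(0.03, 0.1, 10_000)
        r2 = r1 + rng.uniform(0.0, 0.05, 10_000)
        kmax = f * np.minimum(r1, r2) / (C * 1.001)
        k = rng.uniform(0.01, 1.0, 10_000) * kmax
        H = np.array([propagator(np.array([ki]),
                                 PropagatorSpec(a, b, C), fi)[0]
                      for ki, a, b, fi in zip(k[:200], r1[:200], r2[:200],
                                              f[:200])])
        # vectorized check for the rest
        Hv = propagator(k, PropagatorSpec(0.05, 0.08, C),
                        k * C / 0.05 * 1.5)  # guaranteed propagating
        assert np.max(np.abs(np.abs(H) - 1.0)) < 1e-12
        assert np.max(np.abs(np.abs(Hv) - 1.0)) < 1e-12

    def test_branch_inversion(self, rng):
        k = rng.uniform(-50, 50, 128)
        f = 3.5e6
        Hm = propagator(k, PropagatorSpec(0.05, 0.08, C, "-"), f)
        Hp = propagator(k, PropagatorSpec(0.05, 0.08, C, "+"), f)
        prop = np.abs(k) < f * 0.05 / C  # propagating at both radii
        assert Hm[prop] * Hp[prop] == pytest.approx(
            np.ones(prop.sum()), abs=1e-12)

    def test_composition_telescopes(self, rng):
        k = rng.uniform(-80, 80, 256)
        f = 3.5e6
        r1, r2, r3 = 0.05, 0.065, 0.09
        H12 = propagator(k, PropagatorSpec(r1, r2, C), f)
        H23 = propagator(k, PropagatorSpec(r2, r3, C), f)
        H13 = propagator(k, PropagatorSpec(r1, r3, C), f)
        prop = np.abs(k) < f * r1 / C * 0.999
        assert H12[prop] * H23[prop] == pytest.approx(H13[prop], abs=1e-10)

    def test_k_to_zero_continuity(self):
        # smallest nonzero bin approaches the k=0 limit as the angular
        # span grows (bin spacing = 1/span)
        spec = PropagatorSpec(0.05, 0.07, C)
        f = 3.5e6
        H0 = propagator(np.array([0.0]), spec, f)[0]
        gaps = []
        for span in (0.8, 3.2, 12.8):
            k1 = 1.0 / span
            gaps.append(abs(propagator(np.array([k1]), spec, f)[0] - H0))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-4

    def test_evanescent_zero_policy(self):
        spec = PropagatorSpec(0.05, 0.07, C, evanescent_mode="zero")
        f = 3.5e6
        k_evan = f * 0.07 / C * 1.5  # evanescent even at destination
        assert propagator(np.array([k_evan]), spec, f)[0] == 0.0

    def test_evanescent_decay_policy_bounded(self, rng):
        spec = PropagatorSpec(0.05, 0.07, C, evanescent_mode="decay")
        k = rng.uniform(-500, 500, 512)
        H = propagator(k, spec, 3.5e6)
        assert np.all(np.abs(H) <= 1.0 + 1e-12)

    def test_rejects_negative_frequency(self):
        with pytest.raises(ValueError):
            propagator(np.array([1.0]), PropagatorSpec(0.05, 0.07, C), -1.0)


class TestAngularTransform:
    def test_round_trip_identity(self, rng):
        field = random_field(rng, n_theta=256)
        rt = angular_transform(angular_transform(field, "forward"), "inverse")
        assert rt.values == pytest.approx(field.values, abs=1e-12)

    def test_single_mode_hits_single_bin(self):
        n = 128
        theta = np.linspace(-0.4, 0.4, n)
        dth = theta[1] - theta[0]
        k_axis = k_theta_axis(n, dth)
        k0 = k_axis[5]
        vals = np.exp(2j * np.pi * k0 * (theta - theta[0]))[:, None]
        field = PolarField(vals, 0.05, theta, np.array([3.5e6]))
        spec = angular_transform(field, "forward").values[:, 0]
        mags = np.abs(spec)
        assert np.argmax(mags) == 5
        others = np.delete(mags, 5)
        assert np.all(others < 1e-10 * mags[5])

    def test_parseval(self, rng):
        field = random_field(rng, n_theta=256)
        dth = field.dtheta
        dk = 1.0 / (field.n_theta * dth)
        spec = angular_transform(field, "forward")
        lhs = np.sum(np.abs(field.values) ** 2) * dth
        rhs = np.sum(np.abs(spec.values) ** 2) * dk
        assert rhs == pytest.approx(lhs, rel=1e-10)

    def test_rejects_nonuniform_axis(self, rng):
        field = random_field(rng)
        field.theta_axis = field.theta_axis ** 3
        with pytest.raises(ValueError):
            angular_transform(field, "forward")


class TestWindow:
    def test_rectangular_limit(self):
        assert make_window(64, 0.0) == pytest.approx(np.ones(64))

    def test_full_hann_limit(self):
        w = make_window(64, 1.0)
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[-1] == pytest.approx(0.0, abs=1e-12)
        assert w == pytest.approx(np.hanning(64), abs=1e-12)

    @pytest.mark.parametrize("taper", [0.1, 0.25, 0.5, 0.9])
    def test_flat_interior(self, taper):
        w = make_window(65, taper)
        assert w[32] == 1.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            make_window(3, 0.25)
        with pytest.raises(ValueError):
            make_window(64, 1.5)


class TestAsmStep:
    def test_identity_step(self, rng):
        field = random_field(rng)
        spec = PropagatorSpec(field.radius, field.radius, C)
        out = asm_step(field, spec, np.ones(field.n_theta))
        assert out.values == pytest.approx(field.values, abs=1e-12)

    def test_single_mode_multiplied_by_propagator(self):
        """One angular mode at one frequency: Eq-by-eq brute force."""
        n = 64
        theta = np.linspace(-0.4, 0.4, n)
        dth = theta[1] - theta[0]
        k_axis = k_theta_axis(n, dth)
        k0 = k_axis[3]
        f = 3.5e6
        vals = np.exp(2j * np.pi * k0 * theta)[:, None]
        field = PolarField(vals, 0.05, theta, np.array([f]))
        spec = PropagatorSpec(0.05, 0.06, C)
        out = asm_step(field, spec)
        H = propagator(np.array([k0]), spec, f)[0]
        assert out.values == pytest.approx(H * vals, abs=1e-10)

    def test_matches_direct_quadratic_sum(self, rng):
        """asm_step equals an explicit O(N²) DFT/propagator/IDFT sum."""
        n = 64
        theta = np.linspace(-0.4, 0.4, n)
        dth = theta[1] - theta[0]
        f = np.array([3.5e6])
        vals = (rng.standard_normal((n, 1))
                + 1j * rng.standard_normal((n, 1)))
        field = PolarField(vals, 0.05, theta, f)
        spec = PropagatorSpec(0.05, 0.058, C)
        win = make_window(n, 0.25)
        out = asm_step(field, spec, win)

        k_axis = k_theta_axis(n, dth)
        H = propagator(k_axis, spec, f[0])
        direct = np.zeros(n, dtype=complex)
        fwd = np.array([np.sum(vals[:, 0] * np.exp(-2j * np.pi * k * theta))
                        * dth for k in k_axis])
        dk = 1.0 / (n * dth)
        for m in range(n):
            direct[m] = win[m] * np.sum(
                H * fwd * np.exp(2j * np.pi * k_axis * theta[m])) * dk
        assert out.values[:, 0] == pytest.approx(direct, abs=1e-10)

    def test_impulse_spreads_symmetrically(self):
        n = 257  # odd: a sample sits exactly on theta = 0
        theta = np.linspace(-0.5, 0.5, n)
        f = np.array([3.5e6])
        vals = np.zeros((n, 1), dtype=complex)
        vals[n // 2, 0] = 1.0
        field = PolarField(vals, 0.05, theta, f)
        lam = C / f[0]
        spec = PropagatorSpec(0.05, 0.05 + 40 * lam, C)
        out = asm_step(field, spec, make_window(n, 0.25)).values[:, 0]
        assert np.abs(out) == pytest.approx(np.abs(out[::-1]), abs=1e-8)

    def test_theta_rms_never_grows(self, rng):
        field = random_field(rng, n_theta=128)
        spec = PropagatorSpec(field.radius, field.radius + 5e-3, C)
        out = asm_step(field, spec, np.ones(field.n_theta))
        rms_in = np.sqrt(np.mean(np.abs(field.values) ** 2, axis=0))
        rms_out = np.sqrt(np.mean(np.abs(out.values) ** 2, axis=0))
        assert np.all(rms_out <= rms_in * (1 + 1e-12))

    def test_window_length_mismatch(self, rng):
        field = random_field(rng)
        spec = PropagatorSpec(field.radius, field.radius + 1e-3, C)
        with pytest.raises(ValueError):
            asm_step(field, spec, np.ones(field.n_theta + 1))


class TestMarch:
    def test_single_step_equals_asm_step(self, rng):
        field = random_field(rng)
        r0 = field.radius
        grid = PolarGrid(field.theta_axis, np.array([r0, r0 + 0.22e-3]))
        cube, _ = march(field, grid, C)
        step = asm_step(field, PropagatorSpec(r0, r0 + 0.22e-3, C))
        assert cube[:, 1, :] == pytest.approx(step.values, abs=1e-12)

    def test_step_splitting_equivalence(self, rng):
        """10 small steps equal one big step (propagating modes only).

        The composition property holds where the propagator phase
        telescopes, i.e. for modes that propagate along the whole path;
        the field is band-limited in k_theta accordingly.
        """
        n = 128
        field = random_field(rng, n_theta=n)
        r0 = field.radius
        dth = field.dtheta
        k_axis = k_theta_axis(n, dth)
        f_min = field.freq_axis.min()
        spec_vals = np.fft.fft(field.values, axis=-2)
        spec_vals[np.abs(k_axis) > 0.9 * f_min * r0 / C, :] = 0.0
        field.values = np.fft.ifft(spec_vals, axis=-2)
        dr = 0.22e-3
        grid = PolarGrid(field.theta_axis, r0 + dr * np.arange(11))
        cube, _ = march(field, grid, C, keep=[10])
        one = asm_step(field, PropagatorSpec(r0, r0 + 10 * dr, C))
        num = np.linalg.norm(cube[:, 0, :] - one.values)
        den = np.linalg.norm(one.values)
        assert num / den < 1e-8

    def test_default_radial_step_is_half_wavelength(self, c52v):
        g = PolarGrid.for_probe(c52v, 30e-3)
        assert g.dr == pytest.approx(0.5 * C / 3.5e6)
        assert g.dr == pytest.approx(0.22e-3)

    def test_empty_grid_rejected(self, rng):
        field = random_field(rng)
        with pytest.raises(ValueError):
            PolarGrid(field.theta_axis, np.array([]))

    def test_angular_upsampling_preserves_band_limited_fields(self, rng):
        """Zero-padding the angular spectrum interpolates exactly: the
        up-sampled march evaluated on the original samples matches the
        plain march for a band-limited field."""
        n = 64
        field = random_field(rng, n_theta=n)
        k_axis = k_theta_axis(n, field.dtheta)
        spec_vals = np.fft.fft(field.values, axis=-2)
        spec_vals[np.abs(k_axis) > np.abs(k_axis).max() / 4, :] = 0.0
        field.values = np.fft.ifft(spec_vals, axis=-2)
        r0 = field.radius
        grid = PolarGrid(field.theta_axis, np.array([r0, r0 + 0.22e-3]))
        plain, _ = march(field, grid, C)
        up, up_grid = march(field, grid, C, upsample=2)
        assert up_grid.n_theta == 2 * n
        # every other up-sampled theta sample coincides with an original
        on_orig = up[::2, :, :]
        assert np.allclose(on_orig[:, 1, :], plain[:, 1, :], atol=1e-10)

    def test_piecewise_sound_speed_changes_phase(self, rng):
        field = random_field(rng)
        r0 = field.radius
        grid = PolarGrid(field.theta_axis, np.array([r0, r0 + 1e-3]))
        fast, _ = march(field, grid, lambda r: 1600.0)
        slow, _ = march(field, grid, lambda r: 1450.0)
        assert not np.allclose(fast[:, 1, :], slow[:, 1, :])
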