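import numpy as np
import pytest

from polarasm import (PolarField, PolarGrid, Pulse, band_freq_axis,
                      k_theta_axis, make_focused_event, make_window)
from polarasm.geometry import polar_to_cartesian
from polarasm.migration import (PolarImage, band_weights, compound,
                                fnumber_weights, migrate_shot)
from polarasm.simulate import Phantom, simulate_channel_data
from polarasm.wavefield import init_receive_field, init_transmit_field

C = 1540.0


def make_fields(rng, n_theta=64, n_f=8, radius=0.05):
    theta = np.linspace(-0.4, 0.4, n_theta)
    freq = np.linspace(2e6, 5e6, n_f)

    def f():
        v = rng.standard_normal((n_theta, n_f)) \
            + 1j * rng.standard_normal((n_theta, n_f))
        return PolarField(v, radius, theta, freq)

    return f


@pytest.fixture
def grid():
    theta = np.linspace(-0.4, 0.4, 64)
    return PolarGrid(theta, 0.05 + 0.22e-3 * np.arange(8))


class TestMigrateShot:
    def test_zero_receive_gives_zero_image(self, rng, grid):
        mk = make_fields(rng)
        tx = mk()
        rx = mk()
        rx.values[:] = 0
        img = migrate_shot(tx, rx, grid, C)
        assert np.all(img.values == 0)

    def test_self_correlation_real_positive_at_r0(self, rng, grid):
        mk = make_fields(rng)
        tx = mk()
        img = migrate_shot(tx, tx, grid, C)
        at_r0 = img.values[:, 0]
        expect = np.sum(np.abs(tx.values.astype(np.complex64)) ** 2, axis=1)
        assert at_r0.real == pytest.approx(expect, rel=1e-5)
        assert np.abs(at_r0.imag) == pytest.approx(
            np.zeros(grid.n_theta), abs=1e-4 * expect.max())

    def test_conjugate_linear_in_tx_linear_in_rx(self, rng, grid):
        mk = make_fields(rng)
        tx1, tx2, rx1, rx2 = mk(), mk(), mk(), mk()

        def im(tx, rx):
            return migrate_shot(tx, rx, grid, C).values

        theta = tx1.theta_axis
        freq = tx1.freq_axis
        txs = PolarField(tx1.values + tx2.values, 0.05, theta, freq)
        rxs = PolarField(rx1.values + rx2.values, 0.05, theta, freq)
        lhs = im(txs, rx1)
        rhs = im(tx1, rx1) + im(tx2, rx1)
        scale = np.abs(rhs).max()
        assert lhs == pytest.approx(rhs, abs=3e-6 * scale)
        lhs2 = im(tx1, rxs)
        rhs2 = im(tx1, rx1) + im(tx1, rx2)
        assert lhs2 == pytest.approx(rhs2, abs=3e-6 * scale)

    def test_frequency_domain_equals_time_domain_correlation(self, rng):
        """Zero-lag correlation computed per-frequency equals the explicit
        time-domain inverse transform + sample product + time sum."""
        n_theta, n_f = 64, 128
        theta = np.linspace(-0.4, 0.4, n_theta)
        freq = np.fft.fftfreq(n_f, d=1 / (n_f * 30e3))  # full FFT axis
        freq = np.sort(freq)
        vals_tx = rng.standard_normal((n_theta, n_f)) \
            + 1j * rng.standard_normal((n_theta, n_f))
        vals_rx = rng.standard_normal((n_theta, n_f)) \
            + 1j * rng.standard_normal((n_theta, n_f))
        # frequency-domain imaging condition at one shell
        img_f = np.sum(np.conj(vals_tx) * vals_rx, axis=1)
        # explicit time-domain route over the same (full, complex) axis
        tx_t = np.fft.ifft(vals_tx, axis=1)
        rx_t = np.fft.ifft(vals_rx, axis=1)
        img_t = np.sum(np.conj(tx_t) * rx_t, axis=1) * n_f
        assert img_f == pytest.approx(img_t, rel=1e-8)

    def test_axis_mismatch_rejected(self, rng, grid):
        mk = make_fields(rng)
        tx = mk()
        rx = PolarField(tx.values.copy(), 0.05, tx.theta_axis,
                        tx.freq_axis * 1.1)
        with pytest.raises(ValueError):
            migrate_shot(tx, rx, grid, C)


class TestCompound:
    def test_single_image_is_itself(self, rng, grid):
        vals = rng.standard_normal((64, 8)) + 0j
        img = PolarImage(vals, grid, per_shot=True)
        out = compound([img])
        assert out.values == pytest.approx(vals)

    def test_image_plus_negation_cancels(self, rng, grid):
        vals = rng.standard_normal((64, 8)) + 0j
        a = PolarImage(vals, grid)
        b = PolarImage(-vals, grid)
        assert np.all(compound([a, b]).values == 0)

    def test_two_identical_shots_add_6db(self, rng, grid):
        vals = rng.standard_normal((64, 8)) \
            + 1j * rng.standard_normal((64, 8))
        img = PolarImage(vals, grid)
        two = compound([img, img])
        db = 20 * np.log10(np.abs(two.values).max()
                           / np.abs(img.values).max())
        assert db == pytest.approx(6.02, abs=0.01)

    def test_grid_mismatch_rejected(self, rng, grid):
        other = PolarGrid(grid.theta_samples,
                          grid.r_samples + 1e-3)
        a = PolarImage(np.ones((64, 8), complex), grid)
        b = PolarImage(np.ones((64, 8), complex), other)
        with pytest.raises(ValueError):
            compound([a, b])


class TestFnumberWeights:
    def test_sentinel_all_pass(self):
        k = np.linspace(-300, 300, 101)
        w = fnumber_weights(k, 0.06, 3.5e6, C, 0.0)
        assert w == pytest.approx(np.ones(101))

    def test_large_fnumber_keeps_only_dc(self):
        k = k_theta_axis(256, 2e-3)
        w = fnumber_weights(k, 0.06, 3.5e6, C, 1e6)
        assert w[0] == 1.0
        assert np.all(w[np.abs(k) > 1.0] == 0.0)

    def test_cutoff_formula(self):
        f, r, fn = 3.5e6, 0.06, 2.0
        kc = (f * r / C) * np.sin(np.arctan(1 / (2 * fn)))
        k = np.linspace(0, 2 * kc, 1000)
        w = fnumber_weights(k, r, f, C, fn)
        assert np.all(w[k > kc] == 0.0)
        assert np.all(w[k < 0.9 * kc] == 1.0)
        inside = (k > 0.9 * kc) & (k < kc)
        assert np.all((w[inside] > 0) & (w[inside] < 1))

    def test_negative_fnumber_rejected(self):
        with pytest.raises(ValueError):
            fnumber_weights(np.array([0.0]), 0.06, 3.5e6, C, -1.0)


class TestBandWeights:
    def test_flat_mode_binary(self, pulse):
        f = np.linspace(0, 7e6, 400)
        w = band_weights(f, pulse, "flat")
        assert set(np.unique(w)) <= {0.0, 1.0}
        assert w[np.argmin(np.abs(f - 3.5e6))] == 1.0

    def test_zero_taper_equals_flat(self, pulse):
        f = np.linspace(0, 7e6, 400)
        assert band_weights(f, pulse, "taper", 0.0) == pytest.approx(
            band_weights(f, pulse, "flat"))

    def test_taper_bounded_and_interior_flat(self, pulse):
        f = np.linspace(0, 7e6, 400)
        w = band_weights(f, pulse, "taper", 0.5)
        assert np.all((w >= 0) & (w <= 1))
        assert w[np.argmin(np.abs(f - 3.5e6))] == 1.0

    def test_empty_band_rejected(self, pulse):
        with pytest.raises(ValueError):
            band_weights(np.linspace(20e6, 30e6, 10), pulse)


@pytest.fixture(scope="module")
def point_setup():
    """Single point scatterer at the transmit focus, oracle data."""
    from polarasm import PROBE_PRESETS
    probe = PROBE_PRESETS["c52v"]
    pulse = Pulse(3.5e6, 0.5)
    depth = 25e-3
    focus_r = probe.radius_r0 + depth
    ev = make_focused_event(probe, 0.0, focus_r, C, 32)
    px, pz = polar_to_cartesian(0.0, focus_r)
    phantom = Phantom(np.array([px]), np.array([pz]), np.array([1.0]))
    fs, n_t = 14e6, 1024
    channel = simulate_channel_data(probe, [ev], pulse, phantom, C, fs, n_t)
    theta = np.linspace(-0.5, 0.5, 512)
    freq, bins = band_freq_axis(n_t, fs, pulse)
    tx0 = init_transmit_field(probe, ev, pulse, theta, freq)
    rx0 = init_receive_field(channel, 0, probe, theta, freq, bins)
    grid = PolarGrid(theta, probe.radius_r0 + 0.22e-3 * np.arange(160))
    window = make_window(512, 0.25)
    img = migrate_shot(tx0, rx0, grid, C, window=window,
                       band=band_weights(freq, pulse))
    return probe, channel, img, grid, (px, pz), focus_r


class TestEndToEnd:
    def test_point_scatterer_localized_within_half_wavelength(
            self, point_setup):
        probe, channel, img, grid, (px, pz), focus_r = point_setup
        env = img.envelope()
        i_th, i_r = np.unravel_index(np.argmax(env), env.shape)
        x, z = polar_to_cartesian(grid.theta_samples[i_th],
                                  grid.r_samples[i_r])
        half_wavelength = 0.5 * C / 3.5e6
        assert np.hypot(x - px, z - pz) <= half_wavelength

    def test_receive_backpropagation_focuses_at_scatterer(self, point_setup):
        """H+ march of the receive data concentrates energy at the
        scatterer angle when it reaches the scatterer radius."""
        from polarasm import PROBE_PRESETS, march
        probe, channel, img, grid, (px, pz), focus_r = point_setup
        pulse = Pulse(3.5e6, 0.5)
        theta = grid.theta_samples
        freq, bins = band_freq_axis(channel.n_samples,
                                    channel.sampling_rate, pulse)
        rx0 = init_receive_field(channel, 0, probe, theta, freq, bins)
        n = int(round((focus_r - probe.radius_r0) / 0.22e-3))
        g = PolarGrid(theta, probe.radius_r0 + 0.22e-3 * np.arange(n + 1))
        cube, _ = march(rx0, g, C, branch="+",
                        window=make_window(theta.size, 0.25), keep=[n])
        prof = np.sum(np.abs(cube[:, 0, :]) ** 2, axis=1)
        peak_theta = theta[np.argmax(prof)]
        assert abs(peak_theta) <= 2 * (theta[1] - theta[0])
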