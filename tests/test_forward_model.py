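"""N-wave forward model, sensor bandwidth, and noise calibration."""

import numpy as np
import pytest

from spiralpa.forward_model import (
    SOUND_SPEED,
    NoiseSpec,
    SensorResponse,
    SignalSet,
    TimeAxis,
    add_noise,
    apply_sensor_bandwidth,
    nwave_sphere,
    reference_amplitude,
    signal_cylinder,
    simulate,
)
from spiralpa.phantoms import CylindricalAbsorber, Phantom, SphericalAbsorber

TA = TimeAxis()
RESP = SensorResponse()


class TestNWave:
    sphere = SphericalAbsorber(center=(0.0, 0.0, 0.0), diameter=1.0, p0=100.0)
    sensor = (0.0, 0.0, -60.0)

    def test_compact_support_between_the_edge_arrival_times(self):
        sig = nwave_sphere(self.sphere, self.sensor, TA)
        t = TA.times()
        r, a, c = 60.0, 0.5, SOUND_SPEED
        outside = (t < (r - a) / c) | (t > (r + a) / c)
        assert np.all(sig[outside] == 0.0)
        assert np.any(sig != 0.0)

    def test_odd_symmetry_about_the_center_arrival(self):
        sig = nwave_sphere(self.sphere, self.sensor, TA)
        # bipolar: extrema match up to one-sample edge discretization,
        # and the sampled waveform nearly integrates to zero
        assert sig.max() == pytest.approx(-sig.min(), rel=0.06)
        assert abs(sig.sum()) < 0.1 * np.abs(sig).sum()

    def test_peak_amplitude_matches_oversampled_evaluation(self):
        sig = nwave_sphere(self.sphere, self.sensor, TA)
        fine = TimeAxis(fs=TA.fs * 100, n_samples=TA.n_samples * 100,
                        offset_samples=TA.offset_samples * 100)
        oracle = nwave_sphere(self.sphere, self.sensor, fine)
        assert np.abs(sig).max() == pytest.approx(np.abs(oracle).max(), rel=1e-9)
        assert np.abs(sig).max() == pytest.approx(100.0 * 0.5 / (2 * 60.0), rel=1e-9)

    def test_sensor_inside_absorber_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            nwave_sphere(self.sphere, (0.2, 0.0, 0.0), TA)


class TestCylinder:
    def test_single_packing_sphere_limit_equals_scaled_nwave(self):
        # coarse sampling makes the axial step exceed the length -> one sphere
        coarse = TimeAxis(fs=500e3, n_samples=64, offset_samples=10)
        cyl = CylindricalAbsorber(
            center=(0, 0, 0), diameter=1.0, length=1.0, azimuth=0.0, elevation=0.0, p0=100.0
        )
        got = signal_cylinder(cyl, (0, 0, -40.0), coarse)
        # volume ratio pi a^2 L / (4/3 pi a^3) = 3L/(4a) = 1.5
        want = nwave_sphere(
            SphericalAbsorber(center=(0, 0, 0), diameter=1.0, p0=150.0), (0, 0, -40.0), coarse
        )
        assert np.array_equal(got, want)

    def test_band_limited_signal_converges_as_the_axial_step_halves(self):
        cyl = CylindricalAbsorber(
            center=(0, 0, 0), diameter=1.0, length=20.0, azimuth=30.0, elevation=10.0, p0=100.0
        )
        sensor = (10.0, -20.0, -50.0)
        step = SOUND_SPEED / (2.0 * TA.fs)

        def band_limited(axial_step):
            sig = signal_cylinder(cyl, sensor, TA, axial_step=axial_step)
            s = SignalSet(values=sig[None], sensor_ids=("a",), time=TA)
            return apply_sensor_bandwidth(s, RESP).values[0]

        ref, fine = band_limited(step), band_limited(step / 2.0)
        rms = np.sqrt(np.mean((ref - fine) ** 2)) / np.sqrt(np.mean(fine**2))
        assert rms < 0.01

    def test_earliest_arrival_matches_the_closest_approach_distance(self):
        cyl = CylindricalAbsorber(
            center=(0, 0, 0), diameter=1.0, length=30.0, azimuth=90.0, elevation=0.0, p0=100.0
        )
        z = -55.0
        sig = signal_cylinder(cyl, (0.0, 0.0, z), TA)
        first = np.flatnonzero(sig)[0]
        t_first = (TA.offset_samples + first) / TA.fs
        assert t_first * SOUND_SPEED == pytest.approx(abs(z) - 0.5, abs=2 * SOUND_SPEED / TA.fs)


class TestSimulate:
    def test_empty_phantom_gives_silence(self):
        s = simulate(Phantom(absorbers=()), np.array([[0.0, 0.0, -60.0]]), TA)
        assert not s.values.any()

    def test_signals_are_linear_in_initial_pressure(self):
        ph1 = Phantom(absorbers=(SphericalAbsorber(center=(1, 2, -3), diameter=0.8, p0=50.0),))
        ph2 = Phantom(absorbers=(SphericalAbsorber(center=(1, 2, -3), diameter=0.8, p0=100.0),))
        sensors = np.array([[0.0, 0.0, -60.0], [30.0, 0.0, -50.0]])
        assert np.allclose(2.0 * simulate(ph1, sensors, TA).values,
                           simulate(ph2, sensors, TA).values, rtol=1e-12)

    def test_origin_sphere_arrives_simultaneously_at_every_real_sensor(self, device_bundle):
        ph = Phantom(absorbers=(SphericalAbsorber(center=(0, 0, 0), diameter=1.0, p0=100.0),))
        s = simulate(ph, device_bundle.array.coords, TA, sensor_ids=device_bundle.real_ids)
        first = np.array([np.flatnonzero(row)[0] for row in s.values])
        assert first.max() - first.min() <= 1

    def test_radial_shift_moves_the_arrival_by_the_flight_time(self):
        sensor = np.array([[0.0, 0.0, -60.0]])
        delta = 3.0  # mm, radially away from the sensor
        a = simulate(Phantom(absorbers=(SphericalAbsorber((0, 0, 0), 1.0, 100.0),)), sensor, TA)
        b = simulate(Phantom(absorbers=(SphericalAbsorber((0, 0, delta), 1.0, 100.0),)), sensor, TA)
        lag = np.argmax(np.correlate(b.values[0], a.values[0], mode="full")) - (TA.n_samples - 1)
        assert lag == pytest.approx(delta / SOUND_SPEED * TA.fs, abs=1.0)


class TestBandwidth:
    def test_center_frequency_tone_passes_with_unit_gain(self):
        k = round(3.5e6 * TA.n_samples / TA.fs)  # on-grid bin closest to fc
        tone = np.sin(2 * np.pi * k / TA.n_samples * np.arange(TA.n_samples))
        s = SignalSet(values=tone[None], sensor_ids=("a",), time=TA)
        out = apply_sensor_bandwidth(s, RESP).values[0]
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.01)

    def test_minus_six_db_points_sit_at_the_relative_bandwidth_edges(self):
        f = 3.5e6 * np.array([0.55, 1.45])
        assert np.allclose(RESP.amplitude(f), 0.5, rtol=0.01)
        assert RESP.amplitude(np.array([0.0]))[0] < 1e-3  # DC blocked

    def test_matches_independent_zero_padded_fft_oracle(self):
        sig = nwave_sphere(SphericalAbsorber((0, 0, 0), 1.0, 100.0), (0, 0, -60.0), TA)
        s = SignalSet(values=sig[None], sensor_ids=("a",), time=TA)
        out = apply_sensor_bandwidth(s, RESP).values[0]
        n4 = 4 * TA.n_samples
        f4 = np.fft.rfftfreq(n4, 1.0 / TA.fs)
        oracle = np.fft.irfft(np.fft.rfft(sig, n=n4) * RESP.amplitude(f4), n=n4)[: TA.n_samples]
        assert np.sqrt(np.mean((out - oracle) ** 2)) < 1e-6

    def test_band_limiting_never_adds_energy(self):
        sig = nwave_sphere(SphericalAbsorber((0, 0, 0), 1.0, 100.0), (0, 0, -60.0), TA)
        s = SignalSet(values=sig[None], sensor_ids=("a",), time=TA)
        out = apply_sensor_bandwidth(s, RESP).values[0]
        assert np.sum(out**2) <= np.sum(sig**2)

    def test_band_limiting_requires_broadband_input(self):
        s = SignalSet(values=np.zeros((1, TA.n_samples)), sensor_ids=("a",), time=TA,
                      provenance="band_limited")
        with pytest.raises(ValueError, match="ideal_broadband"):
            apply_sensor_bandwidth(s, RESP)


class TestNoiseCalibration:
    def test_reference_amplitude_is_sensor_independent_and_linear_in_p0(self, device_bundle):
        ref = reference_amplitude(RESP, TA)
        # brute force: band-limited reference signal at several real sensors
        sphere = SphericalAbsorber(center=(0, 0, 0), diameter=1.0, p0=100.0)
        sensors = device_bundle.array.coords[::101]
        s = apply_sensor_bandwidth(simulate(Phantom(absorbers=(sphere,)), sensors, TA), RESP)
        peaks = np.abs(s.values).max(axis=1)
        assert np.allclose(peaks, ref, rtol=1e-3)
        assert reference_amplitude(RESP, TA, p0=50.0) == pytest.approx(ref / 2.0, rel=1e-9)

    def test_noise_standard_deviation_matches_the_snr_definition(self):
        ta = TimeAxis(fs=60e6, n_samples=4096, offset_samples=1500)
        s = SignalSet(values=np.zeros((300, ta.n_samples)), sensor_ids=tuple(map(str, range(300))),
                      time=ta, provenance="band_limited")
        out = add_noise(s, NoiseSpec(snr_db=30.0, rng_seed=3), RESP, reference_distance=60.0)
        want = reference_amplitude(RESP, ta) * 10 ** (-30 / 20)
        assert np.std(out.values) == pytest.approx(want, rel=0.01)

    def test_infinite_snr_is_identity_and_seeds_reproduce(self):
        vals = np.random.default_rng(0).normal(size=(4, TA.n_samples))
        s = SignalSet(values=vals, sensor_ids=tuple("abcd"), time=TA, provenance="band_limited")
        assert np.array_equal(add_noise(s, NoiseSpec(snr_db=np.inf), RESP).values, vals)
        n1 = add_noise(s, NoiseSpec(rng_seed=9), RESP)
        n2 = add_noise(s, NoiseSpec(rng_seed=9), RESP)
        assert np.array_equal(n1.values, n2.values)
        assert n1.provenance == "band_limited_noisy"
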