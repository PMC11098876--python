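"""Inverse filter contracts and UBP reconstruction oracles."""

import numpy as np
import pytest

from spiralpa.forward_model import (
    SOUND_SPEED,
    SensorResponse,
    SignalSet,
    TimeAxis,
    apply_sensor_bandwidth,
    nwave_sphere,
    simulate,
)
from spiralpa.phantoms import Phantom, SphericalAbsorber, evaluation_phantom
from spiralpa.recon import (
    InverseFilterConfig,
    Volume,
    VoxelGrid,
    backprojection_term,
    inverse_filter,
    load_volume,
    mip,
    save_volume,
    ubp_reconstruct,
)

TA = TimeAxis()
RESP = SensorResponse()
INV = InverseFilterConfig(sensor_response=RESP)


class TestInverseFilter:
    def test_inverse_of_forward_restores_the_low_passed_signal(self):
        """Band-limit then inverse-filter == low-pass only, on uncapped bins."""
        sig = nwave_sphere(SphericalAbsorber((0, 0, 0), 1.0, 100.0), (0, 0, -60.0), TA)
        s = SignalSet(values=sig[None], sensor_ids=("a",), time=TA)
        rec = inverse_filter(apply_sensor_bandwidth(s, RESP), INV).values[0]
        f = np.fft.rfftfreq(TA.n_samples, 1.0 / TA.fs)
        uncapped = RESP.amplitude(f) > 1.0 / INV.gain_cap
        lpf = 1.0 / np.sqrt(1.0 + (f / INV.lpf_cutoff) ** (2 * INV.lpf_order))
        want = np.fft.irfft(np.fft.rfft(sig) * lpf * uncapped, n=TA.n_samples)
        got = np.fft.irfft(np.fft.rfft(rec) * uncapped, n=TA.n_samples)
        rms = np.sqrt(np.mean((got - want) ** 2)) / np.sqrt(np.mean(want**2))
        assert rms < 0.01

    def test_gain_never_exceeds_the_cap(self):
        f = np.linspace(0.0, 30e6, 20001)
        assert np.max(INV.gain(f)) <= INV.gain_cap + 1e-9

    def test_stop_band_suppression_of_white_noise(self):
        """Spectral density beyond 1.2x the cutoff drops >= 40 dB below passband."""
        rng = np.random.default_rng(0)
        s = SignalSet(values=rng.normal(size=(64, TA.n_samples)), sensor_ids=tuple(map(str, range(64))),
                      time=TA, provenance="band_limited_noisy")
        out = inverse_filter(s, INV)
        f = np.fft.rfftfreq(TA.n_samples, 1.0 / TA.fs)
        psd = np.mean(np.abs(np.fft.rfft(out.values, axis=1)) ** 2, axis=0)
        passband = psd[(f > 1e6) & (f < 4e6)].mean()
        stopband = psd[f > 1.2 * INV.lpf_cutoff].mean()
        assert 10 * np.log10(passband / stopband) >= 40.0

    def test_only_band_limited_provenance_accepted(self):
        s = SignalSet(values=np.zeros((1, TA.n_samples)), sensor_ids=("a",), time=TA,
                      provenance="ideal_broadband")
        with pytest.raises(ValueError, match="provenance"):
            inverse_filter(s, INV)


def brute_force_ubp(s, sensors, grid, c=SOUND_SPEED, weights=None):
    """Per-voxel time-of-flight loop, no vectorization: the UBP oracle."""
    b = backprojection_term(s)
    xs, ys, zs = grid.axes()
    if weights is None:
        weights = [1.0 / len(sensors)] * len(sensors)
    vol = np.zeros(grid.shape)
    for si in range(len(sensors)):
        for ix, x in enumerate(xs):
            for iy, y in enumerate(ys):
                for iz, z in enumerate(zs):
                    r = np.sqrt(
                        (x - sensors[si][0]) ** 2 + (y - sensors[si][1]) ** 2 + (z - sensors[si][2]) ** 2
                    )
                    u = r / c * s.time.fs - s.time.offset_samples
                    i0 = int(np.floor(u))
                    if i0 < 0 or i0 >= s.time.n_samples - 1:
                        continue
                    val = b[si, i0] + (u - i0) * (b[si, i0 + 1] - b[si, i0])
                    vol[ix, iy, iz] += weights[si] * val
    return vol


class TestUBP:
    def test_matches_the_brute_force_per_voxel_loop(self, device_bundle):
        sensors = device_bundle.array.coords[::16]  # 32 sensors
        ph = Phantom(absorbers=(SphericalAbsorber((1.0, -0.5, 0.5), 1.0, 100.0),))
        s = simulate(ph, sensors, TA)
        grid = VoxelGrid(voxel=0.5, extents=((-2.5, 2.5),) * 3)  # 10^3 voxels
        got = ubp_reconstruct(s, sensors, grid).values
        want = brute_force_ubp(s, sensors, grid)
        assert np.max(np.abs(got - want)) < 1e-9

    def test_zero_signals_give_a_zero_volume(self, device_bundle):
        s = SignalSet(values=np.zeros((512, TA.n_samples)), sensor_ids=device_bundle.real_ids,
                      time=TA, provenance="ideal_broadband")
        grid = VoxelGrid(voxel=1.0, extents=((-4.0, 4.0),) * 3)
        assert not ubp_reconstruct(s, device_bundle.array.coords, grid).values.any()

    def test_reconstruction_is_linear_in_the_signals(self, device_bundle):
        sensors = device_bundle.array.coords[::16]
        ph = Phantom(absorbers=(SphericalAbsorber((0.0, 1.0, -1.0), 1.0, 80.0),))
        s = simulate(ph, sensors, TA)
        s2 = SignalSet(values=2.0 * s.values, sensor_ids=s.sensor_ids, time=TA,
                       provenance="ideal_broadband")
        grid = VoxelGrid(voxel=0.5, extents=((-2.5, 2.5),) * 3)
        a = ubp_reconstruct(s, sensors, grid).values
        b = ubp_reconstruct(s2, sensors, grid).values
        assert np.allclose(b, 2.0 * a, rtol=1e-12, atol=1e-12)

    def test_point_source_localized_within_one_voxel(self, device_bundle):
        ph = Phantom(absorbers=(SphericalAbsorber((2.0, 1.0, -3.0), 0.6, 100.0),))
        s = simulate(ph, device_bundle.array.coords, TA)
        grid = VoxelGrid(voxel=0.2, extents=((-6.0, 6.0),) * 3)
        vol = ubp_reconstruct(s, device_bundle.array.coords, grid)
        ix = np.unravel_index(np.argmax(vol.values), vol.values.shape)
        xs, ys, zs = grid.axes()
        found = np.array([xs[ix[0]], ys[ix[1]], zs[ix[2]]])
        assert np.all(np.abs(found - [2.0, 1.0, -3.0]) <= 0.2 + 1e-12)

    def test_whole_voxel_shifts_translate_the_argmax(self, device_bundle):
        sensors = device_bundle.array.coords[::4]
        grid = VoxelGrid(voxel=0.5, extents=((-4.0, 4.0),) * 3)

        def argmax_of(center):
            ph = Phantom(absorbers=(SphericalAbsorber(center, 1.0, 100.0),))
            s = simulate(ph, sensors, TA)
            vol = ubp_reconstruct(s, sensors, grid)
            return np.array(np.unravel_index(np.argmax(vol.values), vol.values.shape))

        base = argmax_of((0.25, 0.25, 0.25))  # a voxel center: unique peak
        shifted = argmax_of((1.25, -1.25, 0.75))  # (2, -3, 1) voxels away
        assert np.array_equal(shifted - base, [2, -3, 1])

    def test_sensor_count_mismatch_rejected(self, device_bundle):
        s = SignalSet(values=np.zeros((5, TA.n_samples)), sensor_ids=tuple("abcde"), time=TA,
                      provenance="ideal_broadband")
        with pytest.raises(ValueError, match="sensor count"):
            ubp_reconstruct(s, device_bundle.array.coords, VoxelGrid(voxel=1.0, extents=((-2, 2),) * 3))


class TestMip:
    def test_single_nonzero_voxel_projects_to_a_single_pixel(self):
        grid = VoxelGrid(voxel=1.0, extents=((-3.0, 3.0),) * 3)
        vals = np.zeros(grid.shape)
        vals[1, 2, 4] = 7.0
        v = Volume(values=vals, grid=grid)
        for plane, keep in (("xy", (1, 2)), ("xz", (1, 4)), ("yz", (2, 4))):
            img = mip(v, plane)
            assert img.max() == 7.0
            assert np.argwhere(img == 7.0).tolist() == [list(keep)]

    def test_mip_equals_the_per_line_maximum(self):
        rng = np.random.default_rng(0)
        grid = VoxelGrid(voxel=1.0, extents=((-2.0, 2.0),) * 3)
        v = Volume(values=rng.normal(size=grid.shape), grid=grid)
        assert np.array_equal(mip(v, "xy"), v.values.max(axis=2))
        assert mip(v, "xz").max() <= v.values.max()

    def test_evaluation_phantom_xz_projection_shows_three_cylinders(
        self, device_bundle, device_eval_ideal
    ):
        """Peaks of the x-z MIP sit at z = -5, 0, +5 mm within half a millimetre."""
        grid = VoxelGrid(voxel=0.25, extents=((-2.0, 2.0), (-2.0, 2.0), (-8.0, 8.0)))
        vol = ubp_reconstruct(
            inverse_filter(device_eval_ideal, INV), device_bundle.dense_coords, grid
        )
        img = mip(vol, "xz")  # (x, z)
        zs = grid.axes()[2]
        profile = img.max(axis=0)
        for z0 in (-5.0, 0.0, 5.0):
            window = (zs > z0 - 2.0) & (zs < z0 + 2.0)
            zpk = zs[window][np.argmax(profile[window])]
            assert abs(zpk - z0) <= 0.5


def test_volume_tiff_roundtrip(tmp_path):
    grid = VoxelGrid(voxel=0.5, extents=((-2.0, 2.0), (-1.0, 1.0), (-3.0, 0.0)))
    v = Volume(values=np.random.default_rng(0).normal(size=grid.shape).astype(np.float32),
               grid=grid)
    save_volume(v, tmp_path / "vol.tif")
    back = load_volume(tmp_path / "vol.tif")
    assert np.allclose(back.values, v.values)
    assert back.grid == v.grid
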