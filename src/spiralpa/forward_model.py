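"""Acoustic forward model: N-waves, cylinder sphere-trains, bandwidth, noise.

A uniformly absorbing sphere of radius ``a`` illuminated by an ideal pulse
radiates the classic N-shaped bipolar wave

    p(t) = p0 * (r - c t) / (2 r)   for |r - c t| <= a,   0 otherwise,

where ``r`` is the sensor distance and ``c`` the sound speed.  Cylinders are
discretized into volume-conserving trains of small spheres along the axis
(axial step fine enough that the discretization is invisible below the
Nyquist frequency).  Sensor bandwidth limitation is a zero-phase Gaussian
amplitude response (with its mirror at negative frequency subtracted so the
response is exactly zero at DC), and the calibrated measurement noise is
i.i.d. Gaussian with a standard deviation fixed by the band-limited peak
amplitude of a reference absorber at the hemisphere center.

Units: mm, seconds, Hz; sound speed in mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .phantoms import CylindricalAbsorber, Phantom, SphericalAbsorber

#: sound speed of the water coupling medium, mm/s
SOUND_SPEED = 1.5e6

PROVENANCE_ORDER = (
    "ideal_broadband",
    "band_limited",
    "band_limited_noisy",
    "cnn_output",
    "inverse_filtered",
)


@dataclass(frozen=True)
class TimeAxis:
    """Sampling grid of the received signals.

    ``offset_samples`` is the delay (in samples) from light irradiation to
    the first recorded sample, so absolute time of sample j is
    ``(offset_samples + j) / fs``.
    """

    fs: float = 60e6
    n_samples: int = 1792
    offset_samples: int = 1500

    def times(self) -> np.ndarray:
        return (self.offset_samples + np.arange(self.n_samples)) / self.fs


def toy_time_axis() -> TimeAxis:
    """Time axis for the 40-sensor desk-scale hemisphere (R = 30 mm)."""
    return TimeAxis(fs=20e6, n_samples=192, offset_samples=300)


@dataclass(frozen=True)
class SensorResponse:
    """Zero-phase amplitude response of the detection elements.

    ``rel_bw`` is the -6 dB fractional bandwidth: the amplitude falls to 0.5
    at fc * (1 +/- rel_bw / 2).
    """

    fc: float = 3.5e6
    rel_bw: float = 0.90
    shape: str = "gaussian"

    @property
    def sigma(self) -> float:
        # half-width at half maximum = (rel_bw / 2) * fc
        return (self.rel_bw / 2.0) * self.fc / math.sqrt(2.0 * math.log(2.0))

    def amplitude(self, f: np.ndarray) -> np.ndarray:
        """Amplitude gain at frequency ``f`` (Hz).

        Gaussian centered at fc minus its mirror at -fc; the mirror term is
        ~1e-6 near fc but forces an exact zero at DC.
        """
        f = np.asarray(f, dtype=float)
        s2 = 2.0 * self.sigma**2
        return np.exp(-((f - self.fc) ** 2) / s2) - np.exp(-((f + self.fc) ** 2) / s2)


@dataclass(frozen=True)
class NoiseSpec:
    snr_db: float = 30.0
    reference_p0: float = 100.0
    reference_diameter: float = 1.0  # mm
    rng_seed: int = 0


@dataclass(frozen=True)
class SignalSet:
    """Pressure traces at a set of sensors (rows) over the time axis (columns)."""

    values: np.ndarray  # (n_sensors, n_samples)
    sensor_ids: tuple[str, ...]
    time: TimeAxis
    provenance: str = "ideal_broadband"

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sensor_ids):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with {len(self.sensor_ids)} sensor ids"
            )
        if self.values.shape[1] != self.time.n_samples:
            raise ValueError("values column count must equal time.n_samples")
        if self.provenance not in PROVENANCE_ORDER:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def id_to_row(self) -> dict[str, int]:
        return {sid: k for k, sid in enumerate(self.sensor_ids)}

    def rows(self, ids) -> np.ndarray:
        lookup = self.id_to_row
        return self.values[[lookup[i] for i in ids]]


@njit(cache=True)
def _accumulate_nwaves(centers, radii, p0s, sensors, fs, offset, c, n_samples):  # pragma: no cover
    out = np.zeros((sensors.shape[0], n_samples))
    for si in range(sensors.shape[0]):
        sx = sensors[si, 0]
        sy = sensors[si, 1]
        sz = sensors[si, 2]
        for k in range(centers.shape[0]):
            dx = sx - centers[k, 0]
            dy = sy - centers[k, 1]
            dz = sz - centers[k, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            a = radii[k]
            j0 = int(math.ceil((r - a) / c * fs - offset))
            j1 = int(math.floor((r + a) / c * fs - offset))
            if j1 < 0 or j0 >= n_samples:
                continue
            if j0 < 0:
                j0 = 0
            if j1 >= n_samples:
                j1 = n_samples - 1
            amp = p0s[k] / (2.0 * r)
            for j in range(j0, j1 + 1):
                t = (offset + j) / fs
                out[si, j] += amp * (r - c * t)
    return out


def _cylinder_sphere_train(
    cyl: CylindricalAbsorber, time: TimeAxis, c: float, axial_step: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discretize a cylinder into a volume-conserving train of spheres.

    Sphere diameter equals the cylinder diameter; the axial step is at most
    c / (4 f_max) with f_max = fs / 2, so the comb structure lies far above
    the Nyquist frequency.  Per-sphere p0 is scaled so the summed absorbed
    volume equals the cylinder volume.
    """
    a = cyl.diameter / 2.0
    step_max = axial_step if axial_step is not None else c / (4.0 * (time.fs / 2.0))
    n = max(1, int(math.ceil(cyl.length / step_max)))
    offsets = (np.arange(n) - (n - 1) / 2.0) * (cyl.length / n)
    centers = np.asarray(cyl.center) + offsets[:, None] * cyl.axis[None, :]
    # volume ratio: pi a^2 L / (n * 4/3 pi a^3) = 3 L / (4 a n)
    scale = 3.0 * cyl.length / (4.0 * a * n)
    return centers, np.full(n, a), np.full(n, cyl.p0 * scale)


def _gather_spheres(
    phantom: Phantom, time: TimeAxis, c: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cs, rs, ps = [], [], []
    for ab in phantom.absorbers:
        if isinstance(ab, SphericalAbsorber):
            cs.append(np.asarray(ab.center)[None, :])
            rs.append(np.array([ab.diameter / 2.0]))
            ps.append(np.array([ab.p0]))
        else:
            c3, r3, p3 = _cylinder_sphere_train(ab, time, c)
            cs.append(c3)
            rs.append(r3)
            ps.append(p3)
    if not cs:
        return np.zeros((0, 3)), np.zeros(0), np.zeros(0)
    return np.vstack(cs), np.concatenate(rs), np.concatenate(ps)


def _check_sensors_outside(phantom: Phantom, sensors: np.ndarray) -> None:
    for ab in phantom.absorbers:
        if isinstance(ab, SphericalAbsorber):
            d = np.linalg.norm(sensors - np.asarray(ab.center), axis=1)
            if np.any(d <= ab.diameter / 2.0):
                raise ValueError(f"sensor inside spherical absorber at {ab.center}")
        else:
            rel = sensors - np.asarray(ab.center)
            u = rel @ ab.axis
            u_cl = np.clip(u, -ab.length / 2.0, ab.length / 2.0)
            closest = np.asarray(ab.center) + u_cl[:, None] * ab.axis[None, :]
            d = np.linalg.norm(sensors - closest, axis=1)
            if np.any(d <= ab.diameter / 2.0):
                raise ValueError(f"sensor inside cylindrical absorber at {ab.center}")


def nwave_sphere(
    absorber: SphericalAbsorber,
    sensor_pos,
    time: TimeAxis,
    c: float = SOUND_SPEED,
) -> np.ndarray:
    """Ideal broadband N-wave of one sphere at one sensor, sampled on ``time``."""
    pos = np.asarray(sensor_pos, dtype=float)
    r = float(np.linalg.norm(pos - np.asarray(absorber.center)))
    a = absorber.diameter / 2.0
    if r <= a:
        raise ValueError(f"sensor at {sensor_pos} lies inside the absorber (r={r:.3f} <= a={a:.3f})")
    u = r - c * time.times()
    return np.where(np.abs(u) <= a, absorber.p0 * u / (2.0 * r), 0.0)


def signal_cylinder(
    absorber: CylindricalAbsorber,
    sensor_pos,
    time: TimeAxis,
    c: float = SOUND_SPEED,
    axial_step: float | None = None,
) -> np.ndarray:
    """Ideal broadband signal of one cylinder at one sensor (sphere-train sum)."""
    sensors = np.asarray(sensor_pos, dtype=float)[None, :]
    _check_sensors_outside(Phantom(absorbers=(absorber,)), sensors)
    centers, radii, p0s = _cylinder_sphere_train(absorber, time, c, axial_step)
    return _accumulate_nwaves(
        centers, radii, p0s, sensors, time.fs, time.offset_samples, c, time.n_samples
    )[0]


def simulate(
    phantom: Phantom,
    sensor_coords,
    time: TimeAxis,
    c: float = SOUND_SPEED,
    sensor_ids: tuple[str, ...] | None = None,
) -> SignalSet:
    """Simulate ideal broadband received signals at every sensor position."""
    sensors = np.ascontiguousarray(np.asarray(sensor_coords, dtype=float))
    _check_sensors_outside(phantom, sensors)
    centers, radii, p0s = _gather_spheres(phantom, time, c)
    values = _accumulate_nwaves(
        centers, radii, p0s, sensors, time.fs, time.offset_samples, c, time.n_samples
    )
    if sensor_ids is None:
        sensor_ids = tuple(f"s{k}" for k in range(sensors.shape[0]))
    return SignalSet(values=values, sensor_ids=sensor_ids, time=time, provenance="ideal_broadband")


def apply_sensor_bandwidth(s: SignalSet, resp: SensorResponse) -> SignalSet:
    """Band-limit signals with the sensor's zero-phase amplitude response."""
    if s.provenance != "ideal_broadband":
        raise ValueError(f"expected ideal_broadband input, got {s.provenance}")
    f = np.fft.rfftfreq(s.time.n_samples, d=1.0 / s.time.fs)
    spec = np.fft.rfft(s.values, axis=1) * resp.amplitude(f)
    values = np.fft.irfft(spec, n=s.time.n_samples, axis=1)
    return replace(s, values=values, provenance="band_limited")


def reference_amplitude(
    resp: SensorResponse,
    time: TimeAxis,
    c: float = SOUND_SPEED,
    distance: float = 60.0,
    p0: float = 100.0,
    diameter: float = 1.0,
) -> float:
    """Band-limited peak amplitude of the noise-calibration reference.

    The reference is a sphere of the given diameter and p0 at the hemisphere
    center observed at one sensor (all sensors are equidistant, so any one
    will do); ``distance`` is the hemisphere radius.
    """
    sphere = SphericalAbsorber(center=(0.0, 0.0, 0.0), diameter=diameter, p0=p0)
    s = SignalSet(
        values=nwave_sphere(sphere, (0.0, 0.0, -distance), time, c)[None, :],
        sensor_ids=("ref",),
        time=time,
    )
    return float(np.max(np.abs(apply_sensor_bandwidth(s, resp).values)))


def add_noise(
    s: SignalSet,
    spec: NoiseSpec,
    resp: SensorResponse,
    c: float = SOUND_SPEED,
    reference_distance: float = 60.0,
    noise_std: float | None = None,
) -> SignalSet:
    """Add calibrated i.i.d. Gaussian noise to band-limited signals.

    The noise standard deviation is ``reference_amplitude * 10**(-snr_db/20)``
    — e.g. 30 dB S/N means noise at -30 dB of the band-limited peak from the
    reference absorber at the hemisphere center.
    """
    if s.provenance != "band_limited":
        raise ValueError(f"expected band_limited input, got {s.provenance}")
    if math.isinf(spec.snr_db):
        return replace(s, provenance="band_limited_noisy")
    if noise_std is None:
        ref = reference_amplitude(
            resp, s.time, c, distance=reference_distance,
            p0=spec.reference_p0, diameter=spec.reference_diameter,
        )
        noise_std = ref * 10.0 ** (-spec.snr_db / 20.0)
    rng = np.random.default_rng(spec.rng_seed)
    values = s.values + rng.normal(0.0, noise_std, size=s.values.shape)
    return replace(s, values=values, provenance="band_limited_noisy")
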