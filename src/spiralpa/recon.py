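"""Inverse filtering and universal back-projection (UBP) reconstruction.

The inverse filter divides the spectrum by the sensor amplitude response to
restore pre-band-limitation signals, guarded by a zero-phase low-pass (so
high-frequency noise where the sensor response vanishes is not amplified)
and a hard cap on the total gain.

UBP back-projects the filtered term b(t) = 2 p(t) - 2 t dp/dt onto each
voxel at the time of flight t = |r_voxel - r_sensor| / c, with per-element
solid-angle weights normalized by the total solid angle.  Element areas of
the device are not published, so the default weighting splits the
hemisphere's 2*pi solid angle uniformly across elements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .forward_model import SOUND_SPEED, SensorResponse, SignalSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InverseFilterConfig:
    sensor_response: SensorResponse = field(default_factory=SensorResponse)
    lpf_cutoff: float = 5e6  # Hz
    lpf_order: int = 32  # Butterworth-magnitude order; >=40 dB by 1.2x cutoff
    gain_cap: float = 100.0

    def __post_init__(self) -> None:
        if self.lpf_cutoff <= 0 or not math.isfinite(self.gain_cap):
            raise ValueError("lpf_cutoff must be positive and gain_cap finite")

    def gain(self, f: np.ndarray) -> np.ndarray:
        """Zero-phase frequency-domain gain LPF(f) / max(H(f), 1/gain_cap)."""
        f = np.asarray(f, dtype=float)
        lpf = 1.0 / np.sqrt(1.0 + (f / self.lpf_cutoff) ** (2 * self.lpf_order))
        h = np.maximum(self.sensor_response.amplitude(f), 1.0 / self.gain_cap)
        return lpf / h


def inverse_filter(s: SignalSet, cfg: InverseFilterConfig) -> SignalSet:
    """Undo the sensor bandwidth within the low-pass guard band."""
    if s.provenance not in ("band_limited", "band_limited_noisy", "cnn_output"):
        raise ValueError(f"cannot inverse-filter signals with provenance {s.provenance}")
    f = np.fft.rfftfreq(s.time.n_samples, d=1.0 / s.time.fs)
    spec = np.fft.rfft(s.values, axis=1) * cfg.gain(f)
    values = np.fft.irfft(spec, n=s.time.n_samples, axis=1)
    return replace(s, values=values, provenance="inverse_filtered")


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid; voxel centers at min + (i + 1/2) * voxel."""

    voxel: float = 0.1  # mm
    extents: tuple[tuple[float, float], ...] = ((-12.0, 12.0), (-12.0, 12.0), (-12.0, 12.0))

    def __post_init__(self) -> None:
        if self.voxel <= 0:
            raise ValueError("voxel must be positive")
        for lo, hi in self.extents:
            if hi <= lo:
                raise ValueError("extents must be well-ordered")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round((hi - lo) / self.voxel)) for lo, hi in self.extents
        )

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            lo + (np.arange(n) + 0.5) * self.voxel
            for (lo, _), n in zip(self.extents, self.shape)
        )

    def centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) voxel-center coordinates."""
        xs, ys, zs = self.axes()
        g = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        return g


@dataclass(frozen=True)
class Volume:
    values: np.ndarray  # (nx, ny, nz)
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")


def backprojection_term(s: SignalSet) -> np.ndarray:
    """b(t) = 2 p(t) - 2 t dp/dt, central differences in the interior."""
    t = s.time.times()
    dpdt = np.gradient(s.values, axis=1) * s.time.fs
    return 2.0 * s.values - 2.0 * t[None, :] * dpdt


@njit(cache=True)
def _ubp_kernel(b, sensors, weights, xs, ys, zs, fs, offset, c):  # pragma: no cover
    nx, ny, nz = xs.size, ys.size, zs.size
    n_samples = b.shape[1]
    vol = np.zeros((nx, ny, nz))
    n_out = 0
    for si in range(sensors.shape[0]):
        w = weights[si]
        sx = sensors[si, 0]
        sy = sensors[si, 1]
        sz = sensors[si, 2]
        for ix in range(nx):
            dx = xs[ix] - sx
            for iy in range(ny):
                dy = ys[iy] - sy
                for iz in range(nz):
                    dz = zs[iz] - sz
                    r = math.sqrt(dx * dx + dy * dy + dz * dz)
                    u = r / c * fs - offset
                    i0 = int(math.floor(u))
                    if i0 < 0 or i0 >= n_samples - 1:
                        n_out += 1
                        continue
                    frac = u - i0
                    val = b[si, i0] + frac * (b[si, i0 + 1] - b[si, i0])
                    vol[ix, iy, iz] += w * val
    return vol, n_out


def ubp_reconstruct(
    s: SignalSet,
    sensor_coords,
    grid: VoxelGrid,
    c: float = SOUND_SPEED,
    weights: np.ndarray | None = None,
) -> Volume:
    """Universal back-projection onto a voxel grid.

    Voxels whose time of flight falls outside the recorded window receive no
    contribution from that sensor (logged once per call).
    """
    if s.provenance not in ("inverse_filtered", "ideal_broadband"):
        raise ValueError(f"cannot reconstruct from provenance {s.provenance}")
    sensors = np.ascontiguousarray(np.asarray(sensor_coords, dtype=float))
    if sensors.shape[0] != s.values.shape[0]:
        raise ValueError("sensor count does not match signal rows")
    if weights is None:
        weights = np.full(sensors.shape[0], 1.0 / sensors.shape[0])
    b = np.ascontiguousarray(backprojection_term(s))
    xs, ys, zs = grid.axes()
    vol, n_out = _ubp_kernel(
        b, sensors, np.asarray(weights, dtype=float),
        xs, ys, zs, s.time.fs, float(s.time.offset_samples), c,
    )
    if n_out:
        log.warning("UBP: %d voxel-sensor pairs fell outside the recorded time window", n_out)
    return Volume(values=vol, grid=grid)


_MIP_AXIS = {"xy": 2, "xz": 1, "yz": 0}


def mip(v: Volume, plane: str) -> np.ndarray:
    """Maximum intensity projection of a volume onto one coordinate plane."""
    if plane not in _MIP_AXIS:
        raise ValueError(f"plane must be one of {sorted(_MIP_AXIS)}")
    return v.values.max(axis=_MIP_AXIS[plane])


def save_volume(v: Volume, path: str | Path) -> None:
    """Write the volume as a TIFF z-stack with a JSON grid sidecar."""
    import json

    import tifffile

    path = Path(path)
    # z as leading (page) axis
    tifffile.imwrite(path, np.moveaxis(v.values, 2, 0).astype(np.float32),
                     photometric="minisblack")
    meta = {"voxel": v.grid.voxel, "extents": [list(e) for e in v.grid.extents]}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_volume(path: str | Path) -> Volume:
    import json

    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = np.moveaxis(tifffile.imread(path), 0, 2).astype(float)
    grid = VoxelGrid(voxel=meta["voxel"], extents=tuple(tuple(e) for e in meta["extents"]))
    return Volume(values=values, grid=grid)
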