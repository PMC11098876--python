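"""Quantitative evaluation: absorber/background masks, volume S/N, Pearson correlation.

The volume S/N protocol takes the mean reconstructed intensity inside the
absorbers as the signal amplitude and the standard deviation of the
background as the noise level:  S/N = 20 log10(mean_signal / std_background).
The background excludes a guard band around every absorber surface, since
partial-volume voxels at the surface belong to neither class cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import SignalSet
from .phantoms import CylindricalAbsorber, Phantom, SphericalAbsorber
from .recon import Volume, VoxelGrid


@dataclass(frozen=True)
class MaskPair:
    signal_mask: np.ndarray  # bool, absorber interiors
    background_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.signal_mask.shape != self.background_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.signal_mask & self.background_mask):
            raise ValueError("signal and background masks overlap")
        if not self.signal_mask.any():
            raise ValueError("signal mask is empty")
        if not self.background_mask.any():
            raise ValueError("background mask is empty")


def _outside_distance(phantom: Phantom, pts: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest absorber surface (0 inside)."""
    d_min = np.full(pts.shape[0], np.inf)
    for ab in phantom.absorbers:
        if isinstance(ab, SphericalAbsorber):
            d = np.linalg.norm(pts - np.asarray(ab.center), axis=1) - ab.diameter / 2.0
            d = np.maximum(d, 0.0)
        else:
            rel = pts - np.asarray(ab.center)
            u = rel @ ab.axis
            rho = np.linalg.norm(rel - u[:, None] * ab.axis[None, :], axis=1)
            dr = np.maximum(rho - ab.diameter / 2.0, 0.0)
            du = np.maximum(np.abs(u) - ab.length / 2.0, 0.0)
            d = np.hypot(dr, du)
        d_min = np.minimum(d_min, d)
    return d_min


def phantom_masks(phantom: Phantom, grid: VoxelGrid, guard: float = 2.0) -> MaskPair:
    """Build signal (inside any absorber) and guard-banded background masks."""
    pts = grid.centers().reshape(-1, 3)
    d = _outside_distance(phantom, pts)
    signal = (d <= 0.0).reshape(grid.shape)
    background = (d > guard).reshape(grid.shape)
    if not signal.any():
        raise ValueError("no voxel center falls inside any absorber")
    if not background.any():
        raise ValueError("background mask is empty (guard too large for the grid)")
    return MaskPair(signal_mask=signal, background_mask=background)


def snr_db(v: Volume, masks: MaskPair) -> float:
    """Volume S/N: 20 log10(mean inside absorbers / std of background)."""
    if v.values.shape != masks.signal_mask.shape:
        raise ValueError("masks do not match the volume grid")
    sig = float(np.mean(v.values[masks.signal_mask]))
    noise = float(np.std(v.values[masks.background_mask]))
    if noise == 0.0:
        raise ValueError("background standard deviation is zero")
    if sig <= 0.0:
        raise ValueError(f"mean absorber intensity is non-positive ({sig:.3g})")
    return 20.0 * np.log10(sig / noise)


def pearson_corr(a: SignalSet, b: SignalSet, subset=None) -> float:
    """Pearson correlation over all (sensor, sample) pairs of a sensor subset."""
    if a.time != b.time:
        raise ValueError("signal sets have different time axes")
    if subset is None:
        if a.sensor_ids != b.sensor_ids:
            raise ValueError("signal sets cover different sensors; pass a subset")
        x, y = a.values, b.values
    else:
        subset = tuple(subset)
        x, y = a.rows(subset), b.rows(subset)
    x = x.ravel()
    y = y.ravel()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])
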