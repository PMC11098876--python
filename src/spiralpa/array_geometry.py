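"""Fibonacci hemispherical sensor array: coordinates, spiral chains, virtual sensors.

A golden-ratio ("Fibonacci") hemispherical lattice places sensor *i* at
azimuth 2*pi*i/G (G the golden ratio) and at uniformly spaced depths
z_i = z1 + (i-1)*dz below the equatorial plane, projected onto the sphere of
radius R via r_i = sqrt(R^2 - z_i^2).  Because consecutive azimuths advance by
the golden angle, the lattice exhibits visible spiral families at Fibonacci
index strides: sensors whose indices share a residue class modulo 34, 21 or 13
are spatial neighbours along a spiral.  This module generates the lattice,
extracts those spiral chains, truncates each chain family to its minimum
length, and places one virtual sensor between every pair of chain-adjacent
real sensors (cubic-spline midpoint, renormalized onto the sphere).

All lengths are millimetres.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

#: spiral direction -> index stride (Fibonacci numbers); direction 1 has the
#: shortest inter-sensor distance, direction 3 the longest.
DEVICE_INTERVALS = (34, 21, 13)


@dataclass(frozen=True)
class ArrayConfig:
    """Configuration of a Fibonacci hemispherical array.

    Parameters
    ----------
    R : hemisphere radius (mm).
    n_channels : number of physical sensors.
    z1 : z of the first (deepest) sensor, mm, strictly negative.
    dz : z-spacing between consecutive nominal indices, mm, positive.
    omitted_indices : nominal indices with no sensor (holes in the bowl).
    appended_indices : extra indices appended past ``n_channels`` to replace
        the omitted ones; ``len(appended) == len(omitted)``.
    intervals : spiral index stride per direction (1, 2, 3).
    """

    R: float = 60.0
    n_channels: int = 512
    z1: float | None = None
    dz: float | None = None
    omitted_indices: frozenset[int] = frozenset()
    appended_indices: tuple[int, ...] = ()
    intervals: tuple[int, int, int] = DEVICE_INTERVALS
    G: float = GOLDEN_RATIO

    def __post_init__(self) -> None:
        if len(self.appended_indices) != len(self.omitted_indices):
            raise ValueError(
                "appended_indices and omitted_indices must have equal size "
                f"({len(self.appended_indices)} != {len(self.omitted_indices)})"
            )
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        # Resolve default z-spacing: nominal indices span the bowl from near
        # the pole (z = -0.99 R, leaving room for the central laser hole) to
        # near the equator (z = -0.05 R).
        i_max = self.max_index
        if self.z1 is None:
            object.__setattr__(self, "z1", -0.99 * self.R)
        if self.dz is None:
            z_end = -0.05 * self.R
            object.__setattr__(self, "dz", (z_end - self.z1) / (i_max - 1))
        if self.z1 >= 0:
            raise ValueError("z1 must be negative (array sits below z = 0)")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        if self.z1 + (i_max - 1) * self.dz >= 0:
            raise ValueError("largest index reaches z >= 0: all sensors must lie below the equator")

    @property
    def max_index(self) -> int:
        return max([self.n_channels, *self.appended_indices])

    @property
    def indices(self) -> tuple[int, ...]:
        """Sorted sensor indices: {1..n_channels} plus appended minus omitted."""
        s = set(range(1, self.n_channels + 1))
        s |= set(self.appended_indices)
        s -= set(self.omitted_indices)
        return tuple(sorted(s))

    def to_json(self) -> str:
        d = {
            "R": self.R,
            "n_channels": self.n_channels,
            "z1": self.z1,
            "dz": self.dz,
            "omitted_indices": sorted(self.omitted_indices),
            "appended_indices": list(self.appended_indices),
            "intervals": list(self.intervals),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArrayConfig":
        d = json.loads(text)
        return cls(
            R=d["R"],
            n_channels=d["n_channels"],
            z1=d["z1"],
            dz=d["dz"],
            omitted_indices=frozenset(d["omitted_indices"]),
            appended_indices=tuple(d["appended_indices"]),
            intervals=tuple(d["intervals"]),
        )


def device_config(**overrides) -> ArrayConfig:
    """The 512-channel hemispherical array (R ~ 60 mm).

    Indices 7 and 20 carry no sensor (water supply/drain hole); sensors are
    placed instead at the positions of nominal indices 513 and 514, keeping
    the channel count at 512.
    """
    kw = dict(
        R=60.0,
        n_channels=512,
        omitted_indices=frozenset({7, 20}),
        appended_indices=(513, 514),
        intervals=DEVICE_INTERVALS,
    )
    kw.update(overrides)
    return ArrayConfig(**kw)


def toy_config(**overrides) -> ArrayConfig:
    """A 40-sensor desk-scale hemisphere used for fast end-to-end runs.

    Spiral strides are the smaller Fibonacci triple (13, 8, 5), matching the
    lattice scale of 40 sensors the way (34, 21, 13) matches 512.
    """
    kw = dict(R=30.0, n_channels=40, intervals=(13, 8, 5))
    kw.update(overrides)
    return ArrayConfig(**kw)


@dataclass(frozen=True)
class SensorArray:
    """Indexed sensor positions on the hemisphere."""

    indices: tuple[int, ...]
    coords: np.ndarray  # (n, 3) mm
    config: ArrayConfig

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.coords):
            raise ValueError("indices and coords length mismatch")

    @property
    def n(self) -> int:
        return len(self.indices)

    def position_of(self, index: int) -> np.ndarray:
        return self.coords[self.indices.index(index)]

    @property
    def index_to_row(self) -> dict[int, int]:
        return {idx: k for k, idx in enumerate(self.indices)}


def fibonacci_coordinates(config: ArrayConfig) -> SensorArray:
    """Compute sensor coordinates of the golden-ratio hemispherical lattice.

    x_i = r_i cos(2 pi i / G), y_i = r_i sin(2 pi i / G),
    z_i = z1 + (i - 1) dz,     r_i = sqrt(R^2 - z_i^2).
    """
    idx = np.asarray(config.indices, dtype=np.int64)
    z = config.z1 + (idx - 1) * config.dz
    if np.any(z >= 0) or np.any(np.abs(z) > config.R):
        bad = idx[(z >= 0) | (np.abs(z) > config.R)]
        raise ValueError(f"indices {bad.tolist()} fall off the hemisphere (z={z.min():.3f}..{z.max():.3f})")
    r = np.sqrt(config.R**2 - z**2)
    phi = 2.0 * np.pi * idx / config.G
    coords = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    arr = SensorArray(indices=tuple(int(i) for i in idx), coords=coords, config=config)
    if arr.n != config.n_channels:
        raise ValueError(f"configuration yields {arr.n} sensors, expected {config.n_channels}")
    return arr


@dataclass(frozen=True)
class SpiralChain:
    """One spiral: the sensors of a single residue class modulo the stride.

    ``member_indices`` run from the bottom of the hemisphere (lowest index)
    towards the periphery.
    """

    direction: int  # 1, 2 or 3
    interval: int
    residue: int  # in [1, interval]; residue == interval <-> index % interval == 0
    member_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        for i in self.member_indices:
            if i % self.interval != self.residue % self.interval:
                raise ValueError(
                    f"chain (direction {self.direction}, residue {self.residue}): "
                    f"member {i} not congruent to {self.residue} mod {self.interval}"
                )
        if any(b <= a for a, b in zip(self.member_indices, self.member_indices[1:])):
            raise ValueError("member_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.member_indices)


def extract_spiral_chains(array: SensorArray, direction: int) -> list[SpiralChain]:
    """Split the array into its spiral chains along one direction.

    Returns one chain per residue class ``1..interval``; the chains are
    disjoint and together cover every sensor.
    """
    if direction not in (1, 2, 3):
        raise ValueError(f"direction must be 1, 2 or 3, got {direction}")
    interval = array.config.intervals[direction - 1]
    buckets: dict[int, list[int]] = {r: [] for r in range(1, interval + 1)}
    for i in array.indices:  # already sorted ascending
        r = i % interval
        buckets[r if r != 0 else interval].append(i)
    return [
        SpiralChain(direction=direction, interval=interval, residue=r, member_indices=tuple(m))
        for r, m in buckets.items()
    ]


def truncate_chains(chains: list[SpiralChain]) -> list[SpiralChain]:
    """Truncate every chain of one direction to the direction's minimum length.

    The members kept are each chain's lowest-index (innermost) sensors, so the
    dropped sensors are the peripheral ends of the longer spirals.
    """
    if not chains:
        return []
    directions = {c.direction for c in chains}
    if len(directions) != 1:
        raise ValueError(f"chains mix directions {sorted(directions)}")
    m = min(len(c) for c in chains)
    return [replace(c, member_indices=c.member_indices[:m]) for c in chains]


@dataclass(frozen=True)
class VirtualSensorSet:
    """Virtual sensors placed midway along each spiral chain.

    ``parent[k] = (direction, residue, pos)`` means virtual sensor ``k`` sits
    between members ``pos`` and ``pos+1`` of that chain.
    """

    coords: np.ndarray  # (k, 3) mm
    parent: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.parent) != len(self.coords):
            raise ValueError("parent and coords length mismatch")
        if len(set(self.parent)) != len(self.parent):
            raise ValueError("duplicate virtual sensor identity")

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f"v{d}.{r}.{p}" for d, r, p in self.parent)


def place_virtual_sensors(
    truncated_chains: dict[int, list[SpiralChain]], array: SensorArray
) -> VirtualSensorSet:
    """Place one virtual sensor between each adjacent pair of chain members.

    Each chain's member coordinates are interpolated with a cubic spline
    parameterized by member ordinal; the virtual sensor is the spline value at
    the half-ordinal, then radially renormalized onto the sphere of radius R.
    Virtual sensors of different directions are kept distinct even where their
    positions nearly coincide.
    """
    row_of = array.index_to_row
    R = array.config.R
    coords_out: list[np.ndarray] = []
    parents: list[tuple[int, int, int]] = []
    for direction in sorted(truncated_chains):
        for chain in truncated_chains[direction]:
            m = len(chain)
            if m < 3:
                raise ValueError(
                    f"chain (direction {chain.direction}, residue {chain.residue}) has "
                    f"{m} members; >= 3 required for cubic spline placement"
                )
            pts = array.coords[[row_of[i] for i in chain.member_indices]]
            spl = CubicSpline(np.arange(m, dtype=float), pts, axis=0)
            mid = spl(np.arange(m - 1, dtype=float) + 0.5)
            mid *= R / np.linalg.norm(mid, axis=1, keepdims=True)
            coords_out.append(mid)
            parents.extend((chain.direction, chain.residue, p) for p in range(m - 1))
    return VirtualSensorSet(coords=np.vstack(coords_out), parent=tuple(parents))


@dataclass(frozen=True)
class GeometryBundle:
    """Everything downstream stages need: array, truncated chains, virtuals.

    ``dense_coords`` stacks real sensors (in index order) then virtual sensors
    (direction, residue, position order); ``dense_ids`` names rows "r<i>" and
    "v<d>.<res>.<pos>" accordingly.
    """

    array: SensorArray
    chains: dict[int, list[SpiralChain]]  # truncated, keyed by direction
    virtuals: VirtualSensorSet

    @property
    def real_ids(self) -> tuple[str, ...]:
        return tuple(f"r{i}" for i in self.array.indices)

    @property
    def dense_ids(self) -> tuple[str, ...]:
        return self.real_ids + self.virtuals.ids

    @property
    def dense_coords(self) -> np.ndarray:
        return np.vstack([self.array.coords, self.virtuals.coords])

    @property
    def n_dense(self) -> int:
        return self.array.n + self.virtuals.n


def build_dense_geometry(config: ArrayConfig) -> GeometryBundle:
    """Build the full real + virtual geometry for a configuration."""
    array = fibonacci_coordinates(config)
    chains = {
        d: truncate_chains(extract_spiral_chains(array, d)) for d in (1, 2, 3)
    }
    virtuals = place_virtual_sensors(chains, array)
    return GeometryBundle(array=array, chains=chains, virtuals=virtuals)


# ---------------------------------------------------------------------------
# CSV + JSON sidecar export


def export_geometry(bundle: GeometryBundle, csv_path: str | Path) -> None:
    """Write real and virtual sensor coordinates to CSV with a JSON sidecar.

    Floats are written with ``repr`` (shortest round-trip form) so that
    export -> import reproduces coordinates bit-exactly.
    """
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["index", "kind", "direction_or_0", "residue_or_0", "x_mm", "y_mm", "z_mm"])
        for idx, c in zip(bundle.array.indices, bundle.array.coords):
            w.writerow([idx, "real", 0, 0, *(repr(float(v)) for v in c)])
        for (d, r, p), c in zip(bundle.virtuals.parent, bundle.virtuals.coords):
            w.writerow([p, "virtual", d, r, *(repr(float(v)) for v in c)])
    csv_path.with_suffix(".json").write_text(bundle.array.config.to_json())


def import_geometry(csv_path: str | Path) -> GeometryBundle:
    """Rebuild a GeometryBundle from :func:`export_geometry` output."""
    csv_path = Path(csv_path)
    config = ArrayConfig.from_json(csv_path.with_suffix(".json").read_text())
    real_idx: list[int] = []
    real_xyz: list[list[float]] = []
    v_parent: list[tuple[int, int, int]] = []
    v_xyz: list[list[float]] = []
    with open(csv_path, newline="") as f:
        rd = csv.reader(f)
        next(rd)
        for row in rd:
            idx, kind, d, r = int(row[0]), row[1], int(row[2]), int(row[3])
            xyz = [float(row[4]), float(row[5]), float(row[6])]
            if kind == "real":
                real_idx.append(idx)
                real_xyz.append(xyz)
            else:
                v_parent.append((d, r, idx))
                v_xyz.append(xyz)
    array = SensorArray(indices=tuple(real_idx), coords=np.array(real_xyz), config=config)
    chains = {d: truncate_chains(extract_spiral_chains(array, d)) for d in (1, 2, 3)}
    virtuals = VirtualSensorSet(coords=np.array(v_xyz), parent=tuple(v_parent))
    return GeometryBundle(array=array, chains=chains, virtuals=virtuals)
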