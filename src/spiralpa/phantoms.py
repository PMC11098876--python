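"""Optical-absorber phantoms: random training phantoms and the fixed evaluation phantom.

Phantoms are pure geometric descriptions (spheres and cylinders with an
initial sound pressure p0); the acoustic part lives in
:mod:`spiralpa.forward_model`.  Random training phantoms mix three absorber
classes — spheres, short cylinders and long cylinders — with every parameter
drawn uniformly from its range, all absorber centers confined to a ball
around the hemisphere center.  Absorbers may overlap; pressures superpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np


@dataclass(frozen=True)
class SphericalAbsorber:
    center: tuple[float, float, float]  # mm
    diameter: float  # mm
    p0: float  # arb. units

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.p0 <= 0:
            raise ValueError("diameter and p0 must be positive")


@dataclass(frozen=True)
class CylindricalAbsorber:
    """Finite cylinder; ``azimuth`` is the axis bearing in the x-y plane (deg),
    ``elevation`` the axis angle with the x-y plane (deg)."""

    center: tuple[float, float, float]  # mm
    diameter: float  # mm
    length: float  # mm
    azimuth: float  # deg, [-180, 180]
    elevation: float  # deg
    p0: float  # arb. units

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0 or self.p0 <= 0:
            raise ValueError("diameter, length and p0 must be positive")
        if not -180.0 <= self.azimuth <= 180.0:
            raise ValueError("azimuth must lie in [-180, 180] deg")

    @property
    def axis(self) -> np.ndarray:
        az = np.deg2rad(self.azimuth)
        el = np.deg2rad(self.elevation)
        return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


Absorber = Union[SphericalAbsorber, CylindricalAbsorber]


@dataclass(frozen=True)
class Phantom:
    absorbers: tuple[Absorber, ...]
    seed: int | None = None

    def to_json(self) -> str:
        items = []
        for a in self.absorbers:
            if isinstance(a, SphericalAbsorber):
                items.append({"type": "sphere", "center": list(a.center), "diameter": a.diameter, "p0": a.p0})
            else:
                items.append(
                    {
                        "type": "cylinder",
                        "center": list(a.center),
                        "diameter": a.diameter,
                        "length": a.length,
                        "azimuth": a.azimuth,
                        "elevation": a.elevation,
                        "p0": a.p0,
                    }
                )
        return json.dumps({"seed": self.seed, "absorbers": items}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Phantom":
        d = json.loads(text)
        absorbers: list[Absorber] = []
        for it in d["absorbers"]:
            if it["type"] == "sphere":
                absorbers.append(
                    SphericalAbsorber(center=tuple(it["center"]), diameter=it["diameter"], p0=it["p0"])
                )
            else:
                absorbers.append(
                    CylindricalAbsorber(
                        center=tuple(it["center"]),
                        diameter=it["diameter"],
                        length=it["length"],
                        azimuth=it["azimuth"],
                        elevation=it["elevation"],
                        p0=it["p0"],
                    )
                )
        return cls(absorbers=tuple(absorbers), seed=d["seed"])


@dataclass(frozen=True)
class AbsorberRanges:
    """Uniform sampling ranges for one training-phantom recipe.

    Defaults are the training conditions for the hemispherical device:
    1-4 absorbers per class, diameters 0.2-1.2 mm, p0 50-100, centers within
    10 mm of the hemisphere center; short cylinders 10-20 mm long with
    elevation in [-70, 70] deg, long cylinders 50 mm long with elevation in
    [-5, 5] deg.
    """

    count: tuple[int, int] = (1, 4)
    diameter: tuple[float, float] = (0.2, 1.2)
    p0: tuple[float, float] = (50.0, 100.0)
    placement_radius: float = 10.0
    # cylinder-only fields; length None means "sample a sphere"
    length: tuple[float, float] | None = None
    elevation: tuple[float, float] = (0.0, 0.0)


TRAINING_CLASSES: tuple[AbsorberRanges, ...] = (
    AbsorberRanges(),  # spheres
    AbsorberRanges(length=(10.0, 20.0), elevation=(-70.0, 70.0)),  # short cylinders
    AbsorberRanges(length=(50.0, 50.0), elevation=(-5.0, 5.0)),  # long cylinders
)

#: sphere-only recipe for the 40-sensor desk-scale hemisphere
TOY_CLASSES: tuple[AbsorberRanges, ...] = (
    AbsorberRanges(count=(1, 4), diameter=(0.6, 1.5), placement_radius=5.0),
)


def _uniform_in_ball(rng: np.random.Generator, radius: float) -> tuple[float, float, float]:
    # rejection sampling from the bounding cube; deterministic given rng state
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if float(p @ p) <= radius * radius:
            return (float(p[0]), float(p[1]), float(p[2]))


def random_phantom(seed: int, classes: tuple[AbsorberRanges, ...] = TRAINING_CLASSES) -> Phantom:
    """Draw one random phantom; deterministic given ``seed``.

    For each absorber class the count is uniform on ``[count_lo, count_hi]``
    and every ranged parameter uniform on its interval.
    """
    rng = np.random.default_rng(seed)
    absorbers: list[Absorber] = []
    for cls_ranges in classes:
        n = int(rng.integers(cls_ranges.count[0], cls_ranges.count[1] + 1))
        for _ in range(n):
            center = _uniform_in_ball(rng, cls_ranges.placement_radius)
            d = float(rng.uniform(*cls_ranges.diameter))
            p0 = float(rng.uniform(*cls_ranges.p0))
            if cls_ranges.length is None:
                absorbers.append(SphericalAbsorber(center=center, diameter=d, p0=p0))
            else:
                absorbers.append(
                    CylindricalAbsorber(
                        center=center,
                        diameter=d,
                        length=float(rng.uniform(*cls_ranges.length)),
                        azimuth=float(rng.uniform(-180.0, 180.0)),
                        elevation=float(rng.uniform(*cls_ranges.elevation)),
                        p0=p0,
                    )
                )
    return Phantom(absorbers=tuple(absorbers), seed=seed)


def random_training_phantom(rng_seed: int) -> Phantom:
    """Random training phantom with the standard three absorber classes."""
    return random_phantom(rng_seed, TRAINING_CLASSES)


def evaluation_phantom() -> Phantom:
    """The fixed three-cylinder evaluation phantom.

    Three cylinders, diameter 1.0 mm, length 50 mm, p0 = 100, axes parallel
    to the y-axis, centered at (0, -5, -5), (0, 0, 0) and (0, 5, 5) mm.
    """
    mk = lambda c: CylindricalAbsorber(
        center=c, diameter=1.0, length=50.0, azimuth=90.0, elevation=0.0, p0=100.0
    )
    return Phantom(
        absorbers=(mk((0.0, -5.0, -5.0)), mk((0.0, 0.0, 0.0)), mk((0.0, 5.0, 5.0))),
        seed=None,
    )
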