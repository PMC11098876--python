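"""Chain-ordered 2D signal patterns: gather, linear interleave, dense scatter.

Arranging the received signals of the sensors along one spiral chain as the
rows of a 2D image yields a regular pattern (wavefronts vary smoothly from
row to row), which is the unit of work of the interpolator.  The linear
interleave inserts the arithmetic mean of neighbouring rows between every
pair of real rows — this only serves to give the interpolator input the same
shape as its output; its interpolation quality is not relied upon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .array_geometry import GeometryBundle, SpiralChain, VirtualSensorSet
from .forward_model import SignalSet


@dataclass(frozen=True)
class Pattern:
    """Real-sensor rows of one chain: (m, n_samples)."""

    values: np.ndarray
    chain_ref: tuple[int, int]  # (direction, residue)

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class InterleavedPattern:
    """Alternating real/virtual rows of one chain: (2m-1, n_samples).

    Rows 0, 2, 4, ... are real sensors; odd rows are virtual.
    """

    values: np.ndarray
    chain_ref: tuple[int, int]

    def __post_init__(self) -> None:
        if self.values.shape[0] % 2 == 0:
            raise ValueError("interleaved pattern must have an odd row count")

    @property
    def m(self) -> int:
        return (self.values.shape[0] + 1) // 2

    @property
    def real_rows(self) -> np.ndarray:
        return self.values[0::2]

    @property
    def virtual_rows(self) -> np.ndarray:
        return self.values[1::2]


def extract_pattern(chain: SpiralChain, s: SignalSet) -> Pattern:
    """Gather one chain's real-sensor signals into a pattern, bottom row first."""
    lookup = s.id_to_row
    rows = []
    for idx in chain.member_indices:
        sid = f"r{idx}"
        if sid not in lookup:
            raise KeyError(
                f"chain (direction {chain.direction}, residue {chain.residue}): "
                f"sensor {sid} missing from signal set"
            )
        rows.append(lookup[sid])
    return Pattern(values=s.values[rows], chain_ref=(chain.direction, chain.residue))


def extract_dense_pattern(chain: SpiralChain, dense: SignalSet) -> InterleavedPattern:
    """Gather real and virtual rows of one chain from a dense signal set."""
    lookup = dense.id_to_row
    m = len(chain)
    out_rows = []
    for pos, idx in enumerate(chain.member_indices):
        out_rows.append(lookup[f"r{idx}"])
        if pos < m - 1:
            vid = f"v{chain.direction}.{chain.residue}.{pos}"
            if vid not in lookup:
                raise KeyError(f"virtual sensor {vid} missing from signal set")
            out_rows.append(lookup[vid])
    return InterleavedPattern(
        values=dense.values[out_rows], chain_ref=(chain.direction, chain.residue)
    )


def interleave_linear(p: Pattern) -> InterleavedPattern:
    """Insert the sample-wise mean of adjacent rows between every row pair."""
    m, n = p.values.shape
    if m < 2:
        raise ValueError("need at least 2 rows to interleave")
    out = np.empty((2 * m - 1, n), dtype=p.values.dtype)
    out[0::2] = p.values
    out[1::2] = 0.5 * (p.values[:-1] + p.values[1:])
    return InterleavedPattern(values=out, chain_ref=p.chain_ref)


def scatter_dense(
    patterns: dict[tuple[int, int], InterleavedPattern],
    bundle: GeometryBundle,
    real: SignalSet,
    use_cnn_real: bool = False,
    provenance: str | None = None,
) -> SignalSet:
    """Assemble the dense (real + virtual) signal set from per-chain patterns.

    Virtual rows come from the odd pattern rows; real rows are taken from the
    original ``real`` signals (measured or simulated) rather than the
    interpolator output, unless ``use_cnn_real`` — denoised real rows come
    with a slight waveform smoothing that can bias the reconstruction low.
    """
    virtuals = bundle.virtuals
    n_samples = real.time.n_samples
    vals = np.zeros((real.values.shape[0] + virtuals.n, n_samples), dtype=float)
    real_rows = real.rows([f"r{i}" for i in bundle.array.indices])
    vals[: real.values.shape[0]] = real_rows

    vrow_of = {p: k for k, p in enumerate(virtuals.parent)}
    filled = np.zeros(virtuals.n, dtype=bool)
    for direction, chains in bundle.chains.items():
        for chain in chains:
            key = (chain.direction, chain.residue)
            if key not in patterns:
                raise KeyError(f"missing pattern for chain {key}")
            pat = patterns[key]
            if pat.m != len(chain):
                raise ValueError(
                    f"pattern for chain {key} has {pat.m} real rows, chain has {len(chain)}"
                )
            for pos in range(pat.m - 1):
                ident = (chain.direction, chain.residue, pos)
                k = vrow_of.get(ident)
                if k is None:
                    raise KeyError(f"virtual identity {ident} unknown to geometry")
                if filled[k]:
                    raise ValueError(f"virtual identity {ident} written twice")
                vals[real.values.shape[0] + k] = pat.values[2 * pos + 1]
                filled[k] = True
            if use_cnn_real:
                lookup = {f"r{i}": r for r, i in enumerate(bundle.array.indices)}
                for pos, idx in enumerate(chain.member_indices):
                    vals[lookup[f"r{idx}"]] = pat.values[2 * pos]
    if not filled.all():
        missing = [virtuals.parent[k] for k in np.flatnonzero(~filled)[:5]]
        raise ValueError(f"virtual identities never written, e.g. {missing}")
    return SignalSet(
        values=vals,
        sensor_ids=bundle.dense_ids,
        time=real.time,
        provenance=provenance or real.provenance,
    )
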