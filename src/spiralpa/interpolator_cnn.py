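"""Convolutional interpolator for chain patterns, in pure NumPy.

One model per spiral direction maps a linearly interleaved noisy pattern
(real rows measured, virtual rows = neighbour means) to the dense noise-free
pattern (real and virtual rows, band-limited, no noise).  The network is a
stack of same-shape 2D convolutions with ReLU activations and periodic skip
connections, a linear regression output layer, and a global identity skip
from input to output — with the output layer zero-initialized the model
starts as the identity, so training can only move it away from the linear
baseline it is fed.

Convolutions are stride-1 same-padding, implemented with im2col + BLAS
matmuls and explicit backward passes; the optimizer is resilient
backpropagation (iRprop-), whose per-parameter step sizes adapt
multiplicatively from the gradient sign history.  Everything is float32 and
deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .array_geometry import GeometryBundle
from .forward_model import (
    SOUND_SPEED,
    NoiseSpec,
    SensorResponse,
    SignalSet,
    TimeAxis,
    add_noise,
    apply_sensor_bandwidth,
    reference_amplitude,
    simulate,
)
from .pattern_ops import InterleavedPattern, extract_dense_pattern, extract_pattern, interleave_linear
from .phantoms import AbsorberRanges, TRAINING_CLASSES, random_phantom

#: device mini-batch sizes per direction (GPU-memory-motivated at full
#: scale; kept as the defaults)
DEVICE_BATCH_SIZES = {1: 50, 2: 100, 3: 150}


@dataclass(frozen=True)
class ModelConfig:
    direction: int
    input_rows: int  # 27 / 45 / 75 for the device
    n_samples: int = 1792
    kernel: tuple[int, int] = (7, 77)  # (sensor direction, time direction)
    n_filters: int = 64
    n_conv_layers: int = 8
    skip_period: int = 2

    def __post_init__(self) -> None:
        if self.kernel[0] % 2 == 0 or self.kernel[1] % 2 == 0:
            raise ValueError("kernel sides must be odd (same-padding convolutions)")
        if self.n_conv_layers < 1:
            raise ValueError("need at least one convolutional layer")


@dataclass(frozen=True)
class TrainConfig:
    solver: str = "rprop"
    learning_rate: float = 1e-5  # initial Rprop step size
    epochs: int = 50
    batch_size: int | None = None  # None -> DEVICE_BATCH_SIZES[direction]
    loss: str = "mse"
    seed: int = 0
    scale: str = "full"  # or "reduced"
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    step_min: float = 1e-9
    step_max: float = 1.0


# ---------------------------------------------------------------------------
# conv2d building blocks


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*kh*kw) patch matrix, same padding."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * H * W, C * kh * kw)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    c_out, c_in, kh, kw = W.shape
    B, C, H, Wd = x.shape
    cols = _im2col(x, kh, kw)
    y = cols @ W.reshape(c_out, -1).T + b
    return y.reshape(B, H, Wd, c_out).transpose(0, 3, 1, 2)


def _conv_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padding stride-1 conv: (dx, dW, db)."""
    c_out, c_in, kh, kw = W.shape
    B, C, H, Wd = x.shape
    dy_mat = dy.transpose(0, 2, 3, 1).reshape(B * H * Wd, c_out)
    cols = _im2col(x, kh, kw)
    dW = (dy_mat.T @ cols).reshape(W.shape)
    db = dy_mat.sum(axis=0)
    W_rot = np.ascontiguousarray(W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx = _conv_forward(dy, W_rot, np.zeros(c_in, dtype=W.dtype))
    return dx, dW, db


class InterpolatorCNN:
    """Same-shape convolutional regressor for one spiral direction."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        kh, kw = config.kernel
        F = config.n_filters
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        c_in = 1
        for _ in range(config.n_conv_layers):
            fan_in = c_in * kh * kw
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(F, c_in, kh, kw))
            self.weights.append(w.astype(np.float32))
            self.biases.append(np.zeros(F, dtype=np.float32))
            c_in = F
        # regression output layer, zero-initialized: model starts as identity
        self.weights.append(np.zeros((1, F, kh, kw), dtype=np.float32))
        self.biases.append(np.zeros(1, dtype=np.float32))

    # -- forward -----------------------------------------------------------

    def _forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        cfg = self.config
        acts = [x]  # post-activation outputs, acts[k] feeds conv k
        pre = []  # pre-activation values, needed for the ReLU mask
        h = x
        for k in range(cfg.n_conv_layers):
            z = _conv_forward(h, self.weights[k], self.biases[k])
            skip_src = k + 1 - cfg.skip_period
            if (k + 1) % cfg.skip_period == 0 and skip_src >= 1:
                z = z + acts[skip_src]
            pre.append(z)
            h = np.maximum(z, 0.0)
            acts.append(h)
        y = x + _conv_forward(h, self.weights[-1], self.biases[-1])
        return y, acts, pre

    def forward(self, x: np.ndarray, chunk: int = 8) -> np.ndarray:
        """Batched inference; ``x`` is (B, rows, samples) or (rows, samples)."""
        single = x.ndim == 2
        xb = np.asarray(x, dtype=np.float32)
        if single:
            xb = xb[None]
        outs = []
        for lo in range(0, xb.shape[0], chunk):
            y, _, _ = self._forward_cached(xb[lo : lo + chunk, None, :, :])
            outs.append(y[:, 0])
        out = np.concatenate(outs, axis=0)
        return out[0] if single else out

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(
        self, x: np.ndarray, t: np.ndarray, chunk: int = 8
    ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """Mean-squared error over the batch and its parameter gradients."""
        cfg = self.config
        gW = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        total = 0.0
        n_total = x.size
        for lo in range(0, x.shape[0], chunk):
            xb = np.asarray(x[lo : lo + chunk], dtype=np.float32)[:, None]
            tb = np.asarray(t[lo : lo + chunk], dtype=np.float32)[:, None]
            y, acts, pre = self._forward_cached(xb)
            resid = y - tb
            total += float(np.sum(resid * resid.astype(np.float64)))
            dy = (2.0 / n_total) * resid
            # output layer (+ identity skip does not reach parameters)
            dh, dW, db = _conv_backward(acts[-1], self.weights[-1], dy)
            gW[-1] += dW
            gb[-1] += db
            d_acts = [np.zeros_like(a) for a in acts]
            d_acts[-1] = dh
            for k in range(cfg.n_conv_layers - 1, -1, -1):
                dz = d_acts[k + 1] * (pre[k] > 0.0)
                skip_src = k + 1 - cfg.skip_period
                if (k + 1) % cfg.skip_period == 0 and skip_src >= 1:
                    d_acts[skip_src] = d_acts[skip_src] + dz
                dx, dW, db = _conv_backward(acts[k], self.weights[k], dz)
                gW[k] += dW
                gb[k] += db
                d_acts[k] = d_acts[k] + dx
        return total / n_total, gW, gb

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def describe(self) -> list[str]:
        out = []
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            kind = "conv+relu" if k < self.config.n_conv_layers else "conv (regression output)"
            out.append(f"layer {k}: {kind}, weights {w.shape}, bias {b.shape}")
        out.append(f"total parameters: {self.n_parameters}")
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"W{k}": w for k, w in enumerate(self.weights)}
        arrays.update({f"b{k}": b for k, b in enumerate(self.biases)})
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "InterpolatorCNN":
        path = Path(path)
        cfg_d = json.loads(path.with_suffix(".json").read_text())
        cfg_d["kernel"] = tuple(cfg_d["kernel"])
        model = cls(ModelConfig(**cfg_d))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            model.weights = [z[f"W{k}"] for k in range(len(model.weights))]
            model.biases = [z[f"b{k}"] for k in range(len(model.biases))]
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> InterpolatorCNN:
    """Construct the per-direction interpolator and sanity-check its shape."""
    model = InterpolatorCNN(cfg, seed=seed)
    probe = np.zeros((1, cfg.input_rows, min(cfg.n_samples, 128)), dtype=np.float32)
    out = model.forward(probe)
    if out.shape != probe.shape:
        raise ValueError(f"model changes shape: {probe.shape} -> {out.shape}")
    return model


# ---------------------------------------------------------------------------
# training data


@dataclass(frozen=True)
class TrainingSet:
    inputs: np.ndarray  # (N, rows, samples) float32, normalized
    targets: np.ndarray  # same shape
    normalization: float  # divide-by constant (reference amplitude)
    direction: int
    phantom_ids: np.ndarray  # (N,) phantom ordinal of each sample


def make_training_set(
    n_phantoms: int,
    direction: int,
    bundle: GeometryBundle,
    time: TimeAxis,
    resp: SensorResponse,
    seed: int = 0,
    snr_db: float = 30.0,
    c: float = SOUND_SPEED,
    classes: tuple[AbsorberRanges, ...] = TRAINING_CLASSES,
) -> TrainingSet:
    """Simulate phantoms and assemble (linear-interleaved noisy, ideal dense) pairs.

    For each phantom: ideal broadband signals are simulated at the real
    sensors and this direction's virtual sensors, band-limited, and used as
    the noise-free targets; the inputs are the band-limited real signals with
    calibrated noise added, chain-extracted and linearly interleaved.  Both
    are divided by the global normalization constant (the band-limited
    reference amplitude), so p0 = 100 maps to O(1).
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    chains = bundle.chains[direction]
    vsel = [k for k, (d, _, _) in enumerate(bundle.virtuals.parent) if d == direction]
    coords = np.vstack([bundle.array.coords, bundle.virtuals.coords[vsel]])
    ids = bundle.real_ids + tuple(bundle.virtuals.ids[k] for k in vsel)
    n_real = bundle.array.n
    R = bundle.array.config.R
    norm = reference_amplitude(resp, time, c, distance=R)
    noise_std = norm * 10.0 ** (-snr_db / 20.0)

    root = np.random.default_rng(seed)
    phantom_seeds = root.integers(0, 2**31 - 1, size=n_phantoms)
    noise_seeds = root.integers(0, 2**31 - 1, size=n_phantoms)
    inputs, targets, owners = [], [], []
    for pk in range(n_phantoms):
        phantom = random_phantom(int(phantom_seeds[pk]), classes)
        ideal = apply_sensor_bandwidth(simulate(phantom, coords, time, c, sensor_ids=ids), resp)
        real_bl = SignalSet(
            values=ideal.values[:n_real], sensor_ids=ids[:n_real], time=time, provenance="band_limited"
        )
        noisy_real = add_noise(
            real_bl, NoiseSpec(snr_db=snr_db, rng_seed=int(noise_seeds[pk])), resp,
            c=c, noise_std=noise_std,
        )
        for chain in chains:
            inp = interleave_linear(extract_pattern(chain, noisy_real))
            tgt = extract_dense_pattern(chain, ideal)
            inputs.append(inp.values)
            targets.append(tgt.values)
            owners.append(pk)
    return TrainingSet(
        inputs=(np.stack(inputs) / norm).astype(np.float32),
        targets=(np.stack(targets) / norm).astype(np.float32),
        normalization=norm,
        direction=direction,
        phantom_ids=np.asarray(owners),
    )


# ---------------------------------------------------------------------------
# training (iRprop-)


class _Rprop:
    """iRprop-: sign-based updates with multiplicatively adapted step sizes."""

    def __init__(self, params: list[np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.steps = [np.full_like(p, cfg.learning_rate) for p in params]
        self.prev = [np.zeros_like(p) for p in params]

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        cfg = self.cfg
        for p, g, step, prev in zip(params, grads, self.steps, self.prev):
            agree = g * prev
            np.multiply(step, cfg.eta_plus, out=step, where=agree > 0)
            np.multiply(step, cfg.eta_minus, out=step, where=agree < 0)
            np.clip(step, cfg.step_min, cfg.step_max, out=step)
            g_eff = np.where(agree < 0, 0.0, g).astype(p.dtype)
            p -= np.sign(g_eff) * step
            prev[...] = g_eff


def train(
    model: InterpolatorCNN,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Train in place; returns the loss history (per-epoch mean MSE).

    Deterministic given ``cfg.seed``.  Raises ``RuntimeError`` if the loss
    diverges to NaN/Inf.
    """
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    if cfg.solver != "rprop":
        raise ValueError(f"unknown solver {cfg.solver!r}")
    batch = cfg.batch_size or DEVICE_BATCH_SIZES.get(model.config.direction, 50)
    params = model.weights + model.biases
    opt = _Rprop(params, cfg)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    val_history: list[float] = []
    n = inputs.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, batch):
            sel = order[lo : lo + batch]
            loss, gW, gb = model.loss_and_grads(inputs[sel], targets[sel])
            if not math.isfinite(loss):
                raise RuntimeError(f"training diverged: loss={loss} at epoch {_epoch}")
            opt.update(params, gW + gb)
            epoch_loss += loss * len(sel)
        history.append(epoch_loss / n)
        if validation is not None:
            vx, vt = validation
            pred = model.forward(vx)
            val_history.append(float(np.mean((pred - vt) ** 2)))
    return {"loss": history, "val_loss": val_history}


def predict(
    model: InterpolatorCNN, interleaved: InterleavedPattern, normalization: float
) -> InterleavedPattern:
    """Apply the interpolator to one interleaved pattern, in signal units."""
    rows, n = interleaved.values.shape
    if rows != model.config.input_rows:
        raise ValueError(
            f"pattern has {rows} rows but model direction {model.config.direction} "
            f"expects {model.config.input_rows}"
        )
    x = (interleaved.values / normalization).astype(np.float32)
    y = model.forward(x)
    if not np.all(np.isfinite(y)):
        raise RuntimeError("model produced non-finite output")
    return InterleavedPattern(
        values=np.asarray(y, dtype=float) * normalization, chain_ref=interleaved.chain_ref
    )
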