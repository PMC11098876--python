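"""Desk-scale benchmark: does a trained interpolator beat the linear baseline?

Full-scale training (512 channels, 1000 phantoms, 50 epochs) needs weeks of
GPU time, so this module runs the identical pipeline on a 40-sensor toy
hemisphere (R = 30 mm, spiral strides 13/8/5, 20 MHz sampling, 192 samples)
with sphere-only phantoms and a shrunken model, small enough to train on a
CPU in a few minutes.  It reports the held-out virtual-signal correlation
and the reconstructed volume S/N for both the trained model and the linear
interleave baseline.  Direction 3 (stride 5, the longest chains of the toy
array) is used; the reconstruction compares the same partial dense aperture
(real sensors + direction-3 virtual sensors) under the two interpolators, so
the S/N difference isolates interpolation quality.
"""

from __future__ import annotations

import numpy as np

from .array_geometry import build_dense_geometry, toy_config
from .evaluation import pearson_corr, phantom_masks, snr_db
from .forward_model import (
    NoiseSpec,
    SensorResponse,
    SignalSet,
    add_noise,
    apply_sensor_bandwidth,
    reference_amplitude,
    simulate,
    toy_time_axis,
)
from .interpolator_cnn import (
    InterpolatorCNN,
    ModelConfig,
    TrainConfig,
    build_model,
    make_training_set,
    predict,
    train,
)
from .pattern_ops import extract_pattern, interleave_linear
from .phantoms import TOY_CLASSES, random_phantom
from .recon import InverseFilterConfig, VoxelGrid, inverse_filter, ubp_reconstruct


def toy_model_config(direction: int = 3, input_rows: int = 15, n_samples: int = 192) -> ModelConfig:
    return ModelConfig(
        direction=direction,
        input_rows=input_rows,
        n_samples=n_samples,
        kernel=(5, 17),
        n_filters=8,
        n_conv_layers=4,
        skip_period=2,
    )


def run_reduced_scale_benchmark(
    seed: int = 0,
    n_phantoms: int = 20,
    holdout_fraction: float = 0.1,
    epochs: int = 40,
    batch_size: int = 30,
    learning_rate: float = 1e-4,
    voxel: float = 0.35,
    guard: float = 1.5,
) -> dict:
    """Train the toy interpolator and compare it against linear interleaving.

    Returns a dict with held-out correlations and MSEs (CNN vs linear) and
    reconstructed S/N values on one held-out phantom.
    """
    direction = 3
    bundle = build_dense_geometry(toy_config())
    time = toy_time_axis()
    resp = SensorResponse()
    ts = make_training_set(
        n_phantoms, direction, bundle, time, resp, seed=seed, classes=TOY_CLASSES
    )
    n_holdout = max(1, int(round(holdout_fraction * n_phantoms)))
    held_phantoms = set(range(n_phantoms - n_holdout, n_phantoms))
    held = np.isin(ts.phantom_ids, list(held_phantoms))
    x_tr, t_tr = ts.inputs[~held], ts.targets[~held]
    x_va, t_va = ts.inputs[held], ts.targets[held]

    chains = bundle.chains[direction]
    m = len(chains[0])
    model = build_model(toy_model_config(direction, 2 * m - 1, time.n_samples), seed=seed)
    cfg = TrainConfig(
        learning_rate=learning_rate, epochs=epochs, batch_size=batch_size,
        seed=seed, scale="reduced",
    )
    history = train(model, x_tr, t_tr, cfg, validation=(x_va, t_va))

    pred_va = model.forward(x_va)
    virt = slice(1, None, 2)  # odd rows are the virtual sensors
    corr = lambda a, b: float(np.corrcoef(a[:, virt].ravel(), b[:, virt].ravel())[0, 1])
    result = {
        "corr_cnn": corr(pred_va, t_va),
        "corr_linear": corr(x_va, t_va),
        "mse_cnn": float(np.mean((pred_va[:, virt] - t_va[:, virt]) ** 2)),
        "mse_linear": float(np.mean((x_va[:, virt] - t_va[:, virt]) ** 2)),
        "loss_history": history["loss"],
        "val_history": history["val_loss"],
    }

    result.update(
        _holdout_reconstruction_snr(
            model, ts.normalization, bundle, time, resp, seed, voxel, guard
        )
    )
    return result


def _holdout_reconstruction_snr(
    model: InterpolatorCNN,
    norm: float,
    bundle,
    time,
    resp,
    seed: int,
    voxel: float,
    guard: float,
) -> dict:
    """Reconstruct one fresh phantom with CNN vs linear virtual signals."""
    direction = model.config.direction
    chains = bundle.chains[direction]
    R = bundle.array.config.R
    phantom = random_phantom(seed + 900_001, TOY_CLASSES)
    real_ids = bundle.real_ids
    ideal = apply_sensor_bandwidth(
        simulate(phantom, bundle.array.coords, time, sensor_ids=real_ids), resp
    )
    noisy = add_noise(
        ideal, NoiseSpec(rng_seed=seed + 77), resp, reference_distance=R
    )
    vsel = [k for k, (d, _, _) in enumerate(bundle.virtuals.parent) if d == direction]
    coords = np.vstack([bundle.array.coords, bundle.virtuals.coords[vsel]])

    def dense_values(use_model: bool) -> np.ndarray:
        vrows = []
        for chain in chains:
            lin = interleave_linear(extract_pattern(chain, noisy))
            pat = predict(model, lin, norm) if use_model else lin
            vrows.append(pat.values[1::2])
        return np.vstack([noisy.values, *vrows])

    grid = VoxelGrid(voxel=voxel, extents=((-7.0, 7.0), (-7.0, 7.0), (-7.0, 7.0)))
    masks = phantom_masks(phantom, grid, guard=guard)
    inv = InverseFilterConfig(sensor_response=resp)
    out = {}
    for label, use_model in (("cnn", True), ("linear", False)):
        dense = SignalSet(
            values=dense_values(use_model),
            sensor_ids=tuple(f"d{k}" for k in range(coords.shape[0])),
            time=time,
            provenance="band_limited_noisy",
        )
        vol = ubp_reconstruct(inverse_filter(dense, inv), coords, grid)
        out[f"snr_{label}"] = snr_db(vol, masks)
    return out
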