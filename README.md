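# spiralpa

Virtual dense hemispherical arrays for sparse-sensor 3D photoacoustic
tomography.

Hemispherical detector bowls give photoacoustic tomography its widest view
of vessels running in arbitrary directions, but affordable bowls are sparse
— the modelled device has 512 elements on a 60 mm golden-ratio (Fibonacci)
lattice — and universal back-projection (UBP) from a sparse aperture leaves
strong streak artifacts.  `spiralpa` implements the virtual-dense-array
method: the lattice's spiral structure is decomposed into three chain
families (index strides 34, 21, 13 — Fibonacci numbers), a virtual sensor is
placed between every pair of chain-adjacent real sensors (1385 virtual
elements, 1897 total), virtual signals are generated by interpolating each
chain's 2D signal pattern (linear baseline, or a trained convolutional
interpolator), and the volume is reconstructed from the dense aperture by
inverse filtering and UBP:

    p0(r) = (1/Omega0) * sum_i dOmega_i * [ 2 p_i(t) - 2 t dp_i/dt ],
    t = |r - r_i| / c

A complete N-wave forward simulator (spheres and volume-conserving
sphere-train cylinders, Gaussian sensor bandwidth, calibrated noise) makes
every stage testable without measured data.  The package is a library plus a
thin `spiralpa` command-line tool; the convolutional interpolator is
implemented directly in NumPy (im2col convolutions, hand-written backward
passes, resilient backpropagation) and trains on a CPU at reduced scale.

## Worked example

Reconstruct the three-cylinder evaluation phantom (1.0 mm diameter, 50 mm
long, p0 = 100, parallel to y at (0,-5,-5), (0,0,0), (0,5,5) mm) under four
signal conditions and compare volume S/N:

```python
from spiralpa.cli_io import run_snr_benchmark

report = run_snr_benchmark(seed=1, scale="ci")  # 0.4 mm voxels, ~10 s
for k in ("corr_linear_virtual", "snr_noisy_512", "snr_ideal_512",
          "snr_linear_1897", "snr_ideal_1897", "snr_density_gain_ideal"):
    print(f"{k:24s} {report[k]: .3f}")
```

prints

```
corr_linear_virtual       0.038
snr_noisy_512             13.815
snr_ideal_512             13.816
snr_linear_1897           16.781
snr_ideal_1897            20.618
snr_density_gain_ideal    6.802
```

Reading: linearly interpolated virtual signals barely correlate with the
true ones (0.038 — two time-shifted N-waves average into the wrong
waveform), yet even wrong-but-dense signals raise the S/N of the
reconstruction by 3 dB over the sparse aperture (16.8 vs 13.8 dB), because
back-projections only reinforce inside real absorbers.  Ideal dense signals
buy +6.8 dB over ideal sparse ones — the pure sensor-density effect.  With
the 1.0 mm-sphere noise reference, 30 dB electrical noise adds almost
nothing on top of the artifact floor (13.815 vs 13.816 dB).

Train and evaluate the interpolator at desk scale (40-sensor hemisphere,
sphere phantoms, ~4 min on one CPU):

```python
from spiralpa.reduced_scale import run_reduced_scale_benchmark

r = run_reduced_scale_benchmark(seed=0, n_phantoms=20, epochs=40)
print({k: round(r[k], 3) for k in
       ("corr_cnn", "corr_linear", "snr_cnn", "snr_linear")})
```

prints

```
{'corr_cnn': 0.176, 'corr_linear': 0.008, 'snr_cnn': 16.463, 'snr_linear': 14.659}
```

— the trained interpolator beats the linear baseline in held-out
virtual-signal correlation and in reconstructed S/N.

The same pipeline is scriptable from the shell:

```
spiralpa geometry build --out geom.csv
spiralpa phantom eval --out eval.json
spiralpa simulate --phantom eval.json --geometry geom.csv --noise-snr 30 --seed 1 --out sig.h5
spiralpa reconstruct --signals sig.h5 --geometry geom.csv --voxel 0.5 --extent 8 --out vol.tif
spiralpa evaluate --volume vol.tif --phantom eval.json --report snr.json
spiralpa mip --volume vol.tif --plane xz --out mip.tif
```

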