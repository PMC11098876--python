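# Methods

## The problem

3D photoacoustic tomography with a hemispherical detector bowl gives the
widest angular aperture for imaging vessels running in arbitrary directions,
but practical bowls are sparse (hundreds of elements, not tens of
thousands), and universal back-projection (UBP) from a sparse aperture
produces curvilinear streak artifacts — each element back-projects its trace
onto spherical shells, and outside the absorbers those shells fail to cancel.
`spiralpa` implements the virtual-dense-array remedy: exploit the regularity
of the golden-ratio sensor lattice to define one-dimensional neighbour
chains, insert a virtual sensor between every pair of chain neighbours, fill
in the virtual signals by interpolating the chain's 2D signal pattern, and
reconstruct from the combined real + virtual aperture.

## Array geometry

Sensor *i* of a Fibonacci hemispherical lattice sits at

    x_i = r_i cos(2*pi*i/G),  y_i = r_i sin(2*pi*i/G),
    z_i = z1 + (i - 1) dz,    r_i = sqrt(R^2 - z_i^2),

with G = (1+sqrt(5))/2.  The modelled device has R = 60 mm and 512 channels;
nominal indices 7 and 20 carry no sensor (a water-handling hole) and indices
513 and 514 are appended instead.  The device's true `z1` and `dz` are not
public; the defaults place the 514 nominal depths uniformly on
z in [-0.99 R, -0.05 R], which preserves the lattice's defining property
(uniform z spacing) and leaves a central opening.  Both are configuration
fields, and every integer property of the chain decomposition (chain counts,
minimum lengths, virtual counts) is independent of them.

Because consecutive sensors advance in azimuth by the golden angle, sensors
whose indices differ by a Fibonacci number are spatial neighbours along a
spiral.  Direction 1/2/3 uses stride 34/21/13 (shortest to longest
neighbour distance).  The chains of one direction are the residue classes of
the sensor indices modulo the stride; for the device they contain 14-16
(stride 34), 23-25 (stride 21) and 38-40 (stride 13) sensors.  Each
direction's interpolator has a fixed input height, so all chains are
truncated to the direction's minimum length (14 / 23 / 38) by dropping the
outermost (highest-index) members; peripheral gaps are simply left without
virtual sensors.  One virtual sensor is placed per adjacent chain pair at
the half-ordinal point of a cubic spline through the chain coordinates
(not-a-knot, parameterized by member ordinal), then renormalized radially
onto the sphere — the spline midpoint falls marginally inside the chord and
the real sensors sit exactly on the bowl, so renormalization keeps the dense
aperture spherical (displacement < 1e-3 mm; whether the original device does
this is unknown and immaterial at that scale).  Virtual sensors of different
directions are deliberately not merged: the dense aperture is
512 + (34*13 + 21*22 + 13*37) = 512 + 1385 = 1897 elements.

## Forward model

All simulations use mm / s / Hz and water sound speed c = 1.5e6 mm/s (the
bowl is water-coupled; the exact value is a config parameter).  A uniform
sphere of radius `a` produces the classic N-wave

    p(t) = p0 (r - c t) / (2 r)  for |r - c t| <= a,  else 0,

sampled on the device's acquisition grid (60 MHz, 1792 samples, 1500-sample
offset from the laser shot; the toy array described below uses 20 MHz, 192
samples, 300-sample offset).  Cylinders are discretized as trains of spheres
of the cylinder diameter with axial step c/(2 fs) (i.e. a quarter wavelength
at Nyquist), each sphere's p0 scaled by 3L/(4 a n) so the absorbed volume is
conserved; halving the step changes the band-limited signal by < 1% RMS.
The accumulation kernel is a numba loop over (sensor, sphere) pairs touching
only each N-wave's compact support.

The detection elements are modelled as a zero-phase Gaussian amplitude
response centered at fc = 3.5 MHz with 90% fractional -6 dB bandwidth.  The
Gaussian's mirror image at -fc is subtracted, which forces an exact zero at
DC (a plain Gaussian would pass 3% of DC, which an element cannot see) while
moving the -6 dB points by < 0.1%.  Measurement noise is i.i.d. Gaussian per
sample with standard deviation set 30 dB below the band-limited peak
amplitude of a reference absorber — a 1.0 mm sphere with p0 = 100 at the
bowl center.  The reference absorber's size and the peak-vs-RMS convention
are not published; the 1.0 mm-sphere peak is this package's reading, and
both the diameter and the S/N are configurable.

## Patterns and the interpolator

Stacking the signals of one chain (innermost sensor first) forms a regular
2D pattern.  The interpolator input interleaves the arithmetic mean of
neighbouring rows between the real rows (linear interpolation serves only to
give the input the output's shape — 27/45/75 rows by 1792 samples for the
device); the target is the same interleave built from noise-free band-limited
signals simulated at both the real and virtual positions.  Inputs and
targets are divided by the reference amplitude so unit-scale activations
correspond to p0 ~ 100.

The interpolator is a stack of same-shape 2D convolutions (kernel 7 rows x
77 samples, 64 filters, 8 layers by default) with ReLU activations, an
additive skip connection every 2 layers, a linear single-filter regression
output layer, and an identity skip from input to output.  The output layer
is zero-initialized, so an untrained model is exactly the identity on its
input — training can only improve on the linear baseline it is fed.  The
layer count and skip period are not published ("multiple convolutional
layers" with skip connections); both are config fields.  Training minimizes
mean squared error with resilient backpropagation (iRprop-: per-parameter
step sizes starting at the learning rate 1e-5, multiplied by 1.2 / 0.5 on
gradient sign agreement / flip, clipped to [1e-9, 1]), 50 epochs, mini-batch
50/100/150 per direction.  The network and optimizer are implemented
directly in NumPy (im2col + BLAS convolutions with hand-written backward
passes); everything is float32 and bit-deterministic given the seed.

At measurement time each chain of each direction is extracted from the 512
measured traces, linearly interleaved, pushed through the direction's model,
and the odd (virtual) output rows are scattered into the dense signal set.
The real rows of the dense set are the original measured signals, not the
model output: the model's denoised real rows are slightly smoothed, which
biases reconstructed pressure low (a flag restores the model rows for
experimentation).

## Reconstruction and evaluation

The inverse filter multiplies the spectrum by LPF(f) / max(H(f), 1/gain_cap)
with gain_cap = 100 and a zero-phase Butterworth-magnitude low-pass of order
32 at 5 MHz (>= 50 dB suppression by 1.2x the cutoff; only the 5 MHz
cutoff itself is published, not the filter family).  UBP back-projects
b(t) = 2 p(t) - 2 t dp/dt (central differences; linear interpolation in
sample space) at the voxel-sensor time of flight, honoring the acquisition
offset; voxels outside the recorded window receive nothing.  Element solid
angles are not published, so the hemisphere's 2*pi is split uniformly across
elements (config-exposed weights).  Default grid: 0.1 mm voxels over
[-12, 12] mm^3 for fidelity runs, 0.4 mm for the CI-scale benchmark; the
device's reference reconstruction extent is unpublished.

Volume S/N follows the reference definition: 20 log10 of the mean
reconstructed intensity inside the absorbers over the standard deviation of
the background.  The background is the grid minus a 2 mm guard band around
every absorber surface (the guard is a design choice — a background region
is only defined for the proprietary palm measurements; sweeping the guard
from 1 to 4 mm moves the sparse-aperture S/N by about 0.6 dB).  The virtual-signal fidelity
metric is the Pearson correlation over all (virtual sensor, sample) pairs
between interpolated and ideal band-limited noise-free signals.

## The four-way benchmark

`run_snr_benchmark` simulates the fixed evaluation phantom — three
1.0 mm x 50 mm cylinders, p0 = 100, parallel to y at (0,-5,-5), (0,0,0),
(0,5,5) mm — and reports S/N for (a) noisy 512-channel, (b) ideal
512-channel, (c) noisy real + linear virtual (1897 channels), (d) ideal
1897-channel reconstructions, plus the linear-vs-ideal virtual correlation
averaged over five noise seeds.  The qualitative structure of the reference
results reproduces robustly: the strict ordering ideal-dense > linear-dense >
ideal-sparse and ideal-dense > noisy-sparse, a near-zero linear-interpolation
correlation (~0.04 vs reported 0.061), and an ideal-signal density gain of
+6.8 dB (reported +6.1).  The absolute S/N levels come out 2-5 dB below the
reported ones: the artifact floor relative to the absorber signal depends on
the unpublished z-spacing of the real bowl, the element weighting, and the
background-region convention, and the reconstructed electrical-noise
contribution is highly sensitive to the unpublished noise-reference
definition (with the 1.0 mm-sphere reference, noise is negligible against
artifacts, so conditions (a) and (b) nearly coincide).  These inputs were
fixed a priori as described above and are reported as computed.

## Reduced-scale interpolator benchmark

Full-scale training (1000 phantoms, 34k/21k/13k patterns, 50 epochs) is a
weeks-long GPU computation and is out of scope; the full-scale constants are
nevertheless the configuration defaults.  The desk-scale stand-in
(`spiralpa.reduced_scale`) runs the identical pipeline on a 40-sensor
hemisphere: R = 30 mm, spiral strides (13, 8, 5) — the Fibonacci triple
matching a 40-point lattice — 20 MHz sampling, 192 samples, offset 300
(covering absorbers within 5 mm of the center), sphere-only random phantoms
(1-4 spheres, 0.6-1.5 mm, p0 50-100), direction 3 (five chains of eight
sensors), a shrunken model (kernel 5x17, 8 filters, 4 layers), 20 phantoms
with 10% held out by phantom (not by pattern, to avoid cross-chain leakage),
initial Rprop step 1e-4, batch 30.  The benchmark reports held-out
virtual-row correlation and MSE for the trained model vs the linear
interleave, and the volume S/N of a fresh phantom reconstructed from the
same partial dense aperture (real + direction-3 virtual sensors) under both
interpolators, isolating interpolation quality.  With 15-40 epochs the
trained model beats the baseline on all three measures (e.g. held-out
correlation ~0.18 vs ~0.01 at 40 epochs).  This demonstrates the learning
mechanism, not the full-scale accuracy (reported full-scale: correlation
0.933, S/N within 1.1 dB of the ideal dense aperture): the toy model sees
two orders of magnitude less data, far fewer rows per chain, and a far
smaller model.

## What the synthetic data does not capture

Absorbers are ideal uniform spheres and straight cylinders with prescribed
p0 — no optical fluence modelling, no acoustic heterogeneity, refraction, or
frequency-dependent attenuation (the same assumptions UBP itself makes), no
element directivity, and no correlated electronics noise.  Passing the
benchmarks shows the geometry, interpolation, and reconstruction machinery
are correct under those assumptions; it does not certify performance on
measured palm data, whose vessels meander (the reported palm results note the
straight-cylinder training prior straightens reconstructed vessels).

## Numerical choices and degenerate inputs

- Chains shorter than 3 members cannot host a cubic spline and raise an
  error naming the chain; arrays whose configured depths leave the
  hemisphere are rejected at construction.
- Sensors inside an absorber are rejected before simulation.
- A cylinder shorter than one axial step degenerates to a single
  volume-scaled sphere.
- The divergence guard aborts training on a non-finite loss; inference
  checks for non-finite outputs.
- The brute-force per-voxel UBP loop in the test suite is the oracle for the
  numba kernel (agreement to < 1e-9); both use identical operation order.
- Geometry CSV export writes shortest-round-trip float representations, so
  export/import is bit-exact.
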