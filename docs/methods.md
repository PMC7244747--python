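# Methods

`paxel` reconstructs 2D photoacoustic tomography (PAT) images from
limited-view, sparsely sampled sensor data.  This note records the models the
package implements, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical choices that matter.

## Physical model and forward operator

The initial pressure `x(r) = Γ(r) A(r)` (optical absorption times the
Grüneisen coefficient) launches an acoustic wave governed by the lossless
homogeneous wave equation

    (∂_tt − c0² Δ) p(r, t) = 0,    p(r, 0) = x,    ∂_t p(r, 0) = 0.

Point sensors on the measurement surface record `y = A x`, the field sampled
at their grid nodes over a finite window.

The solver (`paxel.simulate`) is Fourier pseudospectral: spatial derivatives
are exact in k-space and the two-step recurrence
`p^{n+1} = 2 cos(c0 |k| dt) p^n − p^{n−1}` is the exact propagator of the
semi-discrete system for a homogeneous medium, so the scheme is not bound by
the usual CFL accuracy limit.  Free space is emulated by padding the grid with
an 18-pixel absorbing sponge whose per-step damping ramps quartically from 1
to `exp(−1.2)` at the outer edge.  A sponge reflects more long-wavelength
energy than a true perfectly matched layer; the residual is visible as a
sub-percent energy tail and is the main reason full-view time reversal
saturates around 30–35 dB rather than climbing indefinitely.

Defaults follow the simulated acquisition geometry used throughout the
experiments: `c0 = 1500 m/s`, density `1000 kg/m³`, a 128×128 grid, and
sensors equally spaced on a semi-circle of 120 px diameter (16/32/64 sensors;
a closed ring is available for full-view checks).  The paper-style geometry is
given entirely in pixels; we fix `dx = 1e-4 m` so the 128-px grid spans
12.8 mm, a realistic small-animal field of view.  Time stepping uses CFL 0.3
(`dt = 0.3 dx / c0 = 20 ns`) and `n_steps = ceil(1.2 × grid diagonal / (c0 dt))`
so every pixel's wavefront crosses every sensor within the recording.

Because each elementary step (k-space multiplier, diagonal damping mask,
sensor sampling) is linear with a known transpose, the adjoint `A'` is the
transposed recurrence run backwards.  It is exact to rounding error: the
dot-product identity `⟨Ax, y⟩ = ⟨x, A'y⟩` holds at ~1e-16 relative, far inside
the 1e-5 the iterative solver needs.

Time reversal imposes the recorded series, last sample first, as a Dirichlet
condition on the sensor nodes while the model runs; the field left when the
reversed recording ends is the image (clipped to ≥ 0, min-max normalized).

Not modeled, deliberately: acoustic heterogeneity, attenuation and dispersion,
3D propagation, sensor apertures/directivity, and measurement noise.

## Pixel-wise interpolation

Under the homogeneous linear model the travel time from pixel to sensor is
`tof = ‖pixel − sensor‖ · dx / c0`.  Pixel-wise interpolation reads each
sensor's series at that per-pixel delay, giving an H×W×N volume whose channel
i is sensor i's data mapped into image space.  Choices:

- Interpolation in time is linear (nearest and cubic are available behind a
  flag); linear is the standard beamforming choice and what the vectorized
  implementation is tested bit-for-bit against a per-pixel loop oracle.
- Times of flight outside the recording window zero-fill rather than clamp,
  so late-time samples are not smeared across distant pixels.
- Pixel centers are integer (row, col) coordinates, 0-based; sensors are
  snapped to grid nodes, so a pixel on a sensor node has exactly zero delay.
- The volume is passed to the network unnormalized: a global scale is a units
  choice, but per-channel normalization would destroy the relative amplitude
  cues between sensors.

The mean over the sensor axis is classical delay-and-sum beamforming; it is
exposed as a diagnostic and focuses a simulated point source to within 1 px.

For the direct-reconstruction baseline the raw N×T sinogram is resampled to
image size: the long time axis is block-averaged (anti-aliasing) then linearly
interpolated, the sensor axis linearly interpolated up.

## TV-regularized iterative reconstruction

`x = argmin ‖y − Ax‖² + λ |x|_TV` with isotropic TV (forward differences,
replicate boundary).  The solver is monotone FISTA: step `1/(2L)` with `L`
the top eigenvalue of `A'A` from 10 power iterations (cached per geometry,
inflated 5% against underestimation); the TV proximal step is fast gradient
projection on the dual (20 inner iterations by default) with an optional
nonnegativity constraint, on by default since initial pressure is physical.
On an objective increase the momentum restarts from the last accepted
iterate, so the recorded objective is non-increasing; a plain (non-accelerated)
dual ascent run long serves as the independent reference for the prox point
(agreement to 1e-6 on random inputs, in practice ~1e-13).

λ is exposed as a fraction of `‖A'y‖_∞` (scale-free across geometries); the
default 1e-2 was chosen on noise-free desk simulations, and a PSNR-scored grid
search helper exists for simulation studies where the truth is known.
Initialization is all-zeros; a time-reversal warm start is available.

## Synthetic vasculature phantoms

The generator draws seeded random vessel trees on a 340×340 canvas: walkers
start at border points heading inward, advance one pixel at a time with
Gaussian heading noise (momentum), branch with a small per-step probability
into narrower children, and stamp anti-aliased strokes of width 1–6 px.
Morphology knobs (walker count, width range, turning noise, branch rate) let
experiments build visually distinct phantom families.

Training/testing images are cut by the augmentation recipe: per layer, a
random scale in (0.5, 2) and rotation in (0, 359°), a random 128×128 crop
(zero-padded when the transformed image is smaller), and a random 0–10 px
shift via zero-padding; one to five layers (uniform) are summed, then the
result is min-max normalized once (not per layer).  Constant images normalize
to zeros — a structureless phantom carries no signal — and crops that land on
empty background are redrawn, since an all-zero truth makes fidelity metrics
degenerate.  Train and test use disjoint seed streams, recorded per image.

An optional loader path emulates anatomical pipelines for user-supplied 3D
volumes: a seeded random 128³ sub-volume, the multiscale Frangi vesselness
filter (σ ∈ {1, 2, 3, 4} px, standard β defaults), and a maximum-intensity
projection along a configurable axis.  The filter runs on the extracted
sub-volume rather than the full volume — equivalent up to boundary effects
and far cheaper.

What the generator does not emulate: real vessel connectivity statistics,
intensity heterogeneity from optical fluence, noise, or any anatomy-specific
morphology.  Passing tests therefore demonstrate the *relative* behavior of
the reconstruction methods under these idealized conditions, not absolute
performance on real data.

## FD-UNet and the three learned pipelines

The network is a U-Net with densely connected blocks in both paths: inside a
block each 3×3 convolution sees the concatenation of the block input and all
previous layer outputs (growth rate k, doubling per level from k1), followed
by a 1×1 compression (f1 at the top level, doubling per level); 2×2 max-pool
down, 2×2 stride-2 transposed convolution up, skip concatenation between
matching levels, batch-norm + ReLU ordering, and a plain stem convolution so
the first BN–ReLU never acts on the raw bipolar input.  Reference-scale
hyperparameters are k1 = 16, f1 = 128, 4 levels of 4 dense layers (~51M
parameters).

Three pipelines share the architecture and differ only in input:

- **Post-DL**: the time-reversal image (1 channel), trained with residual
  learning (network output added to the input); the residual identity is exact
  when the network is zeroed.
- **Pixel-DL**: the H×W×N pixel-interpolated volume (N channels).
- **mDirect-DL**: the resampled sinogram (1 channel).

Training follows the standard protocol at full scale (Adam, MSE, learning
rate 1e-4, batch 3, 40 epochs); everything is seeded and deterministic,
including shuffling.  Because no GPU deep-learning framework is assumed, the
network runs on the package's own numpy reverse-mode autodiff engine
(`paxel.nn`), gradient-checked against finite differences.

### Desk-scale study conditions

Full-scale training is a GPU workload; the package's experiments and tests
use a first-class desk preset chosen once and documented here:

- grids of 32–64 px, 16-sensor semicircle (the sparsest, hardest paper
  geometry), 120–200 training images, 20 held-out images;
- a k1 = 8, f1 = 32 network with 2 levels of 2 dense layers (3 levels for the
  sinogram-to-image task, whose mapping is global and needs the deeper
  pyramid's receptive field);
- Adam at learning rate 3e-3 (the larger rate compensates for the tiny
  network), batch 3, 10 epochs, seeds {0, 1, 2} for the ordering comparison.

Under these conditions the package reproduces the qualitative orderings:
median held-out mean PSNR ranks Pixel-DL > Post-DL > time reversal, iterative
TV beats time reversal, and time reversal improves monotonically with sensor
count.  Margins are a fraction of a dB to a few dB — far smaller than the
4–8 dB gaps reported at full scale — so they are treated as orderings, not
effect sizes.

The generalization experiment trains Pixel-DL and mDirect-DL on a regular
phantom family (few thick, straight vessels — easy enough that the direct
network visibly fits it within the desk budget; it gets two ten-epoch rounds,
consistent with its harder task converging more slowly) and tests on the
default curvier family.  The held-out-family PSNR drop is larger for
mDirect-DL than for Pixel-DL even though, by the time-reversal yardstick, the
out-of-family set is intrinsically *easier*: the direct network's learned
sinogram-to-image mapping is family-specific, while the TOF-aligned input
transfers.  One desk-scale caveat recorded honestly: at this budget mDirect-DL
does not beat time reversal even in-distribution (at full scale it does on the
training family); the asymmetry of the drops, not the absolute level, is the
reproduced phenomenon.

## Metrics

PSNR uses a fixed peak of 1.0 (data are [0,1]-normalized), so values are
comparable across images; identical images flag +inf and are excluded from
averages with a warning.  SSIM uses the canonical 11×11 Gaussian window
(σ = 1.5), K1 = 0.01, K2 = 0.03, data range 1.0, population covariances
(scikit-image's implementation; an independent windowed-formula oracle backs
it in the tests).  Summary tables report mean ± std per (method, sensor
count) cell with the cell sample size.

## Known limitations

- The sponge boundary is not a true PML; long-wavelength reflections cap
  full-view time-reversal fidelity (~30–35 dB on smooth phantoms).
- Dirichlet-enforced time reversal is the standard approximate inverse, not
  an exact one; recording windows much longer than the traversal time slowly
  degrade it as sensor nodes act as scatterers.
- The TOF model assumes a homogeneous medium; heterogeneous speed of sound
  would need a different travel-time model and is out of scope.
- Desk-scale CNN results are orderings under the stated conditions; absolute
  PSNR/SSIM values at this scale say nothing about full-scale performance.
- The vectorized SSIM/PSNR, wave solver and TV prox are float64; network
  training is float32 and bit-reproducible only for a fixed seed, data order
  and BLAS configuration.
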