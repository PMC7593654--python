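# Methods

## Acoustic forward model

The initial-value problem for the pressure field in a homogeneous,
non-absorbing medium,

    p_tt = c² Δp,   p(x, 0) = f(x),   p_t(x, 0) = 0,

has the exact spectral solution `p̂(k, t) = f̂(k) cos(c|k|t)`.  The
package evaluates it on a periodic FFT grid; this is exact for the
band-limited interpolant of the discrete image, with no time-stepping
error at any `dt`, so the discrete forward operator is known to machine
precision.  The measurement operator samples the field at point
detectors on every node of the image's top row (optionally strided) at
times `t_k = k·dt`.

Defaults are dimensionless: `dx = c = 1`, `dt = 0.3`, and
`n_t = ceil(2√2·m / (c·dt))` so the record covers the full diagonal
transit.  With `dt = 0.3` the temporal sampling rate exceeds the spatial
Nyquist rate (`π/dt > c·|k|_max = √2·π/dx`), so no information is lost
to time sampling.

**Padding.**  The FFT grid is periodic, so out-going waves re-enter as
ghost images of the source.  The propagation grid is the image padded to
`pad_factor · m` per side (default 4): with the default record length
`c·T = 2√2·m ≈ 2.83 m`, the nearest periodic ghost lies `3m` away and
cannot reach a detector within the record.  A pad of 2 is admissible but
leaves late-time ghost contamination for long records.  Note that
pad-invariance holds at roundoff level only for sources that are smooth
*and* compactly supported inside the window; images with sharp content
at the window boundary acquire band-limitation ringing that differs
between grid sizes.

**Matrix form.**  Because the propagator is translation invariant, each
time sample of the forward map is a circulant convolution; the dense
matrix A (shape `(n_det·n_t) × m²`) is assembled from one FFT kernel per
time step rather than one propagation per pixel, and each column agrees
with the propagator applied to the corresponding unit image at the
10⁻¹²-relative level checked in the tests.  The adjoint is the
transpose.  Assembly refuses to allocate beyond a configurable memory
budget (default 4 GiB), using the same arithmetic as the dense-layer
memory estimator.  Storage is float64 for the oracle-grade path and
float32 for training workloads.

**Noise.**  Measurement noise is i.i.d. zero-mean Gaussian with standard
deviation `relative_std · max|g|` (default 1%), seeded per dataset item;
it is applied to training and, by default, test data (flag-controlled).

## Classical inversions

* **Delay-and-sum** backprojects each detector sample onto its
  arrival-time circle with linear interpolation in time; no filtering,
  so amplitudes are qualitative.
* **2D universal backprojection** implements the exact
  filtered-backprojection integral: the time derivative of `g/t`
  weighted by `1/√(t² − t₀²)`, backprojected with weight
  `κ·cos α = depth`.  The quadrature starts one time sample above the
  integrable `1/√` singularity (trapezoid weights).  The closed-form
  solid-angle prefactor applies to closed measurement curves only; for
  the open line the package calibrates a single global constant per
  geometry by a least-squares amplitude fit against a simulated disc
  phantom, computed once and cached.
* **Fourier-domain (k-space) reconstruction** for the uniform line:
  cosine transform in time, FFT along the (zero-padded, default 2×)
  detector line, and the algebraic map `ω → k_z` through the dispersion
  relation with Jacobian `B = k_z/ω`.  Two numerical points matter:
  the scaling is applied *before* the interpolation in ω, because the
  scaled spectrum is smooth across the dispersion-cone edge where the
  raw spectrum has an integrable singularity; and the `k_z = 0` bin,
  which sits exactly on the cone edge, is filled by even-quadratic
  extrapolation from its neighbours (it carries the image's depth
  baseline).  A one-sided line cannot separate a source from its mirror
  image, so the output is the even-in-depth part cropped to depth ≥ 0.
* **Time reversal** re-emits the record in reversed order as a
  time-varying Dirichlet condition at the detector nodes, using leapfrog
  stepping with a spectral Laplacian (stability requires
  `c·dt/dx ≤ 2/(π√2) ≈ 0.45`; the default 0.3 satisfies it) and an
  exponential damping layer (width `max(m/8, 4)`, quadratic ramp) on the
  three non-detector edges of the padded grid to emulate absorption.
  The iterative variant applies `f ← f − TR(A f − g)`.
* **Variational schemes** run on the dense matrix: Landweber gradient
  descent with default step `η = 1/σ_max(A)²` (power-iteration
  estimate; guarantees monotone misfit decrease), proximal-gradient with
  a non-negativity clip or an isotropic-TV proximal map realized by a
  fixed number (default 20) of dual projection iterations, and the
  closed-form Tikhonov solution via a symmetric positive-definite solve
  whose normal-equation residual is verified at 10⁻⁸ relative.
* **Null-space projector**: a rank-revealing SVD (rank tolerance
  `10⁻¹⁰·σ_max`) yields the orthogonal projector onto null(A), so a
  learned correction `f₀ + P v` provably preserves `A f₀`.  Dense, and
  restricted to `m ≤ 32`.

### Accuracy of the line-geometry inversions

The one-sided finite aperture bounds what the analytic formulas can do.
The long default record makes the *matrix* problem nearly determined
(at m = 32 the rank is 1015 of 1024 and Tikhonov at α = 10⁻⁶ reaches
7% relative error on a central smooth phantom), but the Fourier formula
is derived for an infinite line: components travelling nearly parallel
to the detector (|k_z| ≲ |k₁|) are only partially recovered under
aperture truncation, independent of record length.  On the canonical
central smooth phantom the measured round-trip error is ≈ 0.6 relative
L2 (frozen in the tests at 0.70), with time reversal and the variational
solvers progressively better.  These frozen reference values are
regression bands for this geometry, not general claims about k-space
methods.

## Learned reconstruction

All networks run on the package's own reverse-mode autodiff engine
(`patrecon.nn`: dense, 3×3 same-convolution, 2×2 max-pool, 2×2
transposed convolution, ReLU/ELU, Adam).  Arrays default to float64 so
the degenerate-network equivalences hold at the 10⁻¹⁰ level; training
workloads switch to float32, the conventional precision for network
optimization.  Every gradient is verified against central finite
differences in the test suite.

* **Fully learned** — dense widths default to `m²` per hidden layer
  (bounded memory at desk scale; the last width must be `m²` for the
  reshape); inputs are normalized per sample by `max|g|`.  The CNN tail
  is 3 layers × 32 channels with a final 1-channel ReLU layer enforcing
  `f ≥ 0`.  An L1 penalty on the parameters (default 10⁻⁶) counters the
  overfitting this architecture is prone to.
* **Post-processing** — residual U-Net with 3 scales, 2 convolutions
  per scale, channels 32/64/128 (conventional doubling), max-pool down,
  transposed-convolution up, concatenating skips.  The final convolution
  is zero-initialized, making the untrained network exactly the identity
  on its initializer (default: the adjoint image `Aᵀg`).
* **Learned gradient scheme** — N unrolled blocks (default 5; the
  benchmark uses 2), each a residual CNN (3×32-channel ReLU convolutions
  with bias, then a linear 1-channel convolution without bias,
  zero-initialized) acting on the two-channel input
  `(f_n, s·Aᵀ(A f_n − g))`.  The gradient channel is rescaled by
  `s = 1/σ_max(A)²` to normalize its magnitude across geometries
  (`grad_scale` can be fixed to 1 to recover the raw formulation).
  `set_fixed_step(η)` configures every block to the degenerate update
  `(f, d) ↦ −η·d` exactly — the scheme whose only parameter is a step
  length — which must and does reproduce classical gradient descent to
  10⁻¹⁰; this is the module's central correctness oracle.

**Training** uses mean-squared-error loss with Adam (learning rate
10⁻⁴, batch size 4, shuffled per epoch with a derived seed), a 10%
validation split monitored every 100 iterations, and no early stopping.
End-to-end unrolled training backpropagates through all forward/adjoint
products.  Greedy training fits block n against the ground truth with
the prefix frozen; because the block's inputs depend only on the frozen
prefix they are precomputed once per block (the on-the-fly path is kept
and tested as a cross-check).  Transfer updates resume from a checkpoint
at 1/10 the learning rate, optionally freezing all but chosen layers.
Checkpoints carry config, seeds, and dataset manifest, and identical
seeds reproduce runs bitwise on one machine.

## Synthetic phantoms

Real PAT training sets are built by segmenting vasculature from other
modalities, which yields priors with either piecewise-constant or smooth
features.  The generator emulates both with seeded random branching
vessel trees: 3–7 trees per image, branch widths 1.5–5 px, piecewise
intensities drawn from {0.4, 0.7, 1.0}, rasterized by maximum
composition (so the piecewise family takes at most 4 distinct values);
the smooth family is the identical draw convolved with a Gaussian of 2 px
and renormalized to peak 1.  These defaults were chosen once to give a
mean support fraction of ≈ 15% at m = 64 (regression band 2–40%) and a
clear total-variation separation between the families.  Per-image seeds
are hashes of (base seed, index), so datasets are order-independent and
regenerable from their manifest.

What the generator does *not* emulate: anatomically realistic branching
statistics, contrast calibrated to tissue optics, background absorption,
heterogeneous sound speed, or detector bandwidth.  Passing benchmarks
here demonstrates the relative behaviour of reconstruction approaches
under controlled priors, not in-vivo performance.

## The prior-shift benchmark

Three scenarios: (i) *consistent* — train and test on the piecewise
family; (ii) *shifted* — train on piecewise, test on smooth;
(iii) *combined* — train and test on an even mixture.  Train and test
manifests always use distinct base seeds (enforced), and metrics are
mean ± std over the test set.  SSIM uses a Gaussian window (11 taps,
σ = 1.5), stabilizers K₁ = 0.01, K₂ = 0.03, data range `max(gt)`;
PSNR uses range `max(gt)` and caps at 200 dB for identical images.
Both implementations are cross-checked against scikit-image at 10⁻⁶.

The desk preset runs m = 32, 140 training / 30 test pairs, 500 Adam
iterations, batch 4, and 2 unrolled iterations for the learned gradient
scheme — sizes chosen to make the full two-scenario benchmark a
~10-minute single-CPU run while keeping each network in the regime where
its training loss has visibly plateaued.  The full published protocol
(thousands of samples, 5×10⁴ iterations, 5 unrolled iterations) is
available as configuration but is orders of magnitude more expensive;
absolute desk-scale scores are far below full-scale ones, so only the
*directional* statements (model-based ≥ fully learned under a consistent
prior; degradation under prior shift) are asserted, each with a
one-pooled-standard-error tolerance because training is stochastic.

## Known limitations

* Homogeneous sound speed only; no acoustic absorption; point detectors
  with no directivity or bandwidth model.
* The k-space line reconstruction inherits the finite-aperture
  limitations discussed above.
* The dense-matrix route is quadratic in problem size; m ≳ 128 with the
  default record exceeds a desktop's memory, which is precisely the
  regime argument the memory estimator quantifies.
* The autodiff engine is single-threaded numpy; it is sized for the
  desk-scale benchmark, not for production training.
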