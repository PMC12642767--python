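# Methods

## The imaging model

Magnetic particle imaging (MPI) detects superparamagnetic iron oxide
nanoparticles through their nonlinear magnetization response.  In a
field-free-line (FFL) scanner a static gradient field `-G x` with

    G = diag(-G0, 0, G0)

nulls the field on a line parallel to the y-axis.  A sinusoidal drive
field at `f0` (here 45 kHz) sweeps the FFL rapidly across the (x, z)
plane while a slow zig-zag raster (fast triangular sweep along x, slow
linear ramp along z) covers the field of view.  All fields are stored
as `mu0*H` in tesla.

The tracer ensemble responds with the equilibrium Langevin
magnetization

    M(x, t) = m rho(x) L(beta |H|) H / |H|,      L(a) = coth a - 1/a,

with one particle moment `m` (A m^2) and saturation constant `beta`
(1/T); relaxation and interparticle interactions are deliberately
omitted, so the tracer is described by exactly two parameters.  A
receive coil with sensitivity `b(x)` measures
`s0(t) = d/dt \int b . M dx`, which after evaluating the time
derivative analytically becomes a sum over a 3x3 point-spread tensor
`h(u) = J(G u) G` contracted with the FFL velocity, where `J(w)` is the
Jacobian of `L(beta|w|) w/|w|`:

    J(w) = (L(a)/|w|) (I - ww^T/|w|^2) + beta L'(a) ww^T/|w|^2,  a = beta|w|.

The package does not take this closed form on trust: a test
differentiates the Langevin magnetization of a point source numerically
in time and requires the kernel chain to reproduce it to 1e-4 relative
L2 (observed ~1e-5).

A hardware notch filter `Gamma` removes the fundamental before
digitization.  The discrete model factors into composable linear
operators on the voxel grid,

    s = Gamma V E H B rho,

where `B` applies the receive sensitivity, `H` convolves with the
sampled PSF kernels (FFT-based, zero-padded, kernels scaled by the
voxel area so the discrete model is the Riemann sum of the integral),
`E` samples the convolved images along the FFL trajectory with bilinear
weights, and `V` contracts with the trajectory velocity.  Every
operator carries an exact adjoint and is linear over the complex field;
randomized dot tests gate all of them at 1e-8 (observed at machine
precision).

## Harmonic compression

MPI signal energy concentrates in narrow bands around harmonics of the
drive frequency.  With `F` the DFT and `S` a band selector keeping
0.5 kHz of total bandwidth around harmonics 2..5 (the fundamental is
already notched), the compressed model is

    A_DC = S D_Gamma F V E H B,

where `D_Gamma` is the receive transfer function as a spectral diagonal
— algebraically identical to `S F Gamma V E H B` but needing a single
FFT.  Both forms are implemented and agree to ~1e-15; the band-limited
data vector is what the solver sees.  The "0.5 kHz" is interpreted as
total band width (bin kept iff `|f - k f0| <= 250 Hz`), exposed as a
config knob; bands are taken from positive frequencies of a real
signal's spectrum, with the conjugate mirrors counted in energy
accounting.

## Tomographic coupling

Rotating the scanner about z by theta is modeled as rotating the
density the opposite way: each angle contributes the parallel-beam
projection `rho_theta(x', z) = \int rho((x', y) Q^T, z) dy` with
`Q = [[c, s], [-s, c]]`, followed by the (angle-independent) 2D model.
The projector discretizes the line integral as a Riemann sum with step
half the in-plane voxel spacing and bilinear weights.  Because a
rotated sampling lattice does not exactly tile the bilinear basis, the
raw sum conserves mass only to ~1e-4; the projector therefore
normalizes each adequately covered voxel's weight column to exactly its
y-extent.  Axis-aligned projections are already exact and unaffected;
at 37 degrees the projector agrees with a dense rotate-and-sum oracle
to ~5e-4 relative L2.  Voxels covered below 20% of full (corners
outside the rotated footprint) are left unnormalized, so conservation
is guaranteed only for densities supported on the covered region — all
phantoms here live inside the inscribed cylinder, which is also what
the physical geometry images correctly.

Each angle carries two collinear scans (x-axis and z-axis drive); the
full operator `A` stacks `A_DC P_theta` blocks for all angles and
axes, assuming one shared scan sequence.

## Reconstruction

The image solves `min_x ||A x - b||^2 + lambda ||T x||^2` with `T`
first-order forward differences (zero at the far boundary).  The
solver is fixed-step gradient descent with heavy-ball-like
acceleration,

    y_{k+1} = x_k + (k-1)/(k+2) (x_k - x_{k-1})
    x_{k+1} = y_{k+1} - tau [A^H(A y_{k+1} - b) + lambda T^T T y_{k+1}],

with `tau = (||A^H A|| (1 + 0.05) + lambda ||T^T T||)^-1`.  `||A^H A||`
comes from seeded power iteration (Rayleigh quotient, which cannot
overestimate; the 5% safety factor covers underestimation), and
`||T^T T||` uses the analytic bound `4 * ndim`.  After each update the
iterate is projected to a real nonnegative image (the physical
constraint on a density); iterates are stored complex during the
iteration because the adjoint of complex band data is complex.  The
projection is applied to `x_{k+1}`, not to the extrapolated point.
A fixed iteration count (default 150) is the stopping rule; an optional
relative-change early stop exists but is off by default.

Numerical choices:

* `lambda` can be given as an absolute weight or (default in the CLI)
  as a dimensionless fraction converted to
  `lambda * ||A^H A|| / ||T^T T||` at solve time — the operator's
  physical scale varies by many orders of magnitude with the particle
  moment and voxel size, so a relative default stays meaningful.  The
  default 0.01 makes the smoothness prior contribute ~1% of the
  data-term curvature: enough to damp noise amplification in weakly
  sensed directions on smooth objects without dominating the fit.  At
  the fixed 150-iteration budget the residual stays above the injected
  noise power for every lambda (convergence error dominates), so the
  discrepancy principle offers no interior optimum here, and any
  lambda > 0 measurably biases point-source amplitudes at this budget;
  quantitative point-source analyses therefore run at lambda = 0.
* Initialization: either zero or a Cauchy-scaled backprojection
  `x0 = alpha A^H b` with the optimal scalar
  `alpha = <A A^H b, b> / ||A A^H b||^2`.  The warm start costs two
  operator applications and removes the many early iterations a
  zero start spends recovering the overall amplitude scale; the
  iteration itself is unchanged.
* The Langevin function switches to its Taylor series for |a| < 1e-3,
  where the closed form loses ~7 digits to cancellation; the switch is
  continuous to ~1e-15.
* Trajectory samples outside the grid contribute zero signal (and
  receive zero splat in the adjoint) rather than being clamped, keeping
  the adjoint pair exact; scans are configured so the raster stays
  inside the field of view.

## The simulator and what it does (not) emulate

The simulator reuses the forward operators: per (angle, drive axis) it
computes the unfiltered time-domain signal of a voxelized phantom, adds
white Gaussian noise at a prescribed power SNR in the time domain
(receive-coil noise enters before the filter chain), then notch-filters
and compresses exactly as measured data would be.  With noise off the
compressed data is bitwise identical to applying the block operator.
Phantoms (point sources, cylinders emulating 167 uL sample tubes,
ellipsoids, balls) are voxelized with supersampled partial-volume
boundaries; amplitude-carrying features are normalized so the voxel sum
equals the requested mass exactly.

Because simulation and reconstruction share the same discrete physics,
passing end-to-end tests demonstrates correctness of the inversion
machinery, conditioning, and the compression step — not robustness to
model mismatch.  Real acquisitions add relaxation-induced blur and
phase lag, harmonic background from the scanner, coil-sensitivity
inhomogeneity, drift, and non-Gaussian interference, none of which are
emulated; detection limits measured on simulated data therefore
characterize the *procedure*, not any physical scanner.

## Desk-scale study configuration

Scanner constants mirror a preclinical FFL system: 5.7 T/m gradient,
5 mT drive at 45 kHz, 500 kHz sampling (Nyquist-safe for harmonic 5),
1 kHz notch half-width, homogeneous unit receive sensitivity along the
drive axis.  The default volume is 24^3 voxels at 1.25 mm with 12
equally spaced angles over 180 degrees and a six-line zig-zag raster.
Voxels outside the footprint common to all projection angles (the cube
corners, outside the scanned FOV) are excluded from the reconstruction
support; without this the solver parks unconstrained mass there.

The tracer and raster-period defaults were derived jointly from two
competing constraints that the pipeline's fixed constants impose.
First, the tracer's point spread (FWHM ~ 4.14/(beta G0)) controls the
conditioning of the deconvolution: with a ~3 mm spread (2.4 voxels) the
operator's effective condition number is ~2000 and the fixed
150-iteration budget cannot recover point-source amplitudes over a
1:50 dynamic range; a sub-millimetre spread brings the condition
number to ~240, where 150 iterations quantify amplitudes to ~10%.
Second, harmonic compression keeps only +-250 Hz around each harmonic,
so the signal envelope — whose timescale is the raster crossing time
of the point spread — must vary on >~2 ms scales, which favors a
*slower* raster the sharper the spread is.  The defaults sit where
both are satisfied: a multicore tracer with a ~30 nm equivalent
magnetite core (`m = 5.3e-18 A m^2`, `beta = m/(kB * 300K) = 1280 /T`,
0.57 mm FWHM) and six raster lines of 107 ms (~0.64 s per scan, 321k
samples), at which the bands retain ~99% of the filtered energy.  The
line count trades off two resolutions at fixed scan duration: fewer,
slower lines narrow the envelope sidebands (better compression
fidelity), while the slow-axis line spacing (z-pitch 5 mm at six
lines) must stay within reach of the drive excursion plus point
spread or the z-axis aliases (at four lines / 7.5 mm pitch a bright
source mislocalizes by a voxel).  Faster desk rasters (10-20 ms
lines) push envelope sidebands out of the bands and would fail
compression by construction rather than measuring the method; the
slow raster mirrors the seconds-long rasters of physical scanners.

The continuum-oracle fixture (16x16 grid) instead uses the hardware's
15 mT drive option and a softer tracer (beta = 100/T): at 5 mT the FFL
drive excursion (0.877 mm) is sub-voxel on any 16-cell grid spanning a
realistic FOV, and bilinear trajectory sampling then under-resolves the
harmonic-generating motion.  At 15 mT the excursion spans ~2.6 cells
and the pipeline matches the continuum to ~1.6% relative L2 (the
comparison runs the brute-force magnetization sum at 10x temporal
oversampling for its numeric derivative).

## Known limitations

* Equilibrium Langevin response only — no Neel/Brownian relaxation, no
  interparticle interaction, no eddy-current or coil-coupling effects.
* Homogeneous receive sensitivity by default; measured sensitivity maps
  and transfer functions can be supplied but none ship with the package.
* The projector's mass normalization presumes objects inside the
  inscribed cylinder of the (x, y) field of view.
* Single-channel receive, identical notch configuration for both drive
  axes, fan/cone geometries out of scope.
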