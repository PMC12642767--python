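# fflmpi — model-based 3D field-free-line MPI reconstruction

Magnetic particle imaging (MPI) maps superparamagnetic iron oxide
nanoparticles — tracers used for cell tracking, lymph-node mapping and
therapy monitoring — by driving them with an oscillating magnetic field
and detecting the harmonics of their nonlinear Langevin response.  On
field-free-line (FFL) scanners, 3D images are conventionally assembled
by reconstructing each 2D projection independently and then running a
CT step, which discards per-scan information and leaves haze around
bright organs.  `fflmpi` implements the alternative: one joint,
physics-based inverse problem over all projection angles at once.

The forward model factors into efficient linear operators

    s = Γ V E H B ρ            (one 2D FFL scan)

where `B` applies the receive-coil sensitivity, `H` convolves the
density ρ with the Langevin point-spread tensor
`h(u) = J(G u) G` (with `J` the Jacobian of `L(β|w|) w/|w|` and
`L(a) = coth a − 1/a`), `E` samples along the FFL trajectory, `V`
contracts with the trajectory velocity, and `Γ` is the receive-chain
notch filter.  Because MPI signal energy concentrates around harmonics
of the 45 kHz drive, the data is compressed to narrow Fourier bands
(harmonics 2–5, 0.5 kHz each) with a selector `S`, giving the
single-FFT compressed operator `A_DC = S D_Γ F V E H B`.  Multi-angle
data couples through parallel-beam projectors `P_θ`:

    A = blockdiag(A_DC, …, A_DC) · [P_θ1; …; P_θM],

and the volume solves the Tikhonov problem

    min_x ‖A x − b‖² + λ‖T x‖²

by heavy-ball accelerated projected gradient descent
(`y_{k+1} = x_k + (k−1)/(k+2)(x_k − x_{k−1})`, fixed step
`τ = (‖AᴴA‖(1+0.05) + λ‖TᵀT‖)⁻¹`, real/nonnegative projection each
iteration).  Every operator has an exact adjoint verified by randomized
dot tests, and a scan simulator built from the same physics makes the
whole pipeline testable without scanner hardware.  See
`docs/methods.md` for the model, parameter choices, and limitations.

## Worked example

Simulate a desk-scale acquisition of two nanoparticle samples and
reconstruct it:

```python
import numpy as np
from fflmpi import (AngleSet, ForwardModel3D, PhantomSpec, ReconConfig,
                    ReconstructionModel, build_projection_model,
                    make_phantom, simulate_scan)
from fflmpi.defaults import (default_particle, default_scanner,
                             default_volume_grid)

grid = default_volume_grid()                 # 24^3 voxels, 1.25 mm
phantom = PhantomSpec(
    "tubes",
    positions=((-5e-3, 0.0, -4e-3), (5e-3, 2e-3, 4e-3)),
    amplitudes=(10.0, 2.0),                  # ug Fe per sample
    sizes=((3e-3, 5e-3), (3e-3, 5e-3)), axis="y")
rho = make_phantom(phantom, grid)

models = [build_projection_model(grid.plane_xz(), default_scanner(ax),
                                 default_particle()) for ax in ("x", "z")]
fm = ForwardModel3D(grid, AngleSet.equally_spaced(12), models)
data = simulate_scan(rho, fm, noise_snr_db=30.0, seed=1)

cfg = ReconConfig(lam=0.0, iterations=150, seed=0, power_iterations=15)
results = ReconstructionModel(fm, data.data_vector(), grid, cfg).fit()
print(results.summary())
left, right = results.volume[:12].sum(), results.volume[12:].sum()
print("recovered masses (left/right half):",
      round(float(left), 2), round(float(right), 2))
```

```
FFL-MPI Tikhonov reconstruction
===============================================
grid                                   24x24x24
data size                                 30816
lambda                                        0
iterations                                  150
projection                          real_nonneg
step length tau                      9.6362e+29
||A^H A|| estimate                  9.88336e-31
initial objective                   4.24418e-32
final objective                     3.15803e-35
residual norm                       5.61962e-18
===============================================
recovered masses (left/right half): 10.06 2.01
```

The data vector holds 30816 complex band coefficients (12 angles, two
drive axes, 1284 coefficients each) compressed from 12 x 2 x 321000
raw samples — a 99.2% memory reduction.  The two half-volume sums
recover the simulated 10 and 2 ug of Fe to within about half a
percent, and the objective falls three orders of magnitude over the
150 iterations.  Absolute scales are tiny because the induced signal
of a microgram of tracer is of order 1e-19 in SI units; only relative
quantities matter.

The same pipeline is available from the shell:

```sh
fflmpi simulate --phantom phantom.yaml --angles 12 --snr-db 30 \
    --seed 1 --out data.h5
fflmpi reconstruct --data data.h5 --lambda 0.01 --iterations 150 \
    --out recon.nii.gz --diagnostics diag.json
fflmpi sensitivity-analysis --volumes v1.nii.gz --volumes v2.nii.gz ... \
    --masses 0.5,1,5,10,50 --roi-spec rois.yaml --out limit.json
```

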