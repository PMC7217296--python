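# Methods

## Problem setting

During MRI-guided radiotherapy of mobile lung tumors, a hybrid
linac-MR system acquires 2D cine frames of the treatment plane at a few
frames per second.  The tumor boundary is known on a small library of
pretreatment (planning) frames; during irradiation it must be inferred
on every incoming frame in near real time so the beam can follow it.
`mmtrack` implements the tracking pipeline for this setting: best-frame
selection, diffeomorphic moving-mesh registration, and contour
propagation, plus the standard segmentation-agreement metrics and a
synthetic phantom for controlled evaluation.

## Registration model

The correspondence between a fixed frame `F` (the selected pretreatment
frame, carrying the contour) and a moving frame `M` (the treatment
frame) is the transformation `phi` minimizing the L2 dissimilarity

    E(phi) = mean_xi ( F(xi) - M(phi(xi)) )^2 .

Unconstrained, this problem is ill-posed.  The moving-mesh
parameterization restores uniqueness by describing `phi` through two
scalar fields:

* a **monitor function** `mu > 0` with discrete mean one, prescribing
  the local area change:  `det(J_phi) = mu`;
* a **curl field** `gamma`, prescribing the rotational part of the
  intermediate vector field.

Given `(mu, gamma)` the transformation is constructed in two steps:

1. **Div-curl solve.**  Find `rho` with `div rho = mu - 1`,
   `curl rho = gamma`, and `rho = 0` on the image boundary.
2. **Velocity ODE.**  Integrate every grid node through
   `d psi/dt = v_t(psi)` with `v_t(p) = rho(p) / (t + (1-t) mu(p))`
   from `t = 0` to `t = 1`; set `phi = psi(., 1)`.

The construction guarantees, in the continuum, that the Jacobian
determinant of `phi` equals `mu` pointwise, that the boundary maps to
itself, and that `phi` is a diffeomorphism as long as `mu` is bounded
away from zero.

## Numerical realization

**Grids and units.**  All registration computations run on a regular
`grid_size x grid_size` node grid with spacing normalized to `h = 1`;
physical pixel spacing (mm) enters only when metrics are reported.
Derivatives are centered in the interior and first-order one-sided at
the edges; field evaluation along trajectories is bilinear with
clamping at the domain boundary.

**Div-curl solver.**  `rho` is assembled from two scalar potentials,
`rho = grad(A) + perp_grad(B)` with `Lap(A) = mu - 1` and
`Lap(B) = gamma`.  Prescribing both first-order equations *and* the
full vector boundary value is overdetermined, so some boundary-layer
error is unavoidable; the implementation chooses the potential boundary
conditions to make it as small as possible.  `A` is solved with
homogeneous *Neumann* data (DCT-I diagonalization of the reflected
five-point stencil, compatibility enforced with the trapezoid-weighted
mean), so `grad(A)` is tangential at the boundary; `B` is solved with
homogeneous *Dirichlet* data (DST-I diagonalization), so `perp_grad(B)`
is tangential there as well.  Zeroing the boundary ring — the hard null
condition — then perturbs only the tangential slip, and the interior
equations hold to second order.  Residuals are reported in two parts:
over the deep interior (nodes whose centered stencils never touch the
clamped ring; these show the O(h^2) behaviour) and over the first
interior ring (the boundary-layer error, reported, not hidden).  A
sparse-factorization backend duplicates both transform solvers and
agrees with them to 1e-8; it exists to cross-check determinism, not for
speed.  With a Dirichlet potential for `A` instead, `grad(A)` is
*normal* to the boundary with O(1) magnitude, and the ring clamp
produces an O(1/h) divergence residual at the first interior ring that
visibly corrupts the Jacobian property near the boundary — measured
directly on the analytic eigenfunction case; this is why the Neumann
choice is used.

**ODE integration.**  Classical fixed-step RK4 with `n_steps = 10`
(default).  Fixed stepping keeps results bit-deterministic; on the
smooth monitors used in registration the Jacobian-constraint error is
already dominated by spatial, not temporal, discretization (doubling
`n_steps` does not change it, halving `h` does).

**Monitor normalization.**  Raw monitor updates are clipped to
`[mu_min, mu_max] = [0.2, 5]` and rescaled to discrete mean one,
iterating clip-rescale to a joint fixed point.  The lower bound keeps
the ODE denominator positive; the pair bounds local area change to a
factor of five per registration, which in practice keeps the Jacobian
determinant positive everywhere (a non-positive determinant is recorded
as a diagnostic warning, not an error).

**Optimizer.**  A demons-style projected descent.  Per iteration: warp
`M` by the current `phi`; form the force
`(warped - fixed) * grad(warped)`, smooth each component with a
Gaussian of `force_smoothing_sigma = 2` grid units (truncated at
4 sigma), zero the boundary ring; convert the displacement step
`u = -alpha * force` into parameter updates
`(delta_mu, delta_gamma) = (div u, curl u)` — the exact inverse
direction of the div-curl reconstruction, so iterates never leave the
moving-mesh family; renormalize the monitor; accept the candidate only
if the cost strictly decreases, otherwise halve `alpha` (at most five
times, then stop).  After an iteration accepted without any halving,
`alpha` doubles: pure backtracking from a fixed step was measured to
creep (the force scale of unit-normalized images is ~1e-3 grid units,
so a constant step of 2 moves microns per iteration); the
grow-on-success rule restores a useful step scale while preserving the
monotone accepted-cost trace, which is asserted in tests.  Convergence
is declared after five consecutive accepted iterations with relative
cost decrease below `rel_tol = 1e-4`, or at `max_iterations = 100`.
Defaults: `grid_size = 101`, `step_size_init = 2.0`.  Registration is
single-resolution by design.

**Tracking loop.**  For each treatment frame: select the library frame
with minimal mean-squared intensity difference (identity transform,
min-max-normalized full frames, ties to the smallest index); register
it to the treatment frame; propagate the library contour vertex-wise
through the bilinear interpolation of `phi`.  Each frame is processed
independently — results are invariant to processing order, which is
what makes the per-frame work trivially parallelizable.  A failed
registration falls back to the unwarped library contour and flags the
frame.

## Metrics

Dice is computed on rasterized masks (a pixel belongs to a polygon iff
its center, at integer coordinates, lies inside).  Hausdorff distance
and RMSE are computed on the sub-pixel contours after resampling both
to uniform 0.5-pixel arc length and scaling each axis by its mm
spacing; Hausdorff is the classical maximum (no percentile), and RMSE
is the *symmetric nearest-neighbour* contour RMSE — the root mean
square of closest-point distances averaged over both directions.  This
convention needs no vertex correspondence and pairs naturally with the
Hausdorff distance as its max-norm analogue; note that
corresponding-vertex RMSE definitions also exist and give different
values.  Centroid differences are per-axis absolute differences of
mean foreground pixel-center coordinates, scaled to mm and mapped to
anatomical directions (default: rows = superior-inferior, columns =
anterior-posterior; configurable, since acquisition orientation is
protocol-dependent).

## Synthetic study (phantom)

The phantom emulates a sagittal free-breathing cine acquisition: 30
pretreatment frames plus 100 treatment frames at 4 frames/s, 128x128
pixels at 2 mm, with additive Gaussian noise (SD 0.03 on [0,1]
intensities) standing in for the image-quality drop of a low-field
treatment scanner.  Respiration follows the standard `sin^2` surrogate
with a 4 s period, 10 mm superior-inferior and 3 mm anterior-posterior
tumor excursion, and per-cycle amplitude (SD 0.5 mm) and phase (SD
0.1 rad) jitter.  The treatment waveform is offset by pi/8 rad so the
4 fps sampling grid hits the waveform peaks exactly; the pretreatment
offset (0.37 rad) and an independent jitter stream guarantee no
treatment frame duplicates a library frame.  Anatomy (body background,
dark lung field, vessel-like blobs, diaphragm edge, bright elliptical
tumor) is rendered analytically per frame; the tumor translates
rigidly, so the ground-truth contour is an exact 64-vertex ellipse
polygon with no discretization ambiguity.  Everything is a
deterministic function of the seed.

What the phantom does *not* emulate: through-plane motion, tumor
deformation and rotation, anatomy appearing/disappearing at the slice,
Rician noise statistics, intensity non-uniformity, and scanner drift.
Passing the phantom tests therefore demonstrates the pipeline's
correctness and its accuracy under idealized in-plane motion, not
clinical performance; the noise model is isolated behind `add_noise`
so a Rician variant can be swapped in.

## Numerical choices and degenerate inputs

* Out-of-domain interpolation clamps to the boundary; since `rho = 0`
  on the boundary, trajectories are nearly boundary-preserving and
  clamping bounds any residual drift.
* Best-frame ties break to the smallest index; contour vertices outside
  the grid are clamped by the interpolation.
* A constant (zero-gradient) image short-circuits registration to the
  identity with a diagnostic note.
* An all-zero or non-finite monitor input is rejected; two empty masks
  make Dice undefined and raise.
* The fast bilinear sampler used in the RK4 inner loop is verified
  against `scipy.ndimage.map_coordinates` to machine precision.

## Problem sizes used in the shipped checks

The test suite and the acceptance script use the protocol-scale study
(30 + 100 frames, 128x128 images) at the default `grid_size = 101` for
the end-to-end accuracy check, 65- and 129-node grids for the solver
and Jacobian convergence studies, and 33-node grids for the fast unit
tests of the tracking loop.

## Known limitations

* Single-resolution optimization: very large displacements (beyond a
  few pixels of residual motion after best-frame selection) may fall
  into local minima; the clinical design relies on the library
  absorbing the gross motion.
* The div-curl boundary layer means the Jacobian constraint degrades
  within one or two nodes of the image edge (quantified by the reported
  ring residuals); tumors are assumed to be interior structures.
* 2D only, matching the planar cine acquisition; no inverse transform
  is computed.
* No real-time latency guarantees; the per-frame independence contract
  is the hook for parallel deployment.
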