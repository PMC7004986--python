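# Methods

This note documents the model implemented by `romtflow`, its numerical
choices, the synthetic phantoms the tests rely on, and the limits of what a
green test establishes.

## Transport model

Tracer intensity is treated as a conserved, nonnegative mass density μ on a
uniform cell-centered voxel grid. Between two observed frames, normalized to
the unit time interval, the density evolves under an advection/diffusion
constraint ∂ₜμ + ∇·(μv) = ∇·(σ²∇μ) with constant isotropic diffusivity σ².
The inverse problem minimizes the kinetic transport energy
∫∫ ½ μ‖v‖² dx dt plus a soft endpoint penalty ξ‖μ_N − μ_final‖²_Ψ over the
velocity sequence. Two modeling consequences matter:

- With σ² = 0 this is the classical dynamic (fluid) formulation of optimal
  transport: for a rigid translation of a blob of mass m by displacement d,
  the minimal energy is the action ½·m·‖d‖², which the acceptance suite
  verifies on a 24³ instance to 15%.
- The diffusion term lets Fickian spreading be explained without spurious
  bulk flow. On purely diffusive data, solving with the matched σ²
  suppresses recovered advective speed to well under a fifth of its value
  when diffusion is disabled; the recovered speed decreases monotonically in
  the solver's σ². This is the discrimination property that motivates the
  regularization.

## Discretization

Each of the N sub-steps per frame pair (dt = 1/N) is an operator split:

1. **Particle-in-cell advection.** Every cell's mass rides a particle
   displaced by v·dt and is deposited onto the 8 neighboring cell centers
   with trilinear weights; the deposition matrix A(v) has unit column sums,
   so mass conservation is exact, and nonnegative weights, so positivity is
   structural. Particles pushed past the boundary are clamped — no mass
   leaves the domain.
2. **Backward-Euler diffusion.** (I − dt·σ²·L)μ' = μ with L the 7-point
   Laplacian closed with zero-flux (Neumann) conditions. L is symmetric
   negative semidefinite with constants in its null space (mass conserved);
   the system matrix is an M-matrix, so nonnegativity survives the solve up
   to solver tolerance. The factorization is cached per pair (sparse LU up
   to 80k cells, conjugate gradients at tolerance 1e-10 beyond).

Neither the boundary condition nor the velocity staggering is dictated by
the transport model itself; zero-flux diffusion plus particle clamping is
the unique choice consistent with interpreting total intensity as conserved
mass, and cell-centered velocities are the simplest layout consistent with a
per-cell particle push.

The discrete energy is ½·dt·dx³·Σₙ μ_{n-1}ᵀ(vₙ⊙vₙ summed over components):
the density weight is the one the PIC step actually transports. The ½
mirrors the continuous functional so that the translation action comes out
as ½m‖d‖² (dropping it would only rescale the objective, not the minimizer).

## Optimization

Because μ_{n} is an explicit function of the velocities and the fixed
initial frame, the problem reduces to an unconstrained minimization over v,
started from v = 0 (the natural start for an energy quadratic in v).
Gradients are computed with the discrete adjoint of the propagation
recursion; the acceptance suite checks them against central finite
differences to 1e-4 relative. (The trilinear stencil is only piecewise
smooth — the check seeds velocities away from the half-voxel kinks.)

The Gauss-Newton Hessian keeps the positive-semidefinite part: the
frozen-density energy diagonal plus the misfit sensitivity JᵀJ, applied
matrix-free via one forward and one adjoint sweep per product. The inner
solve is preconditioned CG (Jacobi preconditioner from the energy diagonal,
default cap 20 iterations); a small Tikhonov floor (`hessian_reg`, default
1e-8 relative to the density scale) keeps the operator invertible where
μ ≈ 0. Steps pass an Armijo backtracking line search, so accepted iterates
never increase the objective; an exhausted line search returns the best
iterate with a warning flag rather than failing.

Nonnegativity (a formal constraint of the model) is enforced structurally
by the two split steps rather than by an active-set method; solver-tolerance
negatives in returned interpolants are clipped to zero with the magnitude
logged.

### Parameters

| parameter | default | units / meaning |
|---|---|---|
| `sigma2` | 0.002 | diffusivity of the constraint, dx² per normalized pair interval; the default is the intermediate value found appropriate for rodent DCE-MRI, and should be rescaled to the data's voxel/frame units |
| `xi` | 50 | endpoint-fit weight **per voxel**: the misfit term is (ξ·M/ψ)·‖μ_N−μ_final‖². Scaling by the cell count M keeps the data term dominant at convergence across grid sizes and intensity scales |
| `psi` | 1 | scalar noise covariance Ψ = ψI |
| `n_steps` | 10 | interpolation sub-steps N per pair (dt = 1/N) |
| `max_gn_iters` | 15 | Gauss-Newton cap; hard instances (multi-voxel displacements) benefit from 30–40 |
| `cg_max_iters` | 20 | inner CG cap |

Consecutive pairs are solved independently, each starting from the
*observed* earlier frame (not the previous pair's free endpoint): the free
endpoint exists to absorb noise, and chaining through it would accumulate
model bias. Velocities are per normalized pair interval; physical speeds are
obtained at reporting time by dividing by the real inter-frame interval.

## Lagrangian layer

Pathlines integrate the augmented velocity v_aug = v − σ²∇log μ — the
velocity of the conservation form of the constraint, which is the field a
mass parcel actually follows — with RK4 and trilinear interpolation through
the piecewise-constant-in-time sub-step fields. Reported speeds are
|v_aug| by default (a config switch reports |v| instead; the two differ
only where diffusion contributes). μ is floored at 1e-4 of its maximum
before the logarithm so the correction stays finite in empty regions.

Seed voxels follow the "12% rule": a voxel seeds a pathline when its
percent-of-baseline signal peaks at ≥ 112% anywhere in the interval. The
max-over-frames reading (rather than all-frames) keeps voxels that enhance
during the rising phase; the threshold and an optional decimation stride are
config-exposed.

Clustering is a deterministic single-pass QuickBundles sweep: curves are
resampled to 12 equal-arc-length points, compared to running cluster
centroids under the mean-direct-flip distance (flip-invariant), assigned
within a threshold of 2 voxel edge lengths, and clusters smaller than 5
members are discarded as insignificant. All three constants are
config-exposed; they are conventional values, not fitted ones.
Rasterization deposits every recorded point with the same trilinear weights
used by the transport step; the binary map is the support of the deposited
weight and the speed map the weight-averaged speed.

## Compartmental flux

The boundary between two disjoint masks is the set of 6-connected cell-face
pairs, oriented from source into target. The per-face flux combines an
advective part μ·(v·n)·dx² and a Fickian part −σ²(∂μ/∂n)·dx² (two-point
gradient). For the advective density weight the **donor cell** (upwind
side) is used rather than the face average: the PIC step transfers exactly
the donor cell's mass across a face, so the upwind estimator — together
with evaluating the diffusive part at the post-step density, as implicit
stepping requires (`step_flux`) — reproduces each compartment's discrete
mass change to machine precision (the voxel-level divergence theorem). A
centered option is retained for comparison; it leaves an O(dx) residual
(~3% on the test phantom). Directed influx sums only the positive
(into-target) face fluxes over time.

## Phantoms: what they emulate, what they do not

The generator simulates the same advection/diffusion physics forward in
time with **16 sub-steps per frame** — finer than the solver's default
discretization — so inverse tests never solve data generated by their own
scheme (no inverse crime). Canonical scenes: a centered blob under pure
diffusion (the numerical analogue of a microdialysis diffusion phantom,
where all intensity change is Fickian), rigid translation, solid rotation,
and combinations, plus i.i.d. Gaussian observation noise clipped at zero
(densities must stay nonnegative; the clipped fraction is logged).

Stated-world defaults: 32³ grid, blob sd 3 voxels, σ²_true = 0.5 voxel²
per frame interval (chosen so variance grows visibly over a handful of
frames; the physical phantom's diffusivity is not itself prescribed),
translation speed 2 voxels/frame, one frame per normalized time unit.

What a green test does **not** establish: phantoms contain no MRI physics
(no relaxivity, coil shading, motion, or partial-volume anisotropy), no
anatomical geometry, and signal is exactly proportional to mass. Recovery
results on phantoms bound the method's numerical behavior, not its
biological accuracy on in-vivo data.

## Known limitations

- Diffusivity is constant and isotropic; spatially varying or tensor D is
  out of scope.
- No source term: total intensity must be normalized across frames before
  solving (the preprocessing enforces this), so true tracer influx/efflux
  across the imaging window is folded into apparent transport.
- Gauss-Newton on the nonconvex reduced objective finds local minima; for
  displacements much larger than the blob's smoothness scale convergence
  slows markedly (no multiresolution cascade is implemented).
- Pathline speed averaged over the whole network underestimates the true
  bulk speed on translation phantoms by ~25%, because peripheral seeds ride
  weakly recovered velocity; mass-weighted Eulerian speed is the sharper
  recovery statistic.
- Head-motion correction and anatomical segmentation are upstream concerns;
  inputs are assumed aligned, masks are consumed, never produced.
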