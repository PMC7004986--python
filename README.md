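# romtflow

Regularized optimal mass transport (rOMT) for dynamic contrast-enhanced
image series, with a Lagrangian pathline workflow for quantifying tracer
transport — the kind of analysis used to study glymphatic (CSF–interstitial)
solute movement in DCE-MRI of the rodent brain.

## Who this is for

Researchers with a time series of 3D volumes (NIfTI) in which a tracer's
signal can be treated as a conserved mass, who want to ask: *where is the
tracer moving, how fast, and how much of the movement is bulk flow versus
diffusion?* The package also ships a synthetic phantom generator so the
entire pipeline can be exercised and validated without any imaging data.

## The model

Given two successive images μ_init, μ_final ≥ 0 on a uniform voxel grid, the
solver seeks the time-varying velocity *v* minimizing the dynamic transport
energy subject to an advection/diffusion constraint,

    min_v   ∫₀¹ ∫ ½ μ ‖v‖² dx dt  +  ξ ‖μ_N − μ_final‖²_Ψ
    s.t.    ∂ₜμ + ∇·(μv) = ∇·(σ²∇μ),    μ(0) = μ_init,   μ ≥ 0,

i.e. the Benamou–Brenier fluid formulation of optimal transport, regularized
by an isotropic diffusion term σ² and a soft ("free endpoint") fit of the
final image that absorbs observation noise. Discretely, each time step is an
operator split

    (I − dt·σ²·L) μ_{n+1} = A(v_n) μ_n

with A(v) a particle-in-cell trilinear deposition matrix and L the
zero-flux 7-point Laplacian; both halves conserve mass and preserve
nonnegativity exactly. The reduced problem over v is solved by Gauss–Newton
with adjoint gradients, a matrix-free preconditioned conjugate-gradient
inner solve, and an Armijo line search.

The Lagrangian layer integrates particles through the **augmented velocity**

    v_aug = v − σ² ∇log μ,

the effective velocity of the conservation form of the constraint, producing
*pathlines* with per-point *speedlines*. Pathlines are clustered by a
single-pass QuickBundles sweep under the mean-direct-flip (MDF) distance,
small clusters are discarded, and the survivors are rasterized into binary
(pathline-volume) and speed maps summarized per anatomical mask.
Compartmental exchange is quantified through the total flux
j_AD = −(σ²∇μ − μv) across the oriented face set between two masks.

## Worked example

Solve a single pair: a unit-mass Gaussian blob (sd 3 voxels) translated by
3 voxels on a 24³ grid. The minimal objective approximates the closed-form
transport action ½·m·‖d‖² = 4.5:

```python
import romtflow as rf

grid = rf.ImageGrid((24, 24, 24))
mu0 = rf.gaussian_blob(grid, (10.0, 11.5, 11.5), sd=3.0, mass=1.0)
muf = rf.gaussian_blob(grid, (13.0, 11.5, 11.5), sd=3.0, mass=1.0)
cfg = rf.RomtConfig(sigma2=0.0, xi=50.0, n_steps=8, max_gn_iters=40)
sol = rf.solve_pair(mu0, muf, cfg)
print({k: round(v, 3) for k, v in sol.energy.items()})
```

prints

```
{'total': 4.264, 'transport': 3.528, 'misfit': 0.736}
```

— the recovered objective is within 6% of the analytic action (the discrete
optimum sits slightly below it because trilinear deposition contributes a
little free spreading).

The full pipeline runs from a config file, here on a self-generated
phantom (a blob advected 2 voxels/frame with mild diffusion):

```
romtflow run -c config.yaml -o results/run --seed 1
```

with `config.yaml`:

```yaml
phantom:
  kind: translation
  dims: [24, 16, 16]
  v_true: [2.0, 0.0, 0.0]
  start: [8.0, 7.5, 7.5]
  sd: 3.0
  sigma2_true: 0.05
  n_frames: 3
  substeps: 16
solver: {sigma2: 0.05, n_steps: 5, max_gn_iters: 20}
glad: {stride: 2, step_dt: 0.05}
```

This writes pathlines (`pathlines.trk`, `pathlines.vtk`), the rasterized
binary and speed maps (NIfTI), a per-mask `summary.csv`, convergence
diagnostics and a reproducibility manifest. The resulting summary,

```
mask,pathline_volume_voxels,mean_speed
whole_volume,2934,1.5065067011944864
```

reports the voxel volume of the significant pathline network and its mean
speed in voxels/frame-interval — here recovering the true 2.0 voxels/frame
within the ~25% bias expected from averaging over the whole network (the
periphery of the blob carries less mass and hence a weaker recovered
velocity).

For real data, replace `phantom:` with
`input: {series: my4d.nii.gz, baseline_count: 3}`, add `masks:` for
compartment summaries, and `flux: {from: csf, to: tissue}` for directed
CSF→tissue transfer curves.

## Acceptance script

`scripts/acceptance.py` regenerates the translation phantom from the given
seed and reruns the complete pipeline (synthesis → preprocessing → inverse
solve → pathlines → clustering → rasterization → summaries) from scratch,
writing its result JSON to `--out`:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
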