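# chmito

Phase-field simulation of mitochondrial inner-membrane / matrix phase
separation, with calcium phosphate granules as volume-excluded regions.

Mitochondrial cristae — the invaginations of the inner membrane that house
the oxidative-phosphorylation machinery — can be modeled as one phase of a
binary mixture that separates from the fluid matrix by minimizing a
Ginzburg–Landau free energy. `chmito` implements this model as a tested
simulator for structural modelers who want to explore how geometric
constraints (organelle shape, dense granule inclusions) reorganize
cristae-like patterns, together with the linear-stability diagnostics and
morphometric measurements needed to interrogate the output quantitatively.

## Model

The scalar order parameter Ψ(r, t) ∈ [−1, 1] is the local density
difference between the inner membrane (Ψ = −1) and the fluid matrix
(Ψ = +1). It evolves by the conserved (Cahn–Hilliard) dynamics

```
∂Ψ/∂t = −∇·J,      J = −M ∇μ,      M = 1/2,
μ     = Ψ³ − Ψ − γ ∇²Ψ,
```

the gradient flow of the free energy

```
F(Ψ) = ∫_Ω [ ¼(Ψ² − 1)² + (γ/2)|∇Ψ|² ] dr,      dF/dt = −M ∫_Ω |∇μ|² dr ≤ 0,
```

where γ sets the interface width. Zero-flux conditions hold for both Ψ and
μ on the outer boundary Γ; on each granule boundary Γ′ the order parameter
is pinned, Ψ = C (C = +1 surrounds the granule with matrix fluid), while μ
keeps its zero-flux condition. Linearizing about the homogeneous state
gives the dispersion relation ω(k) = ½(k² − γk⁴): long-wavelength modes
with k < 1/√γ grow (spinodal decomposition), short ones decay.

The solver discretizes the fourth-order equation as two coupled
second-order equations in (Ψ, μ) with P1 simplicial finite elements
(2D triangles / 3D tetrahedra, meshed in-package with a distmesh-style
force-equilibrium mesher), advanced by the theta method (θ = ½ by default)
with full Newton iteration per step.

## Worked example

Run the bundled calcium-free protocol — a disk of radius 4, γ = 1,
Δt = 0.001, 2250 steps from seeded uniform noise:

```
$ chmito simulate --config src/chmito/configs/disk_r4.toml --outdir out_disk_r4
done step=2250 time=2.25 mass=-0.0194606 F_total=12.5632
```

`out_disk_r4/` then contains the echoed configuration, a time-series CSV,
a ParaView-readable `final.vtu` and an HDF5 checkpoint. The recorded
diagnostics for this run show the conserved total mass ∫Ψ = −0.01946
(constant to ~1e−18 relative over all 2250 steps), the free energy falling
monotonically from 16.26 to 12.563, and the characteristic pattern length
2π/⟨k⟩ growing from 1.63 (step 250) to 3.22 (step 2250) — the
merging-and-splitting coarsening of the two-phase pattern. Matrix and
membrane fractions stay near one half (0.47/0.53 at the final step), as
conservation demands for symmetric initial noise.

A granule run (disk radius 5, one granule pinned at C = +1):

```
$ chmito simulate --config src/chmito/configs/disk_r5_granule.toml
$ chmito morpho out_disk_r5_granule/checkpoint.h5
```

reports `granule_halo_mean_0 = 0.993`: the shell around the granule is
essentially pure matrix (Ψ ≈ +1), with the local membrane fraction 0.0
against a global membrane fraction of 0.44 — the simulated counterpart of
matrix fluid filling the space vacated around granules.

Other subcommands: `chmito mesh` (export tagged meshes), `chmito
stability` (dispersion-relation tables, analytic or measured).

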