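# curvecage

Curve-constrained, cage-based template deformation for segmenting
spatiotemporal (4D) volume sequences.

A segmentation *template* is a watertight triangle mesh enclosed by a coarse
free-form-deformation (FFD) cage. The mesh is bound to the cage with
harmonic coordinates, so every deformed mesh vertex is a fixed weighted sum
of the cage vertices and the cage is the single deformation handle. The
user (or a synthetic fixture generator) supplies planar constraint curves —
smooth interpolating curves through control points on axis-aligned
cross-sections — marking the target boundary at each time frame. Each frame
is then fitted independently by alternating, for a fixed number of
iterations:

1. **associate** every resampled constraint point with its closest point on
   the current deformed mesh surface (barycentric footpoint), and
2. **update** the cage by exactly minimizing a regularized quadratic cost:
   a data term pulling footpoints onto the constraint points, a position
   term and a graph-Laplacian term keeping the cage close to its previous
   shape (defaults: α=1, β=1, γ=5, 20 iterations).

Curves shared across the sequence are duplicated to all frames and their
control points linearly interpolated between explicitly edited keyframes.
Fitted meshes can be voxelized onto a reference grid (center-inside-mesh
parity test) and exported as NIfTI label volumes.

## Library quick start

```python
import curvecage as cc

# template: watertight mesh + enclosing cage, bound via harmonic coordinates
mesh = cc.load_mesh("template_mesh.obj")
cage = cc.load_cage("template_cage.obj")
template = cc.bind_template(mesh, cage, resolution=64)

frames, curves, shared = cc.load_curves_json("curves.json")
job = cc.SegmentationJob(template=template, frames=frames,
                         curves=curves, shared_curves=shared,
                         grid=cc.load_grid_json("grid.json"))
result = cc.run_job(job)
cc.export_results(job, result, "out/")   # PLY meshes + NIfTI labels + report
```

## Command-line interface

```sh
# precompute and cache the harmonic binding (invalidated by content hashes)
curvecage bind --mesh M.obj --cage C.obj --resolution 64 --out binding.npz

# fit a sequence of curve constraints and export meshes/labels/report
curvecage fit --mesh M.obj --cage C.obj --binding binding.npz \
              --curves curves.json --grid grid.json \
              --alpha 1 --beta 1 --gamma 5 --iters 20 --interval-mm 1.0 \
              --out results/

# voxelize a watertight mesh onto a reference grid
curvecage voxelize --mesh fit.ply --grid grid.json --out label.nii

# generate a complete synthetic fixture set (template, curves, ground truth)
curvecage synth --seed 1 --out fixtures/
```

`fit` also accepts `--config config.json` mirroring the flags
(`alpha`, `beta`, `gamma`, `iterations`, `resample_interval_mm`,
`binding_resolution`, `organ`, `frames`); explicit flags win. `grid.json`
is `{"dims": [nx,ny,nz], "spacing_mm": [sx,sy,sz], "origin_mm": [ox,oy,oz]}`
with a voxel-center convention. The curve-constraint JSON schema is
documented in `curvecage.curves` (`save_curves_json`).

## Synthetic phantoms

`curvecage.synthetic` builds everything needed to test the pipeline with no
scan data: parametric watertight templates (sphere, ellipsoid, capsule,
bent tube) inside box-lattice cages, smooth seeded ground-truth cage
motions (whose target meshes are exactly cage-representable), constraint
curves sampled from ground-truth cross-sections with optional click jitter,
and voxelized ground-truth labels.

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates all fixtures from the seed, runs the
property-based acceptance checks (harmonic-coordinate correctness and
refinement convergence, dense-oracle equivalence of the cage update,
closest-point exactness, fixed-point behaviour, ellipsoid/phantom shape
recovery, shared-curve semantics, rigid equivariance, the characterized
out-of-model failure mode, and voxelization accuracy) and reports pass/fail
per check on stderr. The quantitative results of the source study are
human interaction times, so there are no machine-recomputable target
values; the JSON written to `--out` is an empty object by design.

The full test suite takes roughly 8–10 minutes on one CPU; the dominant
cost is the resolution-128 harmonic solve in the refinement-convergence
criterion.

## Scope notes

- Volumes are consumed for voxel-grid geometry only; the fit never reads
  intensities.
- Alignment supports translation, rotation, and uniform scale, and is baked
  into cage vertices so curve fitting composes with manual cage edits.
- No GUI, oblique planes, DICOM ingestion, or shape-aware curve matching.
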