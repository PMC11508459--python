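# rvotshape

Statistical shape modelling of post-surgical right ventricular outflow
tract (RVOT) anatomies — the pulmonary trunk from below the valve to the
left/right pulmonary artery bifurcation — built for researchers studying
3D morphology in congenital heart disease cohorts (e.g. candidates for
percutaneous pulmonary valve implantation).

Patient surface meshes in this field are rarely shareable, so the
package couples the full analysis pipeline with a parametric synthetic
cohort generator: open Y-shaped vessel surfaces with known generative
factors (size, length, taper, mid-trunk bulge, frontal/sagittal
curvature, branch calibres and angles), subgroup-linked effects
(transannular-patch repairs larger and straighter, conduits longer and
more slender), and deterministic fixtures reproducing a published
81-subject cohort's screening log and characteristic tables.

The pipeline implements, end to end:

- **Measurement** — plane-sweep centreline with maximal inscribed-sphere
  radii and bifurcation detection; surface area SA; trunk centreline
  length L_RVOT; perimeter-derived diameters D = P/π at 1 mm steps along
  the inlet→bifurcation-saddle axis, averaged into D_AVE.
- **Rigid registration** — landmarks → centrelines → ICP cascade to the
  subject nearest the population mean; proper rotations only (size is a
  finding, not a nuisance).
- **Re-meshing** — area-faithful isotropic re-meshing, with the target
  edge length selected by the sensitivity criterion (<0.5% area change
  on the smallest subject).
- **Atlas estimation** — a deformable template: per-subject momenta at a
  sparse control-point lattice drive a Gaussian-kernel diffeomorphic
  flow (Hamiltonian system, hand-written adjoint gradients), matched to
  each subject with a correspondence-free varifold metric over a
  coarse-to-fine kernel schedule, validated by reconstruction error,
  geometric comparison with the population mean, and k-fold stability.
- **Shape modes** — PCA of the momenta: variance fractions, per-subject
  shape vectors, ±2 SD mode meshes, ≥5% mode selection, compactness.
- **Cohort statistics** — Anderson–Darling normality, ANOVA with
  Welch-t / Wilcoxon post hoc, correlations with log-age and with the
  geometric variables.

The modelling objects follow the statsmodels idiom: `AtlasModel(...)` is
built from data and `fit()` returns an `AtlasResults` carrying template,
momenta, convergence history and `summary()`; `ShapeModePCA(results)`
likewise returns a `ShapeModeResults`.

## Worked example

```python
from rvotshape import ShapeParams, generate_shape, compute_centreline, geometric_summary

params = ShapeParams(size_scale=1.1, taper=0.3, curv_frontal=0.005)
mesh, truth, landmarks = generate_shape(params, seed=0)

centreline = compute_centreline(mesh, step=1.0)
summary = geometric_summary(mesh, centreline)
print(f"SA     = {summary.sa:8.1f} mm^2")
print(f"L_RVOT = {summary.l_rvot:8.1f} mm")
print(f"D_AVE  = {summary.d_ave:8.1f} mm")
```

prints

```
SA     =   8434.4 mm^2
L_RVOT =     60.4 mm
D_AVE  =     27.1 mm
```

i.e. an RVOT with 8.4×10³ mm² of surface, a 60 mm trunk and a 27 mm mean
perimeter-derived diameter — the calibre measure used for device sizing.
The extracted bifurcation lands 0.55 mm from the generator's ground
truth, which is the kind of check the synthetic cohort makes possible at
every stage.

The whole analysis runs from the command line:

```bash
rvotshape run-all --seed 7 --out run12 --n 12
rvotshape report run12
```

which executes simulate → measure → register → atlas → modes → stats and
prints the cohort descriptives, the selected re-meshing edge length
(2 mm on the default cohort), the atlas reconstruction error (median
≈ 0.4 mm, below the 1.2 mm synthetic voxel scale), the template-vs-mean
differences for SA/L_RVOT/D_AVE, the mode variance fractions and the
subgroup tests. Re-running with the same seed reproduces every CSV
bit-identically (checksums in `manifest.yaml`).

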