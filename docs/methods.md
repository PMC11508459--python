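# Methods

`rvotshape` builds a statistical shape model (SSM) of post-surgical right
ventricular outflow tract (RVOT) anatomies: open, Y-shaped tubular
surfaces running from the sub-valvar outflow to the left and right
pulmonary artery (LPA/RPA) origins. Because patient meshes of this kind
cannot be redistributed, the package pairs the analysis pipeline with a
parametric synthetic cohort generator whose ground truth (centreline
spline, radius profile, landmarks, generative factors) lets every stage
be validated quantitatively. This note records the models, the defaults
and the design decisions.

## Synthetic cohort generator

Each subject is a swept tube: a trunk centreline integrated from signed
frontal and sagittal curvatures (units 1/mm), a radius profile

    r(s) = r_inlet (1 − taper·s/L) (1 + bulge_amp · exp(−(s/L − bulge_pos)² / w)),

with bulge width `w = 0.02` in squared arc-length-fraction units (a bulge
spanning roughly 30% of the trunk), an elliptical inlet relaxing to a
circular section at the bifurcation, and two branch tubes (radii `r_lpa`,
`r_rpa`, angles ±`branch_angle` about the trunk end tangent, length
0.32·trunk length by default). The trunk end ring is split along a seam
chord into two base loops, so the three tubes form a single manifold
surface with exactly three boundary loops (inlet, LPA, RPA). The global
`size_scale` multiplies all lengths and divides the curvatures, producing
geometrically similar shapes — surface area scales exactly with its
square, which the tests exploit.

Cohort sampling draws every parameter from an independent normal
distribution, with subgroup-linked mean shifts: transannular-patch (TAP)
subjects are larger (+0.10 size scale), more tapered (+0.07) and
straighter in the sagittal plane; conduit subjects are longer (+9 mm),
more slender (−2 mm inlet radius, −0.06 size scale) and more bent. The
defaults place the cohort at SA ≈ 3–11×10³ mm², trunk length ≈ 40–85 mm
and mean diameters ≈ 15–32 mm, the ranges typical of adolescent RVOT
cohorts assessed for pulmonary valve replacement. Subgroup labels follow
the reference cohort's marginal proportions (50/19/8/4 repair types out
of 81, etc.); ages are log-normal with median 14.5 years and IQR 6.13
years. Draws are clipped to validity bounds (e.g. taper < 0.55, bend
radius larger than the tube radius), which slightly attenuates extreme
effects.

Two deterministic fixtures encode the study tables: a 100-row screening
log (19 exclusions: 5 branch-PA stents, 2 interrupted LPA, 6 poor image
quality, 5 missing surgical data, 1 recent valve replacement) and the
81-subject characteristics table. The joint diagnosis × dysfunction
assignment within a repair type is under-determined by published
marginals; it is fixed by a greedy north-west-corner fill in the fixed
label order, which reproduces both cross-tabs exactly and is
deterministic. Sexes alternate M/F over the table (41 M / 40 F); ages are
log-normal quantiles assigned through a fixed permutation so no subgroup
hoards the extremes.

What the generator does **not** emulate: imaging noise and segmentation
artefacts, wall thickness, cardiac-phase motion, non-circular (crescent
or D-shaped) sections, and secondary branch vessels. Pipeline accuracy
numbers on synthetic data are therefore upper bounds on what real
segmentations would give; the validation logic (not the specific numbers)
is what transfers.

## Measurements

The centreline is extracted by a plane-sweep march: starting from the
inlet centroid along the inlet plane normal, the mesh is cut by a plane
orthogonal to the current direction and the length-weighted centroid of
the enclosing closed section becomes the next point. The marching
direction is low-pass filtered and its turn rate clamped at 5°/mm so that
the centroid bias of oblique sections cannot feed back into direction
oscillation. The bifurcation is the last trunk point before the section
splits into two closed curves (the transition is a figure-eight through
the saddle, handled by a short probe); branches are tracked first by
section-component continuity along the trunk direction and then followed
with the same adaptive march. The inscribed-sphere radius at each point
is the exact distance to the surface (point-to-triangle, KD-tree
candidates). On the synthetic cohort the recovered trunk lies within
~0.1–0.5 mm of the generative spline and landmarks within ~1–2 mm.

The geometric variables mirror clinical device-sizing practice: total
surface area SA (mm²); trunk centreline length L_RVOT from the proximal
opening to the bifurcation; and perimeter-derived diameters P/π measured
every 1 mm on planes orthogonal to the straight line from the inlet
centroid to the bifurcation saddle, averaged into D_AVE. Sections whose
curve touches a boundary loop are discarded (the opening-exclusion
rule). The section planes are orthogonal to the straight axis line, not
the curved centreline, and positions are measured along that line. The
saddle is located operationally as the closest-approach midpoint of the
two branch curves at the first split section, projected to the surface.

## Rigid registration

Subjects are aligned to the subject whose (SA, L_RVOT, D_AVE) z-scores
lie nearest the population mean, through a three-stage cascade: (i)
least-squares fit on the 4 landmarks in the fixed correspondence order
(proximal, LPA end, RPA end, bifurcation); (ii) least-squares fit on the
centrelines resampled at equal arc-length fractions (20 points per
branch), which accounts for calibre and curvature differences; (iii)
point-to-surface ICP (800 sampled vertices, exact nearest-triangle
queries, tolerance 1e-3 mm, max 100 iterations, divergence guard after 5
consecutive increases). All transforms are proper rotations — no scaling
and no reflection, since size is itself a finding of the analysis.
Degenerate (collinear) landmark sets are rejected; collinear centrelines
(straight tubes) fall back to an axis-aligning minimiser.

## Re-meshing

Before template estimation the registered surfaces are re-meshed
isotropically (edge split / collapse / flip plus tangential smoothing
with projection back to the input surface, 4 sweeps). Three guards keep
the operation area-faithful, which matters because the target edge
length is chosen by an area-sensitivity criterion: vertices whose
incident-normal cone opens beyond 45° (the bifurcation groove, sharp
ridges) are frozen; collapses choose the target (midpoint or endpoint)
minimising the one-ring area change and are skipped beyond a budget that
scales with the square of the target edge length (chordal sag ~ e²/8r);
flips and smoothing moves must be area-neutral to 0.5% and 0.05% of the
local ring. Degenerate faces are removed by collapsing their shortest
edge rather than deletion, which would tear holes. The population target
edge length is the largest candidate at which the smallest-area subject
changes area by under 0.5% *and* the target is actually realised (median
edge within 30%); with candidates {1, 2, 4, 8} mm the default cohorts
select 2 mm.

## Deformable template (atlas)

Shape variability is modelled with a control-point diffeomorphic
deformation model: momenta vectors at a sparse lattice of control points
generate a velocity field through a Gaussian kernel
`K(x,y) = exp(−|x−y|²/σ_def²)`; control points and momenta follow the
Hamiltonian system and template points are transported through the
field, integrated with explicit Euler (10 steps by default, 5–8 in the
coarse test configurations). Surfaces are compared with a varifold
metric — Gaussian spatial kernel of width σ_var over triangle centres,
squared alignment of area-weighted normals — which needs no point
correspondence and no consistent orientation. Gradients of the matching
objective with respect to momenta, template vertices and control points
are computed with a hand-written discrete adjoint of the Euler scheme,
verified against finite differences at 1e-4 relative tolerance in the
tests.

Template estimation starts from the subject whose SA is closest to the
population mean (T0) and alternates per-subject momenta optimisation
with template vertex updates (gradient descent with backtracking line
search; the objective trace within each stage is non-increasing by
construction). The schedule is coarse-to-fine: by default 3 stages with
σ_def = 40/20/10% of the template bounding-box diagonal, σ_var =
σ_def/2, and control lattices of 4³/6³/8³ points pruned to within σ_def
of the surface (test and pipeline configurations use 2 stages at
35/18% with 3³/4³ lattices). The regularisation weight is set per stage
so that a probe deformation energy is an order of magnitude below the
median initial data term. After each stage the mean momentum field — a
deformation every subject shares, i.e. a bias of the template away from
the population mean — is transferred onto the template and the momenta
re-centred and briefly refit. This momenta-centering step is what drives
the template to the population mean: without it the template retains its
initialising subject's trunk length (~15% off the cohort mean); with it
template SA, L_RVOT and D_AVE all land within ~3–6% of the population
means on the default cohorts.

Model quality is assessed exactly as a cohort analysis would: per-subject
reconstruction error (mean distance from reconstructed vertices to the
input surface; median ≈ 0.4–0.5 mm on the default n=12 cohort, below the
1.2 mm synthetic stand-in for an imaging voxel), template validation
against the population means of the three geometric variables, optional
compactness-driven re-registration rounds (T3; stops at the first
decrease of the cumulative variance of the first m modes, m frozen as
the smallest count reaching 90% on the first fit), and k-fold template
stability (each subject left out exactly once under a seeded partition;
fold templates compared vertex-wise to the full template).

## Shape modes and statistics

PCA operates on the flattened momenta with the Euclidean inner product
(not the kernel metric — simpler, and stated openly), using the
(n−1)-denominator sample covariance; mode signs are fixed by making each
mode's largest-magnitude loading positive so mode meshes are
reproducible. Modes holding ≥5% of variance are retained and visualised
at ±2 SD by flowing the template along the mode. Compactness(m) is the
cumulative variance fraction.

The statistical layer reproduces a standard clinical-cohort workflow:
Anderson–Darling normality at 5% per group chooses between mean±SD and
median/IQR descriptives and between Welch's t and the Wilcoxon rank-sum
for pairwise contrasts; a one-way ANOVA omnibus at 5% gates the pairwise
tests; geometric variables and shape vectors are correlated with the
natural logarithm of age (the correlation is base-invariant) and with
each other. Groups smaller than 4 are described but excluded from
testing. No multiple-testing correction is applied; reports carry a
note saying so.

## Pipeline, sizes and determinism

`run_all` executes simulate → measure → register → atlas → modes → stats,
each stage reading only earlier stages' artifacts, with one root seed
feeding every random draw and a manifest of per-stage CSV checksums;
re-running a configuration reproduces the CSVs bit-identically. The
default configuration uses 12 subjects at 40×28 surface samples with the
two-stage coarse atlas schedule — sizes chosen so a full run completes in
minutes on one core while leaving every validation criterion measurable;
the 81-subject cohort with the three-stage schedule is a configuration
change (`n_subjects`, `schedule`), not a code change. Test
configurations go smaller still (6 subjects, 24×16 sampling, one-stage
schedule).

## Known limitations

- The plane-sweep centreline assumes tube-like sections; it is validated
  against the generator's spline, not against a Voronoi/medial-axis
  method, and would need extension for sharply curved or non-tubular
  anatomies (bends tighter than ~5°/mm of arc).
- The varifold data term leaves open boundaries weakly constrained; the
  area guards in re-meshing and the centering step mitigate but do not
  remove boundary drift in the template.
- Euler integration of the Hamiltonian flow is first-order; large
  deformations (momenta moving points by more than ~σ_def) would need
  more steps or a higher-order integrator.
- PCA on momenta with the Euclidean metric slightly mixes modes compared
  with the kernel-metric inner product when control points are unevenly
  distributed.
- Statistical power statements are calibrated on the generator's
  independent-normal parameter draws; real cohorts have correlated
  factors.
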