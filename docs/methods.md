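# Methods

`vertload` is a desk-scale, fully synthetic re-creation of the analysis
chain used to ask how vertically oriented trabecular bone determines the
compressive stiffness and strength of a whole vertebral body. This note
documents the models, the numerical choices, and what the synthetic
study conditions do and do not establish about real data.

## The scientific question and the pipeline

In compression, the load through a vertebral body travels along
near-parallel columns of vertically oriented bone — vertical trabeculae
plus the cortical shell. The hypothesis the pipeline is built to probe
is that the bone volume fraction of *vertical* trabeculae (vBV/TV), and
the *vertical tissue fraction* vBV/BV = vBV/TV ÷ BV/TV, explain
inter-individual variation in strength better than the total bone
volume fraction (BV/TV) does. The chain is:

1. **Volume handling** — read/write MetaImage, NIfTI-1 and TIFF stacks;
   global intensity threshold; integer-factor coarsening (block mean,
   binary re-threshold at 0.5 with ties to bone). Arrays are `[x, y, z]`
   with axis 2 the superoinferior (SI) axis.
2. **Compartment peeling** — isolate the trabecular compartment from
   the cortical shell and endplates with a moving-average wall-thickness
   rule (below).
3. **Individual trabeculae segmentation (ITS)** — medial skeletonization,
   junction cutting, competing-front region growth; each trabecula gets
   a plate/rod call, an orientation angle to the SI axis, and a class:
   vertical [0°, 30°], oblique (30°, 60°], horizontal (60°, 90°].
4. **Morphometry** — the nine orientation-resolved bone fractions plus
   cortical mass fraction, all from integer voxel counts.
5. **Micro-FE** — every bone voxel becomes an 8-node hexahedral element
   (tissue E = 10 GPa, ν = 0.3); compression to 1% apparent strain
   through PMMA layers (E = 2.5 GPa, ν = 0.3); apparent stiffness
   K = reaction force / applied displacement, solved twice per specimen
   (intact, `K_intact`, and shell removed, `K_trab`).
6. **Load paths** — bone elements with von Mises stress above the 75th
   percentile (sensitivity over 75–90) decomposed by compartment and
   orientation class.
7. **Cohort statistics** — OLS regressions of simulated strength on each
   morphology parameter, paired t tests on absolute residuals and on
   jackknife slopes, Bonferroni adjustment, and the two-predictor
   multiple regression of strength on BV/TV + vBV/BV.

## Synthetic phantoms: what they emulate

No imaging data accompany the study this pipeline reconstructs, so a
generator produces voxelized vertebral-body stand-ins with exact ground
truth: vertical columns and plates, horizontal beams (two in-plane
families), oblique struts (nearest-voxel rasterized lines at a stated
angle, dilated to thickness), a rectangular cortical wall spanning the
full SI height (optionally hole-punched to model porosity), and
endplates capping the ring interior. The default 64×64×80-voxel phantom
at 60 µm was tuned to the morphology of elderly thoracic vertebrae:
tissue fractions near 57/21/22% (vertical/oblique/horizontal) and
BV/TV ≈ 14%. Struts keep a one-voxel lateral gap to the wall (the
inner cortical surface is mostly marrow-lined) while staying fused to
the endplates, so every strut carries load.

Cohorts sample per-family strut dropout independently
(vertical 0–0.4, horizontal and oblique 0.1–0.9). This reproduces the
partial decoupling real cohorts show: vBV/TV and BV/TV correlate at
ρ ≈ 0.95 while the horizontal/oblique families add BV/TV variance that
carries no strength information. Simulated strength follows

    F_ult = β₀ + β₁ · vBV/TV + ε,   β₀ = 0.5 kN, β₁ = 50 kN, ε ~ N(0, 0.7 kN),

placing specimens on a 2–7 kN scale with a strength–vBV/TV coefficient
of determination near 0.85 at the default spread. The linear-in-vBV/TV
form is a modeling convenience; real strength also depends on shell
mass, tissue properties and plate/rod architecture, so passing cohort
statistics here demonstrate *recovery of a known generative model
through the measurement pipeline*, not biological truth.

What the phantoms do **not** emulate: anatomic outer contours and
curvature (the wall is a rectangular ring), BMD calibration, scanner
noise structure (grayscale noise is i.i.d. Gaussian), intravertebral
gradients, and realistic shell-to-trabecular mass proportions — at
desk scale the shell's surface-to-volume ratio is exaggerated, so the
cortical mass fraction is ~40% instead of the ~15% seen in whole
vertebrae. Results that depend on the shell/trabecular *balance* (e.g.
the shell's share of highly stressed tissue) are therefore
qualitative; results about orientation classes within the trabecular
compartment transfer more directly.

## Compartment peeling

The shell of a vertebra is thin and porous; the peeling rule follows
the moving-average idea: per SI slice and per in-plane axis direction,
each ray from the exterior background records the entry depth and run
length of the first contiguous bone run. Rays that run tangential to
the wall (run length far above the direction's median) or that pass
through a pore (entry far beyond the median) are discarded; gaps up to
`max_bridge_vox` (default 2) are filled from the nearest valid ray; the
thickness field is smoothed with a `window_vox` (default 5, odd) moving
average; bone within the smoothed band is shell. The same procedure
along the SI axis within `endplate_search_depth_vox` (default 10)
labels the endplates; remaining bone is trabecular. Two safeguards are
the package's own: per-slice shell fragments smaller than 12 voxels are
rejected (a strut tip facing the exterior is not a wall), and any 3D
shell component spanning less than half the SI height is rejected (a
cortical wall runs the full height; endplate rims do not). Peeling
only relabels bone — voxel counts are conserved. Where the wall and
endplates meet, the rim corners are labeled shell, matching the
generator's convention; other conventions exist and real-data users
should treat the rim assignment as a package choice.

Known limitation: rays are cast only along the two in-plane axes, which
is adequate for convex, roughly axis-aligned walls (and for the
phantoms) but will underestimate strongly oblique or concave anatomy.
A shell-less specimen that contains large vertical plates at its
periphery can also be misread as walled, since an outermost plate face
is locally indistinguishable from a cortical wall.

## Skeletonization and ITS

Plates and rods must survive thinning as surfaces and curves, which is
exactly what generic 3D skeletonizers do not guarantee (a plate is
topologically a ball and may legally collapse to a point). The
package's thinning deletes *simple points* — voxels whose removal
changes neither foreground 26-connectivity nor background
6-connectivity in the 18-neighborhood — sequentially in increasing
Euclidean-distance-transform order, with two preservation rules:

* **DT-ridge anchors**: voxels whose distance value is not exceeded in
  their 26-neighborhood are never deleted. On even-thickness plateaus
  every voxel ties, so the member of a tied axis pair with the smaller
  distance behind it is demoted — exactly one medial layer of a
  two-voxel slab stays anchored.
* **Locally-thin freeze**: a voxel that is already one voxel thick
  along some axis at the start of a sweep is medial and is not deleted.
  Because deletion proceeds in distance order, a voxel only becomes
  thin once erosion has reached the medial structure, so this freezes
  medial surfaces (plates) and axes (rods) without stranding sweep
  artifacts.

The simple-point test was validated exhaustively against an independent
`scipy.ndimage` labeling reference on 200,000 random neighborhoods, and
the homotopy property is tested on a torus and on whole phantom
networks (Euler characteristic and component counts preserved).

Skeleton voxels are tagged by the topology of their skeleton
neighborhood: ≤ 2 neighbors → curve; neighbors forming ≥ 3 connected
components → junction; otherwise surface. Two refinements: compact
surface blobs (≤ 8 voxels) touching at least two curve branches are
re-tagged as junctions (where skeleton lines cross, the meeting voxels
coalesce into a blob that looks locally sheet-like but is not a
plate), and curve and surface voxels always form separate branches even
when touching (a rod abutting a plate is a junction in its own right).
Junction voxels cut the skeleton; each remaining branch seeds one
trabecula; branches of a single voxel merge into their largest
neighbor; every trabecular voxel is then assigned by competing-front
growth, one Chebyshev shell per round, ties to the lower id —
deterministic by construction. How junction tissue is apportioned among
meeting trabeculae is not standardized anywhere; distance-ordered
growth is this package's choice.

Per trabecula, the plate/rod call is by majority of surface-tagged
skeleton voxels, and the orientation angle comes from the eigenvectors
of the voxel-coordinate covariance of the *reconstructed* voxel set:
rods use the principal axis; plates use 90° minus the angle of the
plate normal to the SI axis, so a plate whose plane contains the
loading direction scores 0° and is vertical — the load-bearing
reading of "vertical plate". Degenerate cases: a rod whose top two
eigenvalues tie falls back to the farthest-point (endpoint) vector; an
isotropic covariance is flagged and classified vertical by the
closed-below bin rule. Bin boundaries are closed below —
[0, 30], (30, 60], (60, 90] — so a trabecula at exactly 30° is
vertical; the integer-degree phrasing of the field convention leaves
the real-valued boundary open and this is the package's determination.

## Micro-FE

Uniform cubic voxels mean one unit-modulus 24×24 element stiffness
matrix per material (2×2×2 Gauss quadrature of the trilinear
hexahedron) serves the entire mesh; the global operator is applied
matrix-free, element by element, in a numba kernel. The constrained
system (prescribed SI displacement on the exterior face of the top
PMMA layer, SI-fixed bottom face) is solved by Jacobi-preconditioned
conjugate gradients to a relative residual of 1e-6 (default; cap
20,000 iterations). The 1% apparent strain is computed over the full
model height *including* the PMMA layers (default thickness 3 voxels;
2 in the compact cohort phantoms) — the alternative (bone height only)
rescales K by a constant factor per specimen and does not affect any
correlation-based conclusion.

Boundary conditions: `frictionless` prescribes only SI displacements on
the loaded faces, with three lateral pins on the bottom face (corner
node x+y, far corner y) to remove rigid modes; the pins sit where the
uniform-strain field has zero lateral displacement, so a homogeneous
block reproduces K = E·A/L exactly at any resolution — the closed-form
oracle of the test suite (observed relative error ~1e-11). `bonded`
fixes all components on the loaded faces, closer to glued platens; the
package defaults to frictionless because it admits exact oracles, and
the lateral constraint of the real PMMA interface lies between the two.
Element components (face connectivity) that do not connect the two
loaded faces are removed before solving: they carry no load and are
singular under frictionless conditions; the removed count is recorded
on the model. Edge- or corner-connected fragments count as separate
components for this purpose, which also removes hinge mechanisms.

Von Mises stress is evaluated from the centroid strain (trilinear
shape-function gradients) and isotropic Hooke's law, per element, in
MPa. Percentile cutoffs are linearly interpolated over the *bone*
elements only (PMMA excluded) and the mask is strict (> cutoff), so a
uniform stress state yields an empty mask. Composition is measured in
element counts — at uniform voxel size, tissue volume.

## Statistics

Simple regressions use OLS with the Pearson r and a two-sided p from
the t distribution on n−2 degrees of freedom. Predictors are compared
on the same outcome by a paired two-sided t test on per-specimen
|residual| differences. Two outcomes' slopes on a common predictor
(K_intact vs K_trab) are compared by pairing leave-one-out slope
estimates; no standard construction exists for a "paired t test on
slopes" of two cohort-level regressions, and the jackknife pairing is
this package's documented choice. Slope differences below 1e-9
relative are reported as p = 1 rather than running a t test on
floating-point noise. The multiple regression (statsmodels OLS with
intercept) guards against collinearity with a condition-number check
(> 1e8 on the standardized design rejects). Bonferroni adjustment is
min(1, m·p). All tests are two-sided at α = 0.05.

## Problem sizes and runtime

The package solves desk-scale models by design. Cohort-level FE runs
(ten specimens, intact + shell-removed) use 32×32×40-voxel phantoms
(`compact_fe_phantom_spec`), about 22,000 elements and 18 s per
specimen pair; the default 64×64×80 phantom (~116,000 elements plus
PMMA) solves in minutes and is used for single-specimen work.
Statistics replicates (100 cohorts of n = 100) use 24×24×32 phantoms,
where generation dominates and the whole study takes seconds. The
acceptance script runs the full chain in under five minutes on one CPU.

## Known limitations

* Peeling assumes near-axis-aligned convex walls; no diagonal rays.
* The plate/rod call inherits the skeleton tagging; structures thinner
  than two voxels everywhere are classified from very few skeleton
  voxels and the call is fragile (orientation, computed on the full
  voxel set, is much more robust — the orientation-recovery tests pass
  at ≥ 95% across 0–90°).
* TV estimation from labels alone (`"auto"`) seals shell pores by
  morphological closing per slice; for shell-less volumes it falls back
  to the whole grid. Ground-truth TV is exact and preferred when the
  generator is the source.
* Linear elasticity only: no failure analysis, and simulated strength
  is generated, not predicted, by the FE stage.
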