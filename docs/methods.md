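# Methods

This note documents the models, conventions and numerical choices behind
`orbitometry`, and what the phantom-based validation does and does not
establish.

## Coordinate and labelmap conventions

All in-memory volumes are canonicalised to RAS+ axes: array axis 0
increases toward the patient's right (+x), axis 1 toward anterior (+y),
axis 2 toward superior (+z). Axial slices are planes of constant axis-2
index. Voxel indices are 0-based; world coordinates are continuous mm at
voxel centers (`world = origin + index · spacing`). One stated convention
avoids half-voxel systematic offsets in distance measurements. NIfTI files
whose affine is axis-aligned up to permutation and flips are reoriented
losslessly; genuinely oblique acquisitions are resampled to the canonical
axes by nearest neighbour with a warning, keeping slice-based operations
well defined at the cost of sub-voxel interpolation error.

Labelmaps are per-orbit (one file per side per timepoint); bilateral
patients contribute two independent records. The label schema binds
integers to anatomical roles; the superior rectus and levator palpebrae
are one role (`superior_rectus_levator_complex`) because the two are not
separable on routine orbital CT.

## Volumetry and IREOV

Volumes are voxel counts times the voxel volume, with no partial-volume
weighting: inputs are hard labelmaps, and sub-voxel accuracy is instead
bounded empirically by the phantom tolerance tests. Since a labelmap
assigns one label per voxel, the orbital cavity label cannot overlap the
organ labels; the **orbital volume** is therefore defined as the union of
the cavity label and all soft-tissue organ labels (globe, recti, optic
nerve). Under this convention the organs are part of the orbital volume by
construction, and whether a rigid organ (globe, optic nerve) is included
in the organ accounting set is immaterial for IREOV — its terms cancel in
the numerator. The default organ set is the four rectus roles only;
inclusion of globe/optic nerve is a configuration switch that changes the
printed effective-volume magnitudes but not IREOV.

IREOV is computed as `[(post effective) − (pre effective)] / V_orb_pre`,
where effective volume is `V_orb − Σ V_org`. The quantity's name and its
normalising purpose force this grouping. IREOV is stored at full precision
and rounded to two decimals only for display. Negative values are returned
(with the effective-volume subtraction also emitting a data-quality
warning when organs exceed the orbital volume, which indicates a broken
segmentation rather than an admissible outcome).

Per-muscle association with IREOV uses the Spearman rank correlation of
each muscle's volume change across orbits; constant change vectors have
undefined correlation and are reported as NaN.

## Proptosis measurement

1. **Base points.** Bone-surface voxels are restricted to the *exterior*
   surface (background flood-filled from the grid boundary), so hollow
   bone does not expose its inner table. Within the search region — by
   default the octant superior and lateral to the orbital centroid,
   mirrored across the bone midline for the contralateral side — the
   concavity depth of each surface voxel is its distance below the convex
   hull of the regional surface patch (smallest outward-normal distance to
   a hull facet). Restricting the hull to the regional patch matters:
   a whole-skull hull would make the orbital aperture itself the deepest
   "concavity". Rasterization perturbs individual depths by up to half a
   voxel diagonal and the depth profile of a machined notch is locally
   flat, so the reported landmark is the surface voxel nearest the
   depth-weighted centroid of the near-maximal plateau (all voxels within
   half a voxel diagonal of the maximum); remaining ties go to the most
   superior, then most lateral voxel. A maximal depth below a configurable
   floor (default 0.5 mm — comfortably above the ~0.3 mm hull roughness of
   a rasterized convex surface at 0.5 mm spacing) raises a
   degenerate-surface error.
2. **Apex slice.** The axial slice maximising globe cross-sectional area
   (voxel count × in-plane voxel area); ties resolve to the median index
   of the longest run of tied slices, making symmetric phantoms
   deterministic.
3. **Corneal apex.** The anterior-most globe voxel center on that slice;
   ties go to the voxel laterally closest to the globe centroid. The
   composed `measure_proptosis` first applies a one-voxel morphological
   opening and closing to the globe mask so that single-voxel segmentation
   speckle cannot masquerade as the apex; the component-level function
   keeps the raw anterior-most-voxel contract.
4. **Distance.** Perpendicular distance from the apex to the
   interzygomatic line. The default `in_plane` convention projects the
   apex and the 3D line into the apex's axial plane before taking the 2D
   point-to-line distance — exophthalmometry measures anteroposterior
   protrusion in an axial frame — while `full_3d` uses the unprojected 3D
   distance. The base points are *not* re-detected per slice; the 3D line
   is projected, because the landmarks legitimately live on different
   slices. Distances are reported unsigned with a `posterior_to_line`
   flag (a signed variant is available) since the sign convention for
   enophthalmic eyes is not standardised.

The concavity criterion itself is an engineering choice: "most concave
point" has no canonical mathematical definition, and hull depth was chosen
because it is parameter-free, deterministic, and matches an exhaustive
per-voxel search by construction.

## Phantom generator

The phantom emulates what an orbital segmentation pipeline outputs, with
every measured quantity known in closed form before rasterization:

| structure | solid | default |
|---|---|---|
| orbital cavity | truncated cone along +y | apex r 6 mm, base r 18 mm, depth 45 mm (≈22.05 cm³) |
| globe | sphere | r 11 mm, center 18.5 mm anterior of the interzygomatic line |
| recti (4) | axis-parallel cylinders | r 2.5 mm pre; post 3.0 mm (medial) / 2.6 mm (others) |
| optic nerve | axial cylinder | r 1.5 mm |
| zygomas | spherical shells, one per side | r 9 mm, thickness 5 mm, hemispherical notch r 4 mm on the upper-outer surface |
| wall removal | box slab, pre-op bone → post-op cavity | 6 × 26 × 20 mm = 3120 mm³ |

Grid: 280 × 150 × 120 voxels at 0.5 mm isotropic (140 × 75 × 60 mm), an
adult-head scale at routine orbital CT resolution. The default parameters
give an analytic IREOV of 0.1378 with the medial rectus expanding most —
deliberately placed at the clinically reported scale for medial wall
decompression — and a programmed globe retraction of 3 mm, at the scale of
reported post-decompression proptosis reductions. The "post" cavity is the
pre cavity united with the removed-wall box (the herniation space), so the
removed volume is an exact box volume; randomized specs snap the box to
the voxel lattice so the analytic volume is attained exactly.

Rasterization uses the voxel-center rule (a voxel belongs to a solid iff
its center lies inside), with priority bone > globe > muscles > nerve >
cavity; cylinder and box extents are half-open intervals so lattice-aligned
faces are not double-counted. The spec validator proves slice-wise
containment and pairwise disjointness of all solids before rasterization,
so the analytic volumes are exact, not approximate.

**Boundary noise** models segmentation jitter: on each soft-tissue
interface (organ↔cavity, cavity↔background) every shell voxel flips to the
neighbouring label with probability 0.05, from a generator seeded by the
phantom seed — fixed spec + seed is bit-reproducible. Bone surfaces are
left noise-free: bone is the highest-contrast tissue on CT and the
landmark tolerances are specified in voxels, so jittering bone would test
the noise model rather than the detector. The noise is volume-unbiased
only approximately (interface shells differ slightly in size); the
residual bias is far inside the stated tolerances.

What the phantom does **not** model: real CT intensities, partial-volume
label mixing, deformable soft tissue, orbital fat, asymmetric or
pathological bone, and segmentation errors that are spatially correlated
rather than independent per voxel. Passing the phantom suite therefore
shows that the *measurement* routines are correct and voxel-stable; it
does not certify any particular upstream segmentation model.

## Phenotyping

The MH/FH grouping has no standardised numeric criterion. The rule is an
explicit configuration object: statistic = preoperative total rectus
volume / orbital volume; the threshold has **no default** and must be
supplied by the user — inventing a clinical cutoff would lend it false
authority. Calls at exactly the threshold go to MH by the default tie
policy. The rule is monotone by construction: raising rectus volume at
fixed orbital volume can never flip MH to FH.

## Cohort statistics

Group summaries report mean ± SD (sample SD, n−1 denominator, the clinical
reporting convention) and range. Contrasts are gated on per-group
Shapiro–Wilk normality at α = 0.05: both groups normal → t-test (paired,
or Welch for independent groups), otherwise the rank analogue (Wilcoxon
signed-rank / Mann-Whitney U), always two-sided, starred as *p < 0.05,
**p < 0.01, ***p < 0.001, ****p < 0.0001. Between-surgery and
between-phenotype contrasts default to unpaired tests since different
patients populate the groups; pairing is an explicit per-contrast flag.
The chosen test is recorded in every result — no silent fallback. No
multiple-testing correction is applied, and orbits from one patient are
treated as independent records; both caveats are printed in the output.
Under a seeded null simulation the gated procedure holds its nominal size
(empirical rejection rate ≈ 0.05 over 1000 replicates in the acceptance
script).

## Problem sizes and tolerances

The validation suite runs 20 randomised phantom pairs at 0.5 mm spacing
for IREOV recovery (observed worst error ≈ 0.002 against a 0.02 bound),
six phantom pairs for the 1–6 mm retraction sweep (worst error 0.5 mm =
one voxel, from apex quantisation), and rasterization-convergence checks
on primitive solids at 1.6/0.8/0.4 mm (refinement monotonicity is assessed
on the mean error over several sphere placements, since the
signed error of any single placement fluctuates — a lattice-counting
effect) and 1.0/0.5/0.25 mm. Convergence is checked on compact primitive
grids rather than the full bilateral scene at 0.25 mm, which would be a
~40M-voxel computation adding nothing to the mechanism under test.
Point-to-line distances are verified against independent bounded scalar
minimisation to 1e-6 mm; hull depths against an exhaustive per-voxel,
per-facet loop.

## Known limitations

* Voxel-center volumetry has O(h) surface error on anisotropic or coarse
  grids; all tolerances here were established at ≤ 1 mm spacing.
* The hull-depth base point assumes the zygomatic notch is the dominant
  regional concavity; exotic bone defects inside the search region would
  win instead. The search region is overridable per side.
* The in-plane distance convention drops the superior coordinate at the
  apex slice; comparing distances across timepoints assumes consistent
  head orientation to within a few degrees (validated: ≤ 2 voxel spacings
  of drift under a 5° in-plane rotation with nearest-neighbour
  resampling).
* `run_pipeline` trusts the schema's side label; it does not infer
  laterality from the image.
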