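# Methods

This note records the conventions, numerical choices and known limits of
the pipeline. Everything stated here is exercised by the test suite or by
`scripts/acceptance.py`; no empirical claim beyond what those compute is
made.

## Geometry and conventions

Voxel indexing is 0-based `(slice, row, col)`. A voxel center maps to
patient space (LPS, mm) as `x = origin + D (spacing ⊙ index)`, where the
columns of `D` are the unit direction cosines of the slice, row and
column axes. Series slices are sorted by the projection of
ImagePositionPatient onto the slice normal (cross product of the row and
column cosines), never by filename; rescale slope/intercept are applied
on read. Inter-slice gaps must be uniform to 1e-3 mm — a non-uniform
series is rejected rather than silently resampled, because interpolation
at read time would be invisible provenance.

RTSTRUCT↔series matching has no universal rule in the DICOM ecosystem;
we use the precedence FrameOfReferenceUID → referenced SeriesInstanceUID
→ co-location in the same case directory, and the chosen rule is recorded
in the pairing (`matched_by`) and logged. ROI names are trimmed and
internal whitespace collapsed; name matching is case-insensitive glob,
exclusion wins over inclusion.

## Mask rasterization

A voxel belongs to a VOI iff its *center* lies inside the even-odd
(parity) fill of the union of that slice's polygons, evaluated in the
slice plane. Multiple polygons on a slice combine by parity, so inner
contours carve holes. Boundary ties follow the half-open scan-line rule
(a center exactly on an edge is inside for left/top edges only), which
makes the fill deterministic and makes complementary polygons partition
the plane. Contours are assigned to the nearest slice with tolerance half
the slice spacing; tilted contours are projected onto the assigned plane
with a warning.

Two implementations of this contract exist deliberately: a vectorized
scan-line fill (`rasterize`) and a per-voxel ray-casting oracle
(`oracle_rasterize`) sharing no fill code. Their Dice coefficient is
required to be exactly 1.0 on randomized phantom ROIs (rectangles, 64-gon
circles, rings) across grid spacings; this in-repo cross-validation
replaces a cross-software comparison, which would not be reproducible
without external converters. Random fixture geometry is drawn
continuously, so polygon edges do not coincide with voxel-center rows or
columns and the comparison does not hinge on tie-breaking.

## Preprocessing

Defaults are deliberately minimal: no resampling, no re-segmentation,
fixed bin width 25 intensity units anchored at the region minimum. These
mirror the defaults of the dominant open-source extractor so that a
"basic" run means the same thing, and all active settings are serialized
into the output graph — nothing about the run is implicit. Fixed bin
count is available as the alternative (`level = min(n, ⌊n(x−min)/(max−min)⌋+1)`;
a constant region maps to level 1). Resampling uses trilinear
interpolation for the image and nearest-neighbor for the mask on a grid
that keeps the first voxel center at the old origin.

## Feature panel

The 105-feature default panel (18 first-order, 14 shape, 22 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) is fixed as this tool's basic
panel; families toggle individually. Conventions that differ between
implementations in the wild, pinned here:

* population (biased) variance throughout; Pearson (non-excess) kurtosis,
  so a normal distribution scores 3;
* entropies in bits (log₂);
* GLCM/GLRLM: one matrix per each of the 13 unique distance-1 directions,
  features per direction, then an unweighted mean;
* GLCM correlation of a flat (single-level) region is defined as 1;
* GLDM: dependence = number of 26-neighbors (within the mask) whose level
  differs by at most α (default 0); the matrix column index is
  dependence + 1;
* NGTDM: voxels with no masked neighbor do not participate; ε = 1e-6
  guards divisions, so Coarseness of a constant region caps at 1e6 and
  Busyness/Strength fall back to 0;
* degenerate regions yield NaN-valued results with a logged reason,
  never missing rows (a single voxel has no skewness; an isolated-voxel
  region has no co-occurrence).

### Surface estimation

Shape features triangulate the 0.5 iso-surface of the zero-padded mask
indicator with marching cubes. On raw binary data marching cubes inherits
the voxel staircase and overestimates the area of smooth solids by
roughly 8–9% (volume is far less affected); we therefore smooth the
indicator with a narrow Gaussian (σ = 0.8 voxels) before meshing, which
brings both area and volume of a digitized 20 mm sphere within 1% of the
analytic values. Structures so thin that smoothing would sink them below
the iso-level (single-voxel-thick slabs) fall back to the raw binary
surface, trading bias for existence. Mesh volume uses the divergence
theorem over signed tetrahedra; axis lengths are `4√λ` from the
population covariance of physical voxel-center coordinates; maximum 2-D
diameters are measured on surface vertices projected onto the three grid
planes (convex-hull-pruned pairwise distances).

## Semantic export

Feature nodes live under a deterministic IRI scheme
`local:patient/<id>/voi/<name>/run/<fingerprint>/<family>/<feature>`,
where the fingerprint hashes the extraction configuration and software
version — distinct runs can never collide, and merging graphs is plain
set union. Each feature is typed by its ontology code. The bundled
mapping table covers the whole panel but ships only two established IBSI
identifiers (intensity-histogram entropy TLU2, GLCM joint entropy TU9B);
all other panel features carry deterministic local-namespace codes
flagged as such, and users can supply a two-column CSV mapping table to
override. Value literals are written with `repr` (17 significant digits),
so CSV and graph values agree bit-for-bit.

The query engine implements exact basic-graph-pattern join semantics
only — conjunctive triple patterns with `?var` variables, no
OPTIONAL/FILTER/property paths. Full SPARQL is intentionally out of
scope: serialized Turtle/N-Triples can be loaded into any standard store.

CCC uses population moments:
`2 cov / (var x + var y + (Δmean)²)`; two constant equal vectors give 1
by convention. Note the hand-checkable case `x=(1,2,3), y=(3,2,1)` gives
exactly −1 (equal moments, Pearson r = −1).

## Synthetic phantoms

The phantom generator emulates the input contract of a clinical
radiotherapy export — one DICOM file per slice with consistent UIDs and
geometry tags, plus an RTSTRUCT whose contours are planar polygon point
lists in patient mm. Intensity patterns (constant, index-affine gradient,
cycling levels, sphere lesion on background) are integer-valued and
stored with slope 1 / intercept 0 in int16, so read-back is exact. All
UIDs derive deterministically from the patient id and seed; repeated
writes are byte-stable where it matters (pixel data, UIDs). One generator
option rotates the in-plane axes about the slice normal to exercise the
direction-cosine code.

What the phantoms do *not* model: realistic anatomy and texture, noise,
multi-frame/enhanced DICOM, gantry-tilted or non-uniform series.
Passing tests therefore demonstrate correctness of the geometry, fill,
feature and export code under clean conditions — not robustness to
malformed clinical exports beyond the specific failure modes tested
(shuffled files, mixed series, non-uniform gaps, degenerate contours,
corrupt RTSTRUCT).

## Problem sizes

Acceptance-scale runs use desk-scale inputs chosen to keep the full suite
fast while staying in the regime where the claims are meaningful: 100
randomized ROIs on 8×24×24 grids at two spacings for the rasterizer
concordance; a ~33k-voxel digitized sphere (r = 20 mm at 1 mm spacing)
for surface accuracy; 50 random ≤5³ level grids for texture-oracle
equivalence (tolerance 1e-9 relative); 3-case batches for the workflow.

## Known limitations

* 3-D features only; no per-slice (2-D) variants, no filtered-image
  (LoG/wavelet) feature classes — filtered variants are the motivating
  example for ontology labels, not something this tool computes.
* No DICOM-SEG/RT Dose, no network DICOM, no HTTP SPARQL endpoint.
* The Gaussian-smoothed surface slightly rounds true corners of
  polyhedral masks (volume low by ~1% on a 10³ cube); voxel volume is
  always exact.
* Fixed-bin-width discretization anchors at the region minimum, so
  levels are comparable across regions only when intensities are on a
  calibrated scale (e.g., HU).
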