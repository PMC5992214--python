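# Methods

This note documents the models, estimators and numerical choices behind
`retquant`, what the synthetic benchmark does and does not establish, and
the design decisions taken where the underlying laboratory procedure was
manual or underspecified.

## Image model and calibration

All measurements start from an `ImageStack`: a `(channel, z, y, x)` grid of
non-negative intensities with voxel calibration `(dx, dy, dz)` in µm.
The default z-step is 0.5 µm (the confocal acquisition setting); the
default xy sampling of the generator is 0.1 µm/px, a stated assumption —
the acquisition pixel size was not recorded — chosen as typical for a ×60
water-immersion confocal. Calibration is attached to every derived 2D
image and is never altered by an operator; areas and volumes are always
computed in µm² / µm³ so anisotropic voxels are handled uniformly.

Operators follow their conventional definitions: maximum-intensity
projection over z; de-speckling as a 3×3 median filter (removes isolated
single-pixel noise, the operation's defining property); binarization with
a strict `>` threshold, either fixed (preserving a manual-threshold
workflow) or computed by Otsu's method on a 256-bin histogram. An optional
percentile contrast stretch (0.1–99.9 by default) exists for visualizing
faint processes but is off for quantification, since it precedes only the
morphology branch of the original workflow.

## Microglia morphometry

Morphometry is 2D, on the maximum projection, matching the procedure it
automates; 3D branch tracing is out of scope.

**Segmentation.** Binarize → 8-connected labelling → components below a
minimum area (default 20 µm²) discarded → components touching the field
border flagged and excluded from per-cell records (only cells fully
contained in the field are measurable), though they still count toward
density.

**Skeletonization.** Homotopic 2D thinning (scikit-image) with a
post-pass that deletes topologically simple pixels from any residual
fully-filled 2×2 block. A 2×2 block can survive this pass only at a
"locked" diagonal crossing where no pixel is individually deletable; all
four of its pixels then classify as junction pixels and are absorbed into
one junction cluster. Genuinely thick input (any fully filled 2×3 / 3×2
block) is rejected with an error.

**Skeleton graph.** Pixels are classified by their 8-connected skeleton
neighbour count: 1 → endpoint, 2 → slab, ≥3 → junction; 8-adjacent
junction pixels merge into one junction node so thick crossings are not
double-counted. Maximal slab paths between terminals become branches with
geodesic length (axial steps `dx`, diagonal steps `dx·√2`). Three cleanup
rules, all resolution-independent (µm units, defaults 1.2 µm, exposed in
`MorphometryConfig`), handle rasterization artefacts:

- *degree-2 dissolution*: a junction carrying exactly two branch ends is a
  corner artefact of 8-connectivity and is merged through;
- *spur pruning* (`prune_um`): leaf branches shorter than the threshold
  are thinning spurs; a component whose entire skeleton is shorter than
  the threshold (a collapsed soma-only blob) is dropped, so an
  unramified cell reports zero branches;
- *junction merging* (`merge_um`): junction pairs closer than the
  threshold along the skeleton collapse into one node (a thick soma thins
  to several nearby junctions rather than one), and sub-threshold
  self-loops — crossing artefacts, not holes — are removed.

The defaults were set so that branch/endpoint/junction/triple-junction
counts recover the generator's ground-truth topology exactly on rendered
cells with 3–7 px stroke widths; the acceptance suite scores this on 100
seeded cells and requires ≥95 % exact recovery plus the tree identity
`branches = endpoints + junctions − 1` on every tree-shaped skeleton.

**Soma area.** The manual outline of the cell body is automated as an
intensity-core segmentation within the cell mask. The default splits the
in-mask intensity histogram at its Otsu threshold — the soma is the bright
mode, processes the dim one — keeps the largest component, closes it
morphologically and fills holes. This keeps the measure local to the cell
body: two cells with identical somata but different arbors report equal
areas, which a fixed in-mask intensity *quantile* cannot guarantee (its
kept-pixel count scales with arbor size). The quantile variant
(`soma_method="quantile"`, default 90th percentile) is retained for
workflows that prefer it. A cell of uniform intensity has no separable
core and reports its whole mask.

**Arborization area and index.** The polygon through the distal end of
each process is approximated by its tightest convex analogue: the convex
hull of skeleton endpoints (scipy Qhull), zero for fewer than three or
collinear endpoints. The morphological index is arborization area divided
by soma area. "Total processes" is reported two ways, since the term is
ambiguous: `n_branches` (all skeleton branches) and `n_primary_processes`
(branches with a terminal inside the soma core, i.e. processes leaving the
soma); both appear in the CSV.

## Field-level quantification

- **Density**: `n / (A·t) · 10⁹` cells/mm³, with `A` the field area and
  `t = n_slices · dz` the imaged thickness; all segmented cells count,
  border-touching included.
- **Caspase-3 positivity**: puncta are detected on the de-speckled
  projection; a ganglion neuron is positive iff a punctum centroid lies
  within 5 µm (configurable) of its nucleus centroid, an operational
  reading of "perinuclear localization". Components smaller than 0.2 µm²
  are discarded as residual shot noise.
- **Astrogliosis**: thresholded GFAP area over slice (or ROI) area.
- **Aggregates**: one global threshold per channel applied voxelwise, 3D
  26-connected labelling, volume = voxel count × voxel volume, equivalent
  spherical diameter `(6V/π)^{1/3}` — chosen for the minimum-diameter
  floor because it is rotation-invariant and well-defined for any
  component shape. Floors default to 0.58 µm (Aβ) and 0.68 µm (pTau), the
  smallest reported detectable aggregates. 3D labelling across the stack
  is the faithful reading of "aggregate volume" from a z-series; the
  choice is recorded in config so a projection-based mode could be
  compared. Layers are assigned from the centroid's y-band (IL/OL
  boundaries from ground truth or an annotation file).

**Automatic thresholds and empty channels.** Otsu always splits a
histogram — on a signal-free channel it would declare half the background
noise "foreground". Automatic thresholds in puncta and aggregate detection
are therefore floored at the channel's mean + 4σ: a channel of pure
background yields (almost) no detections, while any real structure drives
Otsu far above the floor. Constant channels yield no detections rather
than an error.

## Synthetic data: what it emulates, and what it does not

**Microglia** are random recursive bifurcating trees: `n_primary` straight
processes leave the soma at near-evenly-spaced angles (bounded jitter keeps
siblings ≥ ~40° apart); each process either terminates or splits into two
children (probability `branch_prob`, length ratio 0.7, up to `max_depth`).
Trees whose strokes would cross outside the soma — which would rasterize
into a cycle the skeleton cannot un-merge — are rejected and redrawn, so
the emitted `CellSpec` topology (computed by condensing the centerline
graph: degree-1 nodes are endpoints, degree-≥3 junctions, degree-2 merged
through) is exactly what a perfect skeletonization recovers. The soma disk
is rendered at twice the process intensity so the intensity-core soma
segmentation has a target. An unramified cell has zero
endpoints/branches/junctions by convention (its skeleton collapses to a
point); a cell with one process is a path with two endpoints, counting the
soma-side tip.

**Nuclei and puncta**: ganglion nuclei are spheres in the IL band with a
minimum separation of 8 µm; caspase positivity is a Bernoulli mark; each
positive nucleus receives 1–2 puncta at 0.8–2.5 µm offset. The separation
and offset defaults make the 5 µm positivity rule recover the marked set
exactly on noise-free fields (no punctum can fall within 5 µm of a
foreign nucleus).

**GFAP** is an anisotropically smoothed Gaussian random field thresholded
at its `(1 − f)` quantile — elongated streaks with area fraction exactly
`f` by construction (the realized fraction is recorded).

**Aggregates** are voxelized ellipsoids (a voxel belongs if its centre is
inside); the exact voxel count is the ground-truth volume. A 1.0 µm-radius
sphere at (0.1, 0.1, 0.5) µm voxels lands within ~20 % of the analytic
volume; a 1.5 µm sphere within ~5 %.

**Noise** is Poisson shot noise on the signal (`photon_scale`, default 30
counts per intensity unit) plus Gaussian background (mean 5, σ 2 on a
signal scale of 100–200), the standard fluorescence model. With noise
disabled the stack equals the rendered signal exactly, so binary channel
supports equal ground-truth masks.

**Seeding**: every random draw flows from one integer seed through
`numpy.random.SeedSequence((seed, subsystem, index))`, so per-cell and
per-field draws are independent of iteration order and fields are
bitwise-reproducible.

**Stage × genotype presets** encode the qualitative disease pattern:
transgenic microglia hyper-ramified at the pre-symptomatic stage (5
primaries, branch probability 0.85, primary length 6.5–8.5 µm vs 4 / 0.45 /
5–7 µm in controls) and de-ramified late (3 / 0.15 / 4–5.5 µm); microglia
density doubled only at the late stage (10 vs 5 cells per field);
caspase-positive fraction rising 8 → 12 → 18 % in transgenics vs 2–3 % in
controls; GFAP area fraction elevated early (0.20/0.18 vs 0.08) and
normalized late (0.09); aggregates only in transgenics, IL-only and small
(0.5–0.8 µm radius) at pre, spreading to the OL and growing through early
(0.8–1.2 µm) and late (1.0–1.4 µm, capped so spheres fit the 3 µm imaging
depth). The hyper-ramified state pairs longer processes with more
branches because the scanning domain — hence the morphological index —
grows with process reach, not branch count alone. Series fields are
128 × 128 µm at 0.2 µm/px with six 0.5 µm slices: a deliberately
down-scaled field that keeps every stroke ≥ 3 px wide while making whole
series fast to render; 16 fields per condition mirrors the study's
sampling. The paper-scale biological values (absolute densities,
intensities, plaque volumes) are *not* calibrated — only orderings and
detectability are — so passing the stage-ordering checks shows the
pipeline preserves the designed contrasts through measurement, not that it
reproduces tissue-scale numbers.

Not emulated: optical PSF blur, vasculature, photobleaching, non-ganglion
nuclei layers, and anatomical layer boundaries (layers are horizontal
bands).

## Statistics

The two-way ANOVA is computed from sums of squares of nested least-squares
fits on treatment-coded design matrices; Type II adjustment (each main
effect against the model with the other main effect; the interaction
against both) so unbalanced user data are handled sensibly — for the
balanced designs of the presets Type I/II/III coincide. F p-values come
from the F survival function (SciPy's regularized incomplete beta). Data
with zero total variance report F = 0 for every effect rather than 0/0.
Post-hoc cell-mean t tests use the pooled residual variance; because the
adjustment family is ambiguous in practice, both families are emitted and
labelled — genotype differences within each stage, and stage differences
within each genotype — with Holm–Šidák applied per family:
`p_adj(i) = max_{j≤i} min(1, 1−(1−p_(j))^{m−j+1})` over the ascending
p-values, returned in input order. The genotype F test's simulated null
type-I error at α = 0.05 is required to lie in [0.035, 0.065] over 5,000
seeded replicates.

Pearson's r is provided as the estimator for retina-vs-hippocampus
aggregate-volume correlation. The published per-stage correlation values
aggregate stage-cumulative means of undeposited measurements and are not
recomputable; no synthetic target is invented for them.

## Pipeline

`RunConfig` serializes to YAML and round-trips exactly; its SHA-256 hash,
the seed and the package version form the provenance block of
`report.json`, sufficient to reproduce all tables bit for bit. Stages
write their tables as soon as they finish (schema-versioned CSV with a
`# schema_version=` header line); `resume=True` reuses existing
measurement tables and recomputes only what is missing. Every resolved
parameter is logged at INFO level, because manual thresholding is the main
reproducibility hazard in this kind of analysis. Per-cell skeleton-overlay
PNGs are not implemented.

## Known limitations

- Morphometry is 2D-projective: overlapping cells merge into one
  component and z-structure is collapsed; the generator places cells with
  a minimum separation, real tissue does not.
- The soma segmentation assumes a soma brighter than its processes; cells
  without an intensity core raise (and are skipped in batch mode).
- The convex hull overestimates a concave manual arborization polygon.
- Aggregate volumetry truncates objects at the stack boundary; equivalent
  diameter understates elongated aggregates' longest axis.
- The mean + 4σ threshold floor assumes background-dominated channels; a
  channel in which true signal covers most voxels would need a fixed
  threshold.
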