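# Methods

## The model

The package treats a profiled section as two co-registered layers: a point
cloud of transcripts (the sDGE table: x, y in fractional pixels, gene,
count ≥ 1) and a multi-channel fluorescence image (DAPI, GFP, tdTomato)
with a known pixel size. All computation uses a single coordinate
convention — 0-based pixel indices, origin top-left, x = column, y = row —
and transcripts are binned by truncation (floor) to the containing pixel,
which makes assignment deterministic.

### Segmentation

Nuclei are reduced to points: seeds are local maxima of the
Gaussian-smoothed DAPI image, separated by at least `min_distance_px` and
above `min_intensity` (Otsu of the smoothed image by default). Growth is
the distance-capped Voronoi partition: pixel p gets the label of its
nearest seed by Euclidean distance between pixel centers, provided that
distance is ≤ `radius_px` (inclusive, so a lone seed at radius 6 owns
exactly the 113 lattice points with dx² + dy² ≤ 36); equidistant pixels go
to the smaller seed id — a deterministic stand-in for the underdetermined
"expansion stops where territories meet" behavior. The default cap of 6 px
corresponds to ~15 µm at the default 2.5 µm/px, about half a hepatocyte
diameter. The model deliberately ignores cell-size variability and
intensity-weighted boundaries; its accuracy degrades in densely packed
regions, and the synthetic benchmark reproduces (rather than hides) that
limitation — transcript purity per cell is ~70% at the default packing.

Detection defaults are `smooth_sigma = 1` px and `min_distance_px = 3`.
These are sized to the nuclear geometry the generator plants (radius 3 px,
minimum center spacing 6 px): smoothing at sigma 2 merges adjacent nuclei
into single peaks and costs ~15% recall, so the narrower kernel is the
package default.

### Quantification and reporter calling

Transcripts are aggregated per segment into a cells × genes sparse matrix
(one row per seed id, including empty segments; counts conserved exactly,
with off-segment counts tallied as unassigned). QC retains cells with
**≥ 100** unique detected genes — the cutoff is applied inclusively, a
choice the filter documents since "cutoff: 100" alone does not fix
strictness. Reporter calling thresholds each channel's per-segment mean at
the 99.9th percentile of background (out-of-segment) pixels; a channel is
positive iff its mean strictly exceeds the threshold. The class follows
the (GFP, tdTomato) pair; p21 positivity defaults to GFP OR tdTomato
(`p21_rule="or"`), with `p21_rule="tdtomato"` restricting to
tdTomato-involved classes — both behaviors are provided because a
GFP-only cell (ongoing activity without recombination readout) is
ambiguous in the reporter design.

### Annotation

Normalization is the standard library-size log transform,
v(c,g) = ln(1 + count·t/total(c)), t defaulting to the median per-cell
total; it is exactly invariant to per-cell depth. Variance-stabilizing
regression and cross-sample anchor integration are intentionally out of
scope; the replicate id is carried as metadata instead. Marker-panel
scoring (panel mean of normalized values, argmax with a minimum margin of
0.25, ties → "unassigned") is the primary annotation route because it is
directly checkable against planted truth; clustering
(PCA → kNN → Leiden, delegated to scanpy, seeded and deterministic) is
provided as the conventional alternative. The default Leiden resolution is
a conservative 0.1 with 30 neighbors: segment-to-segment transcript
spillover blurs fine structure, and higher resolutions cut the zonation
continuum into arbitrary pieces rather than discover types.

### Niche and statistics

Neighbors are first-order only: a cell whose segment boundary touches
(8-connectivity by default, so corner contact counts) at least one
p21⁺ segment and is not itself p21⁺. Roles are a strict partition
{p21_positive, neighbor, other}, and neighbors are computed among
QC-passing cells only.

Contrasts are evaluated within each annotated type: group A = p21⁺ cells
vs all remaining cells of the type, and group A = neighbor cells vs the
type's `other` cells (p21⁺ cells are excluded from the second reference so
the two special groups never sit in each other's background). Each needs
≥ 3 cells per group or the pair is skipped with a logged reason. Per gene:
log₂FC = log₂((mean_A + ε)/(mean_B + ε)) with ε = 1e−9 on means of
normalized values; two-sided rank-sum p (exact enumeration when
n_A + n_B ≤ 12 without ties, doubling the smaller tail; otherwise the
normal approximation with midranks, tie correction and 0.5 continuity
correction); Benjamini–Hochberg within each (type, contrast) family
(chosen as the conventional default where only "adjusted p" is specified;
Bonferroni would be stricter but is not the norm in this toolchain);
significant ⇔ adjusted p < 0.05 and log₂FC > 0.

The cumulative ISG score is defined here as the mean normalized expression
over the ISG panel (Rsad2, Ifit1, Cmpk2, Ifit3), with a sum variant by
flag — an interpretation, since "cumulative score" admits either. ISG
status is score > a quantile threshold (default 0.98, matched to the
planted 2% prevalence), or cluster membership when an ISG cluster id is
supplied. Fisher's exact test uses the probability-mass two-sided rule
(sum of hypergeometric probabilities ≤ the observed table's, within
relative tolerance 1e−7); odds ratio = ad/bc, infinite when bc = 0 with
ad > 0; a zero margin returns p = 1 with an undefined odds ratio.

### Registration

Image↔array alignment is a least-squares planar transform fitted to
control-point pairs — similarity by default (sequential imaging of one
section needs no shear), affine by flag, with an explicit rank check for
degenerate (collinear) configurations and the RMS residual reported. The
synthetic pipeline shares one frame between images and transcripts, so
registration is identity there and exercised by its own tests.

## The synthetic generator

Defaults describe a 512 × 512 px (1.28 mm) square of aged liver at
2.5 µm/px with 2000 cells:

| parameter | default | why |
|---|---|---|
| type proportions | hepatocyte 0.70, macrophage 0.12, neutrophil 0.05, plasma 0.04, HSC 0.05, injured hepatocyte 0.04 | hepatocyte-dominated aged liver with immune infiltration |
| p21 fraction by type | 1.2–4% (macrophages highest), ~1.6% overall | reporter cells are a rare multi-lineage minority; macrophages most prone |
| reporter class split | 60% double, 40% tdTomato-only | both observed classes, proportion configurable |
| nuclear radius / annulus | 3 px / 3–6 px | one cell's territory matches the 6 px cap; transcripts cytoplasm-localized |
| mean counts per cell | Poisson(500) | same order as real per-cell depth; ~190 unique genes/cell post-binning |
| zonation | 36 weight units split linearly periportal→pericentral along x | monotone lobule-axis gradient over 3+3 marker genes |
| SASP boost | Gpnmb, Cxcl9, Cxcl10 at 4× in p21⁺ macrophages | planted positive signal for the contrast engine |
| ISG focus | 40 nearest cells to a fixed center, ISG profile override | compact interferon-stimulated focus, independent of p21 |
| fluorescence | DAPI: Gaussian blobs (σ = 2 px); reporters: soft-edged cytoplasmic disks (radius 4.5 px); half-normal background, SNR 10 | reporter protein fills the cell body, unlike the peaked nuclear stain |
| replicates | 3 blocks along y | spatial blocks stand in for separate sections |

What it does **not** emulate: optical PSF and channel bleed-through,
3-D tissue, cell-size variability, segmentation-free ambient RNA, and
platform-specific capture biases. Passing recovery tests therefore shows
the algorithms are correct under the stated geometric and noise model, not
that the defaults transfer unchanged to any particular instrument.

## Numerical choices and degenerate inputs

Everything is driven by `numpy.random.Generator` seeds; identical config +
seed reproduces outputs byte-for-byte (result tables are written with a
fixed float format). Flat images yield zero seeds; duplicate seed
coordinates, empty groups, zero-total cells, unknown labels and
out-of-bounds transcripts raise informative errors (out-of-bounds records
can instead be skipped and logged). Poisson-disc placement fails loudly
with a suggestion when the requested density is infeasible.

## Problem sizes

The test suite and the acceptance script run the full study at its default
size (2000 cells, ~10⁶ transcripts, 512² px; a single generation plus
analysis takes a few seconds) and use 300-cell sections for end-to-end
determinism checks; oracle equivalences run on ≤ 128² grids where
brute-force enumeration is exact and fast. These sizes are the package's
benchmark conditions; the algorithms themselves are linear in pixels and
transcripts and run comfortably at much larger sections.
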