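# Methods

## Coordinate and angle conventions

Images use the standard raster frame: origin top-left, x rightward, y
downward. The biological convention is anterior = −x (anterior is towards
the left of a dorsal-skin image) and orientation angles are measured from
the anterior direction, positive counterclockwise in the y-up biological
sense. A single module (`planarpol.conventions`) owns the transform
between the two frames; every other module works in biological degrees.
Vector angles are stored in (−180°, 180°] (0° anterior, ±180° posterior);
nematic (axis) angles in [0°, 180°), with the structure-tensor module
reporting its raw axis in [−90°, 90°). Wrapping guards against the
floating-point `mod` edge case where a tiny negative argument returns the
modulus itself.

## Follicle orientation detection

Embryonic placodes are imaged in two channels: an anterior-marker blob
and a posterior-marker crescent. Each channel is Gaussian-smoothed
(default σ = 2 px), thresholded (Otsu on the smoothed channel — a
relative method, so the detector is intensity-scale invariant), connected
components are area-filtered, and A-blobs are paired to B-blobs greedily
on ascending centroid distance with a hard cutoff; each blob is used at
most once and unmatched blobs are reported as residuals. The follicle
position is the centroid midpoint; its orientation is the direction from
the B centroid to the A centroid. Pairs whose separation falls below
`unpolarized_offset_px` (default 0.25 × the median equivalent blob
radius; no numeric criterion is established in the literature, so this is
an exposed parameter) are flagged unpolarized and carry a NaN angle
sentinel rather than a number.

Greedy pairing is deterministic and matches the minimum-total-distance
assignment whenever marker pairs are separated by more than the
within-pair offset — the regime follicle images are in; genuinely
ambiguous cases land in the residual list and are resolved by the
file-based correction mechanism (`set_angle`, `set_unpolarized`,
`delete`, `add`; the last action per follicle id wins, which makes
re-applying a correction file idempotent).

## Local order parameter

For each focal follicle, the polarized follicles within a radius are
collected (the focal follicle included). Embryonic mode uses radius
3×d with d the mean minimum neighbor distance; postnatal mode uses a
fixed radius, 200 px by default. The order is

    order = (1 + mean over unordered pairs {j,k} of cos(θⱼ−θₖ)) / 2

computed through the resultant identity |Σe^{iθ}|² = n + 2Σ_{j<k}cos(θⱼ−θₖ)
(an independent O(n²) pairwise implementation backs it in the tests).
The affine map to [0, 1] is fixed, not per-image min–max rescaled: the
fixed map is what anchors 0 to an antiparallel pair and 1 to a parallel
field on every dataset (a per-image `minmax_rescale` helper is provided
for presentation). Two pair conventions are defensible — all pairs within
the neighborhood versus focal-vs-neighbor pairs only; both agree on the
anchors, the all-pairs reading is the default and the focal variant is
available via `pairs="focal"`. Neighborhoods with fewer than two
polarized members yield a NaN sentinel (rendered black) rather than
propagating NaN into statistics; unpolarized follicles are excluded from
every pair average but keep their map position.

On a synthetic reversed-patch field this reproduces the characteristic
phenotype: order > 0.9 deep inside and outside the patch and a contiguous
ring of order < 0.5 along the boundary, where neighborhoods straddle the
reversal and antiparallel cross-pairs outweigh within-side pairs.

## Postnatal flow fields

Local hair orientation is estimated from bright-field texture with a
Gaussian-windowed structure tensor (window parameter w gives σ = w/2; the
window parameterization of the upstream plug-in is not restated anywhere
authoritative, so σ = w/2 is adopted and documented). At each point of a
regular lattice (default spacing 12 px, matching one vector per follicle
at the published image scale) the tensor is eigen-decomposed; the
eigenvector of the **smaller** eigenvalue is the along-stripe axis —
stated explicitly because sign and eigenvector conventions differ across
implementations — and coherence = (λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1] is the
confidence. Tensor smoothing uses reflect boundary handling and the
lattice is inset from the image border by the smoothing support (2σ), so
no estimate leans on out-of-image pixels. Grid points with coherence
below a configurable floor (default 0.1) carry no vector downstream.

The axis is 180°-ambiguous; a binary flip mask (any nonzero pixel = flip)
adds 180° at masked grid points to produce the 360° vector field. Flip
masks are human-authored for real data and generated from ground truth
for synthetic data. Applying the same flips twice is the identity.

## Junctional polarity nematics

Per cell, boundary-band pixels (within `boundary_width`, default 2 px, of
the cell border) are grouped into 36 equal angular sectors about the cell
centroid. Sector mean intensities weight the sector direction nematics,
and the principal axis of the resulting second-moment matrix gives the
director angle, with magnitude (λ₁−λ₂)/(λ₁+λ₂) — equivalently the
magnitude-weighted double-angle resultant of the sector directions.
Averaging per sector normalizes away the uneven angular sampling of a
polygonal boundary: a raw pixel-position PCA lets cell elongation
masquerade as intensity polarity (median angular error above 10° on
clean synthetic tessellations), whereas with sector normalization a
uniformly lit boundary of any cell shape scores exactly 0 and the painted
cos² round trip recovers the director within 5° for >95% of cells. The
sector count must be a multiple of 4 so the sector grid is symmetric
under 90° image rotations. This magnitude definition is dimensionless,
bounded in [0, 1], and 0 for uniform rings; it may diverge numerically
from other polarity tools' calibrated magnitudes, but the bounded
anchors (coherent case exact, orthogonal cancellation exact) are what the
tests pin down. Cells touching the image border (partial boundary) are
excluded and reported.

Local averaging follows double-angle nematic algebra:
S = Σᵢ mᵢ(cos 2θᵢ, sin 2θᵢ)/n over cells whose centroids lie within the
radius (default 40 px, self included); averaged magnitude = |S|, averaged
angle = ½·atan2(S_y, S_x) folded to [0°, 180°). Coherent neighborhoods
are reproduced exactly and orthogonal equal-magnitude nematics cancel to
machine precision. Circular histograms weight each cell by its magnitude
(not a unit count) over [0°, 180°) bins, conserving total mass.

Spatial maps exclude cells with averaged magnitude < 0.02 (sentinel
black), affinely map the remaining magnitudes so the 1st percentile → 0
and the 99th → 1 (clipped), and color each cell by averaged angle (cyclic
over 180°) with saturation = scaled magnitude. A degenerate constant
magnitude distribution maps to saturation 1 to stay visible. A nematic is
sign-blind: these maps detect rotation of the polarity **axis** across a
tissue band, not a vectorial reversal, and the outputs are labeled
accordingly.

## Intensity metrics

Nuclear exclusion uses minimum-error (Kittler–Illingworth) thresholding:
the two-Gaussian classification-error criterion
J(T) = 1 + 2[P₁lnσ₁ + P₂lnσ₂] − 2[P₁lnP₁ + P₂lnP₂] is minimized
exhaustively over 256 histogram splits (deterministic, and symmetric
under intensity inversion, unlike the fixed-point iteration some tools
use; natural logarithms as in the published criterion). Masked Pearson is
the standard correlation over non-excluded pixels of the raw (not
re-thresholded) intensities, with explicit errors for degenerate inputs.

Surface ratios: the cell mask comes from an Otsu threshold of the total
(fluorescent-protein) channel with small speckle components dropped, or
from a supplied label mask. Background — the mean of pixels outside every
cell mask; a fixed-ROI alternative can be passed as a precomputed mask —
is subtracted per channel, the surface mean is divided by the exposure
scaling factor (the surface channel is acquired at a longer exposure by
that factor), and ratio = corrected surface / corrected total, floored at
0 with a warning. Cells containing saturated surface pixels are flagged
and excluded from normalization. Cohort normalization rescales all ratios
so the reference (wild-type) group's mean is exactly 1.

## Track analysis

Smoothing is a centered moving average (default 30 frames; even windows
are incremented to stay centered) with symmetric shrinking windows at the
endpoints, so the first and last samples are untouched and a linear track
is invariant; path length never increases. Tracks are colored by the rank
of their initial AP position through a rainbow colormap (ties broken by
initial y, then id — rank-based, hence permutation invariant).

The net-flow summary splits cells by their initial AP side of the placode
center (supplied, or the mean initial position) and reports each group's
mean displacement vector and convergence score (mean displacement
component toward the center). The `anteriorward` flag is True when the
converging group is the posterior one — the wild-type counter-rotation,
in which posterior cells converge and migrate anteriorly while anterior
cells are swept outward — and False when the anterior group converges
(the reversed placode, the same field mirrored along AP). Convergence
side rather than raw AP displacement sign is used because the outward-
swept group's AP drift has the same sign in both phenotypes; the flag is
None when no group converges (static placodes). This is a conservative,
explicit surrogate for visual classification and is labeled as such in
outputs.

## Synthetic scenes

The generator defines the study conditions for every round trip:

- **Positions**: dart-throwing with rejection (Poisson-disc-like),
  capacity error after 10,000 consecutive rejections rather than silently
  returning fewer points.
- **Orientations**: pattern angle (uniform; reversed patch — base+180°
  strictly inside, base outside, shortest-arc interpolation across an
  optional transition band whose width defaults to 0 because no
  quantitative width is established; whorl — tangential around a center;
  random) plus wrapped Gaussian noise applied on the circle (default sd
  10°, a realistic biological spread), never clipped linear noise.
  round(fraction × n) follicles, sampled without replacement, are
  unpolarized; within a transition band a configurable extra fraction
  becomes unpolarized, emulating follicles that grow straight down.
- **Placode rendering**: channel A is a round Gaussian blob displaced by
  `blob_offset` along the orientation; channel B an offset anisotropic
  Gaussian (crescent stand-in — the detector uses centroids only, so the
  exact crescent shape is immaterial); unpolarized follicles render
  concentrically; additive Gaussian noise (default sd 0.05 of unit blob
  amplitude). Follicles closer than 2×σ warn (detector stress case).
- **Tessellations**: nearest-seed labeling of jittered grid points
  (convex cells); stray pixels from discretized slivers are absorbed into
  adjacent cells so every label is one connected region; a 1-px border
  frame is background.
- **Junction painting**: boundary-band pixels (width matching the
  measurement band) get base·(1−s) + base·s·cos²(φ−θ) with φ the angular
  position about the cell centroid and θ the local director — antipodal
  enrichment, as for a PCP protein on the two AP-facing junctions.
- **Textures**: sinusoidal stripes along a requested axis; locally
  varying fields are rendered by pointwise projection onto the local
  stripe normal (exact for piecewise-constant axial fields, approximate
  where the field curves).
- **Tracks**: the counter-rotational field sends posterior cells
  anteriorly and inward and sweeps anterior cells outward with a weak
  posterior drift; the reversed pattern is, by construction, that field
  mirrored along AP, track by track.
- **Correlation pairs**: B = r·Ã + √(1−r²)·Ñ with Ã standardized over
  the non-nuclear region and Ñ residualized against it there, so the
  achieved masked Pearson equals the target to numerical precision.

Identical (parameters, seed) reproduce every scene bit-exactly.

What the generator does **not** emulate: 3D structure and optical PSFs
beyond Gaussian blobs, photobleaching or stage drift, realistic crescent
morphology, cell-shape changes over time, or spatially correlated noise.
Passing round trips therefore demonstrate the correctness of the
measurement code under controlled conditions, not robustness to every
artifact of real microscopy.

## Problem sizes and numerical choices

Round-trip checks use desk-scale scenes chosen to give stable statistics:
100-follicle placode scenes on 600×600 px for detection, an 800-follicle
field on 1000×1000 px with a 300-px reversed patch for the order-ring
profile, a 500-cell tessellation on 700×700 px for junction polarity,
480×600 px textures for flow fields, and 256×256 px correlation pairs.
Brute-force oracle comparisons run on 100 random instances of 5–30
points at 1e−9 tolerance. Ties and degeneracies: constant images raise on
thresholding (no threshold exists); isotropic structure tensors report
coherence 0 with an arbitrary axis; zero-magnitude nematic sums report
angle 0 with magnitude 0; collinear follicle tables raise on Voronoi
construction naming the degeneracy.
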