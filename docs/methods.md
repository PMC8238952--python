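# Methods

This note documents the models and numerical choices behind `nichemap`,
what the synthetic-scene generator does and does not emulate, and the known
limitations of each stage.

## Barcode code

MERFISH encodes each RNA species as a 16-bit binary barcode read out over
16 hybridization/imaging rounds.  The code is the Hamming-weight-4 subset
of the extended Hamming code of length 16 ([16,11,4]: the [15,11] Hamming
code plus an overall parity bit).  This subset has exactly 140 codewords,
pairwise Hamming distance ≥ 4, and constant weight 4, so each molecule
appears in exactly four readout rounds and any single readout error (a
dropped or spurious bit) leaves the vector closer to the true barcode than
to any other.  Decoding uses a precomputed lookup table over all 2^16 bit
patterns containing each barcode and its 16 single-bit corruptions;
patterns outside every such neighborhood are unassigned.  Error budgets
≥ 2 are rejected outright — with minimum distance 4 a 2-error ball is not
uniquely decodable.  Gene-to-barcode assignment is a seeded permutation of
the canonically ordered codeword list; a published assignment can be loaded
from JSON instead, and blank (unassigned) barcodes are supported for
false-positive estimation.

## Synthetic scenes

The generator produces the data structure the analysis assumes, with full
ground truth:

- **Positions.** Dart-throwing with a hard minimum separation (default
  8 µm) in a rectangular field; an occupancy grid keeps sampling linear.
- **Territories.** Each pixel belongs to its nearest cell center (Voronoi
  tessellation) — the simplest model of closely packed tissue with no
  extracellular space.  The membrane image carries Gaussian-smoothed ridges
  (~2 px wide) along territory boundaries plus white noise (σ = 0.05 of
  ridge height by default).
- **Types.** A Potts-like Gibbs sampler: starting from independent draws
  from the configured abundance fractions, each cell is relabeled with
  P(t) ∝ fraction_t · exp(Σ_neighbors affinity[t, type_j]) over neighbors
  within 12 µm, for 20 sweeps.  A zero affinity matrix reduces exactly to
  independent multinomial labels.  Couplings are deliberately weak
  (self-affinity 0.12, planted cross-affinities 0.18–0.30): stronger
  couplings drive the Potts model toward phase separation and distort the
  marginal type abundances far from the configured fractions.
- **Counts.** Negative binomial via a gamma–Poisson mixture with
  type-specific means and a global size parameter r (default 10;
  var = µ + µ²/r; r = ∞ gives Poisson).  NB is the standard overdispersed
  count model; the default panel has two high-mean markers per type
  (mean 9), Mecom/Kit marking a rare HSC type (1% of cells by default),
  and a tail of low-expression filler genes so cells carry ~25–30 molecules.
- **Images.** Each molecule sits at a uniformly chosen pixel of its cell's
  territory and renders a Gaussian spot (σ = 0.8 px, unit peak) in the four
  bit images its barcode selects; spots are dropped independently with the
  dropout rate, per-pixel false-positive spots are added at the configured
  rate, and round r images (bits and beads) are translated by r times the
  per-round drift.  The default pixel grid is 107.9 nm per pixel.

What the generator does **not** emulate: realistic point-spread functions
and their fitting, photobleaching, chromatic aberration, autofluorescence
background, z-structure (scenes are strictly 2D), segmentation-confusing
morphology (nuclei, elongated cells), or empty/acellular regions.  Passing
tests therefore demonstrate the correctness of the analysis logic under
the stated noise model, not robustness to every artifact of real imaging.

## Imaging analysis

- **Drift.** Integer-pixel phase correlation of each round's bead image
  against round 0.  Sub-pixel correction is out of scope; the generator's
  drift is integer by construction.
- **Binarization.** Each bit image is thresholded at its own high intensity
  quantile (default 0.999); pixels strictly above the quantile are "on".
  In a sparse or noiseless image the quantile is 0 and any positive pixel
  is on, so clean scenes decode exactly.  The quantile is a config
  parameter: it must exceed the expected per-bit spot-pixel density, and is
  robust to per-round brightness differences because it adapts per image.
- **Decoding and merging.** Per-pixel 16-bit vectors are decoded with ≤ 1
  error; adjacent same-gene pixels (4-connectivity, the conservative
  choice) merge into one molecule at the component centroid.  Single-pixel
  components are kept.  Dense scenes lose a small fraction of molecules to
  optical crowding (overlapping spots corrupt the local bit vector), a
  real-data phenomenon the generator reproduces.
- **Segmentation.** Watershed on the smoothed membrane image (Gaussian
  σ = 2 px), seeded at local minima deeper than h = 0.2 (h-minima
  transform, which suppresses noise minima in cell interiors); watershed
  lines become background.  A constant image has no minima deeper than h
  and yields zero labels.  Ties are resolved by the deterministic scan
  order of the labeling.
- **Filters.** Areas < 2,500 or > 20,000 px are removed (strict
  inequalities: exactly 2,500 or 20,000 px is retained); labels touching
  any field border are removed; both operations are idempotent and relabel
  sequentially.
- **Coordinates.** 0-based pixel indices, (x, y) = (column, row),
  µm = pixel × pixel size / 1000, one convention across all modules.

## Quantification and typing

Dataset-level QC correlates log10(x+1) per-gene totals with log10(FPKM+1)
from a bulk reference (the log transform is a switch; FPKM comparisons are
conventionally made on the log scale); the dataset is usable when r > 0.7.
A configurable exclusion list drops species known to disagree with bulk.
Cells with < 10 molecules are removed, then each cell is normalized to
1,000 total (counts ÷ cell total × 1,000), making profiles proportions of
the labeled panel.

Clustering is Louvain–Jaccard: a k-nearest-neighbor graph (k = 15,
Euclidean on normalized profiles), edges weighted by the Jaccard overlap of
the endpoints' neighbor sets, Louvain multilevel modularity with a seeded
RNG (resolution 1.0).  Louvain subdivides large homogeneous populations on
such graphs — this is expected modularity behavior, and harmless here
because types are assigned at cluster level: each cluster takes the type
whose markers have the highest mean normalized expression, falling to
"Unknown" when the top score fails to exceed the runner-up by a relative
margin (default 0: only exact ties and all-zero scores are Unknown).
Per-type expression profiles are log2 of the type mean over the population
mean with a 10⁻⁶ pseudocount.

HSCs are called on **raw** counts (copy numbers, not normalized values):
the Mecom threshold is the 99.95th percentile (linear interpolation, the
numpy default convention) over all retained cells of a genotype dataset,
and a cell is an HSC when Mecom exceeds the threshold strictly and
Kit ≥ 1.  In synthetic runs where the generator plants HSCs at 1% of
cells the pipeline is run with the percentile set to 99.0, keeping the
rule's selectivity matched to the planted rarity.

## Spatial statistics

Neighborhoods are cell pairs with centroid distance strictly < 20 µm
(k-d tree; centroid distance because centroids are what segmentation
produces).  Pair enrichment compares the observed share of neighbor edges
joining types (a, b) with the random-pairing expectation 2 f_a f_b (f_a²
for self pairs); the log2 ratio is the enrichment fold.  Significance per
pair is a 1-df chi-square of observed vs expected edge counts with Yates
continuity correction (exposed as a flag), BH-corrected across pairs.
When self pairs are excluded — the informative view in strongly
self-clustered tissue — same-type edges are removed and expectations are
renormalized by 1 − Σ f_t², so expected probabilities still sum to 1.
A pair is "reproducible" when positively enriched with adjusted P < 0.01
in ≥ 3 replicates (raw-P mode available).  Abundance fractions for the
null are computed per replicate, matching the per-replicate significance
calls.

A niche is the set of cells strictly within 20 µm of an HSC, excluding the
central HSC itself (other HSCs can be members); the niche/non-niche
partition for composition and DEG analyses uses the union of all niches.
Niche composition per type is the 2×2 Yates-corrected chi-square of niche
vs overall proportions — the variant that reproduces the published
P = 0.0422 for the 21/254 vs 5,876/112,392 endothelial-cell table.  Direct
contact between two cells means one label's pixels, dilated by one pixel
(8-connectivity), overlap the other's.

## Composite tests

Differential expression between two cell groups: per-gene Wilcoxon
rank-sum (exact enumeration when the pooled sample is ≤ 20 without ties,
tie-corrected normal approximation otherwise) on the pooled data with BH
correction, fold change on group means with a 0.1 pseudocount (normalized
units).  A gene is significant only when |log2 FC| ≥ 1 and adjusted
P < 0.05 on pooled data **and** raw P < 0.1 with the same fold-change
direction in each of two replicate groups (default split: first half vs
second half of replicate ids).  The pooled threshold is interpreted as
FDR-adjusted and the within-group threshold as raw — the volcano
convention the rule derives from draws its cutoff line at adjusted
P = 0.05, while the replicate check is a consistency filter.  The ± values
in the HSC-abundance contrast are treated as standard deviations; that
reading reproduces the published Welch P = 0.04 (SEM does not).

The niche co-expression screen computes Pearson r between each niche gene
and each cell-type marker across individual niche cells, BH-adjusts over
all tested pairs, keeps the best marker per (gene, type), and reports
records with r > 0.1 and adjusted P < 0.05.  Constant vectors (undefined
correlation) are skipped.

## Problem sizes and defaults

The default end-to-end configuration analyses two replicate scenes of
150–280 cells in a 150–205 µm square field (≈1,400–1,900 px images), with
5% spot dropout and 10⁻⁶ per-pixel false positives as the moderate-noise
condition; at these settings the pipeline recovers ≈98% of molecules and
types ≈100% of retained cells correctly, and the whole workflow runs in
about a minute per replicate pair on one CPU.  Null-calibration checks use
20 seeds of 5,000-cell point scenes (pair enrichment) and 200-cell,
54-gene niches (correlation screen); planted-effect checks use 10 seeds
each.

## Known limitations

- 2D only; no z-stacks, and no correction for the single-cell-layer
  sectioning bias in contact and niche statistics.
- Integer-pixel drift correction; no sub-pixel registration.
- Watershed on the membrane channel only; no learned segmentation, no
  nuclear channel.
- The chi-square variant used for pair enrichment (Yates on observed vs
  expected edge counts) treats edges as independent draws, which ignores
  the dependence between edges sharing a cell; the FDR-control simulations
  show the resulting test is conservative under the independent-types null.
- The published gene-to-barcode assignment and per-gene panel are inputs,
  not built-ins; defaults use a generic seeded assignment.
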