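# Methods

## Problem setting

Whole-genome-duplication paralogs can buffer each other's loss. When one
member of a pair is deleted, the GFP-tagged sister protein may respond by
changing abundance, by moving into the deleted paralog's subcellular
compartment (compensation), or by losing abundance or mislocalizing
(dependency). The pipeline quantifies these responses from single-plane
micrographs of each tagged gene imaged in two genetic backgrounds
(wild-type and paralog deletion), across replicates and fields.

## Image model and preprocessing

Raw micrographs are modeled as signal + a spatially structured background
(uneven illumination, read-out noise). The background reference is the
per-pixel median across all images of a dataset; it is subtracted from
every image and negative residuals are clipped at 0, since intensity below
the median background carries no abundance information. For segmentation,
images are variance-stabilized as x′ = ln(x + 1) and standardized per
image to mean 0, standard deviation 1 (population σ; the normalization is
descriptive, not inferential). Replicates with fewer than `min_cells`
segmented cells (default 50, matching the expected 50–100 cells per field)
are dropped, and user-supplied gene/image exclusion lists are honored;
every removal is written to an audit log. Filtering changes membership
only, never pixel values.

## Segmentation

Ground-truth stencils are eroded per label with the minimal cross: a pixel
survives only if all four neighbors carry its own label (image borders
count as background), so touching cells become disjoint. The training
target is T = w·B + (1 − w)·min(EDT(B), d)/d with w = 0.8 and d = 20 px,
where EDT is the Euclidean distance to the nearest background pixel.
Border pixels of an eroded stencil thus score exactly
0.8 + 0.2/20 = 0.81, increasing to 1.0 where the interior depth reaches
the clip. Note that a 40 × 40 square erodes to 38 × 38 with maximum
interior distance 19, so its target peaks at 0.99; only stencils at least
~42 px deep reach 1.0 exactly.

Probability-map production is a contract (image → per-pixel probability in
[0, 1]) so that any segmentation model can be plugged in. Two reference
backends are provided: an oracle backend that emits the training target
computed from ground truth (exact on synthetic data), and a classical
backend that applies an Otsu threshold and the same binary + scaled-EDT
combination to the thresholded mask. Post-processing is a seeded
watershed: 4-connected components of (p ≥ 0.8) are markers, growth runs
on −p restricted to (p ≥ 0.5), and objects with area < 256 or > 8192 px
are removed (strict inequalities, as specified by the size gates), with
labels relabeled consecutively. 4-connectivity is used throughout,
consistent with the cross erosion.

## Per-cell measurements

Each retained object yields a 64 × 64 frame centered on the rounded
centroid, spanning [c − 32, c + 32) per axis (half-open, so the frame is
exactly 64 px) and zero-padded at image edges. Abundance uses raw
background-subtracted frames; feature extraction uses log-standardized
frames, mirroring the split between intensity quantification and
appearance embedding. Per-cell mean intensity is the mean over the whole
frame, including non-cell pixels (a masked mode exists but is off by
default); since background-subtracted non-cell pixels are near zero, the
frame mean is a scaled, low-variance proxy for cell signal.

The reference feature extractor emits exactly 128 features per frame in
fixed, versioned blocks: intensity moments and quantiles, raw and
mean-centered radial profiles (16 annuli), an angular profile (16
sectors), gradient statistics and an orientation histogram, binary- and
intensity-weighted shape moments including the seven Hu invariants,
radial dispersion, short-lag autocorrelations, radial mass concentration,
histogram entropy and top-pixel mass concentration. It is a pure,
deterministic function of the pixels; the centered radial block is
invariant to whole-frame intensity offsets by construction. It is not a
learned embedding and does not pretend to match one — it exists to give
the downstream statistics a reproducible, documented feature space in
which distinct localization patterns are linearly separable (verified by
a held-out nearest-centroid test).

## Redistribution scores

All cells of a gene are pooled across replicates (each cell weighted
equally) and averaged into one 128-dimensional centroid per background.
The redistribution score is the Euclidean distance between the wild-type
and deletion centroids; it mixes localization and abundance changes by
design. The classification threshold is selected by ROC analysis:
candidate thresholds are midpoints between consecutive sorted unique
scores plus sentinels (so no score ever equals the threshold under the
strict-greater rule), and the candidate with minimal false-positive rate
is chosen, breaking ties by maximal true-positive rate and then by the
smallest threshold. The published operating point (score > 4.73) is the
config default when no control genes are supplied, but that number is a
property of the original learned feature space; with the reference
extractor the threshold must be re-selected from controls, which the
pipeline does whenever positive/negative gene lists are given. PCA views
z-score the features first; scores are always computed on raw features.

## Abundance statistics

The abundance score of a condition is the pixel-weighted grand mean over
all frames (not a mean of per-frame means). The fold change is
log₂(s_del + 1) − log₂(s_wt + 1); orientation is deletion minus wild-type
so that positive values mark compensation candidates. Significance is a
two-sided Mann–Whitney U on per-cell frame means, exact (full permutation
distribution) when n_x + n_y ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections. Benjamini–Hochberg
step-up adjustment runs across genes. Direction calls use lfc ≥ 0.2 with
q < 0.05 (increase) and lfc ≤ −0.2 with q < 0.05 (decrease). Note that BH
is *not* idempotent in general (re-adjusting q-values multiplies by m/j
again); the implementation is validated against the step-up definition
and statsmodels instead.

## Network features

Interaction networks are consumed as generic edge tables (undirected,
self-loops dropped, duplicate edges collapsed to the strongest evidence:
largest |ε|, then smallest p). Genetic-interaction stringency classes
follow the published thresholds (lenient p < 0.05; intermediate
p < 0.05, |ε| > 0.08; stringent p < 0.05, ε > 0.16 or ε < −0.12;
stringent-negative ε < −0.12; synthetic-lethal ε < −0.35).
Shared-interactor counts exclude the pair members and are binned against
the cohort median with ties assigned to "low" (the split is "fewer or
more than the median", which excludes equality). Disconnected pairs fall
in the "1+" shortest-path bin. Colocalization is the Jaccard index
100·|A∩B|/|A∪B| with an inclusive ≥ 50 call. Enrichment of private
interactors (neighbors of one paralog that are not neighbors of the
sister) in the sister's compartment uses a two-sided Fisher exact test;
the odds ratio is the cross-product ratio with a Haldane 0.5 correction
only when a cell is zero. Boxplot summaries use linear-interpolation
quartiles and 1.5·IQR whisker fences.

## Compartment quantification (two-channel)

Cells whose centroid lies within the image-wide median major-axis length
of any border are removed. Within each replicate, images whose background
intensity falls outside mean ± sd (inclusive, population sd) are
discarded. Within each retained cell, reporter-channel pixels at or above
the 0.975 within-cell quantile are ER, pixels strictly below the 0.973
quantile are cytoplasm, and the thin band between the two quantiles stays
unassigned exactly as specified — no silent merge. Quantiles use linear
interpolation between order statistics. Cells with fewer than 100 ER
pixels, or with constant reporter intensity, are flagged and discarded.
Abundances are medians of the GFP channel over each pixel class divided
by the image background (median over non-cell pixels), making them
invariant to global intensity rescaling.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the analysis assumes:
fields of ~45 non-overlapping elliptical cells (areas 400–1600 px by
default, within the watershed size gates) on a Gaussian background
(mean 100, sd 5 AU) with an optional shot-noise term (off by default),
single z-plane, 3 replicates × 4 fields per strain, and four strains per
paralog pair. Localization classes are parametric weight fields in the
cell-intrinsic elliptical frame (nucleus: central disk at 0.3× radius;
ER: perinuclear ring plus cortical rim; cytoplasm: uniform with a dim
vacuole lumen; mitochondria: angular tubule bands; vacuole: membrane
ring; Golgi/punctate: discrete foci), normalized so the programmed
abundance equals the cell's mean foreground intensity. A programmed
relocalization of fraction f places exactly f of the cell's signal inside
the target compartment's core region and renormalizes the native pattern
outside it, so ground-truth recovery checks are exact. All randomness
descends from one integer seed through spawned generator streams;
identical seed and configuration reproduce scenes bit for bit.

Not modeled: budding morphology, cell-cycle heterogeneity, 3-D structure,
photobleaching, camera-specific noise, segmentation failure modes of real
clumped cells, or biological cell-to-cell expression variability. Passing
tests therefore demonstrate the correctness and statistical calibration
of the quantification given faithful segmentation and programmed effects;
they do not certify performance on real micrographs, where the
probability-map backend and the feature extractor would be replaced by
trained models through the existing contracts.

Default study conditions used by the test suite: the parameter-recovery
panel has 8 effect pairs (lfc = ±0.5, relocation fraction 0.6 into the
ER) plus 3 random-paired null control pairs, 3 replicates × 4 fields × 42
cells ≈ 500 cells per strain. The two-channel validation scenario
programs a strong abundance gain (lfc = 1.0) with partial ER relocation
(f = 0.3), the regime in which both the ER and the residual cytoplasmic
signal rise in the deletion background — a large relocated fraction would
mathematically deplete the cytoplasm below wild-type regardless of the
abundance gain. Validation cells use larger areas (4000–8000 px) so the
2.5 % ER tail clears the 100-pixel gate, mirroring higher-magnification
acquisition.

## Numerical conventions and edge cases

Even-count medians are midpoints of the central values. σ is always the
population standard deviation. Constant images raise an explicit
degenerate-input error in standardization; constant feature coordinates
are dropped with a warning before PCA, whose component signs are fixed by
making each component's largest-magnitude loading positive. Empty label
maps yield empty frame collections; zero-cell abundance scores and empty
centroid sets are errors, not NaNs. Feature vectors must be finite; any
non-finite pixel aborts extraction. The batch and single-frame feature
paths agree to machine precision (BLAS summation order may differ in the
last bits). Thresholds are inclusive/strict exactly as documented: seeds
use ≥, the redistribution call and the area gates are strict, the
Jaccard call and the background-QC bounds are inclusive.

## Known limitations

The reference feature space is hand-designed; absolute redistribution
scores are not comparable to those from a learned embedding, so the
published numeric threshold (4.73) cannot be reproduced here and
threshold re-selection from controls is mandatory. The intensity-mode
segmentation backend assumes bright cells on a dark background and will
not separate dense clumps as a trained model would. The Mann–Whitney unit
of analysis is the cell, pooled across replicates; a replicate-level mode
would be more conservative under strong batch effects and is left to the
caller by pre-aggregating.
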