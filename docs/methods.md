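# Methods

## Data model

The pipeline's currency is the stack of single-nucleus pairwise-distance
(snPWD) matrices: N nuclei × B × B distances in µm, symmetric, zero on the
diagonal where the barcode was detected, NaN wherever either barcode of a
pair went undetected. Zero is never used as a missing marker. Matrices are
stored dense with the symmetric half duplicated (B ≤ ~100, so the waste is
irrelevant and indexing stays simple). Genomic intervals are 0-based
half-open; browser-style coordinates are converted at the reader.

A barcode library fixes the barcode order, TAD membership, and the *border
barcode* — the barcode at the ensemble boundary between the two TADs. The
border must be interior to the chain, since the insulation window needs
barcodes on both sides.

## Ensemble maps

Per barcode pair, the ensemble summary is the location of the **first local
maximum** (scanning from zero distance) of a Gaussian kernel density
estimate of the distance samples. This approximates the mode while ignoring
the long right tail of distance distributions. Conventions:

- bandwidth: 0.25 camera pixel; with the 0.106 µm pixel of the reference
  acquisition system this is 0.0265 µm. The pixel size is configurable so
  the "0.25 pixel" rule resolves explicitly.
- distances above 4.0 µm are excluded before estimation (segmentation
  artifacts); the exclusion applies to the median method too, so the map
  invariant values ≤ max_distance holds for either estimator.
- evaluation grid: 2001 uniform points on [0, 4] µm (2 nm step). Ties on a
  density plateau resolve to the lowest-distance grid point, honoring
  "first" maximum. No boundary correction at zero: the bandwidth is far
  below typical distances, so mass leakage across zero is negligible.
- the KDE is evaluated by direct kernel summation rather than a library
  KDE: the fixed *physical* bandwidth and the first-maximum scan are the
  estimator's defining features, and covariance-scaled bandwidths of stock
  estimators cannot express them.

The per-entry sample count (after exclusion) is recorded alongside the map;
entries with no usable sample are missing, never zero.

## Pair correlation

The upper triangle of each snPWD map is flattened row-major (length
B(B−1)/2) and inverted entrywise; the Pearson correlation of two such
reciprocal vectors, over the entries defined in both, is the pair
correlation. The reciprocal is applied *before* correlating — this is what
makes the statistic sensitive to short-range rearrangements. A pair of
nuclei is skipped when the joint overlap covers less than half of the
*full* complement B(B−1)/2 (not of the pair's union); nuclei with fewer
than 13 of 20 detected barcodes are excluded before pairing (the default
matches a 20-barcode two-TAD library). Exact zero distances have no
reciprocal and are dropped from the overlap.

The null reference randomly permutes one pair member's vectorized entries
(10 reorderings per pair by default) and recomputes the correlation; its
mean sits at zero because permutation destroys the entry-to-entry
correspondence. Permutation acts on the flat upper triangle, not on barcode
labels: either reading of "reordered randomly" is defensible, and the flat
permutation destroys *all* structure including the distance-vs-separation
trend, which is the point of a null.

An important caveat for interpretation: the *expected* reciprocal distance
of a polymer falls with genomic separation (∝ |i−j|^(−1/2) for an ideal
coil), and this profile is shared by every nucleus. Two completely
independent conformations therefore correlate positively (median ≈ 0.3 at
the generator's defaults). The baseline for "no more similar than chance"
is the shuffled band, not zero.

## Radius of gyration

Rg² = Σᵢⱼ d²ᵢⱼ / (2N²) over ordered pairs of the barcode subset, which
equals the mean squared distance to the centroid (Lagrange's identity) —
the package tests this equivalence to 1e−9 µm against coordinates.
Distances above 1.0 µm are masked as outliers before summation, and N²
counts only the pairs (diagonal included) whose distance is defined after
masking. A nucleus is reported missing when fewer than one third of the
subset's distinct pairs survive; the fraction is assessed after the outlier
mask, so "detected but absurdly large" counts as undetected.

## Insulation score

At candidate border position i (boundary between barcodes i and i+1, the
border barcode belonging to the upstream side), the single-nucleus IS sums
the inverse distances in the 2×2 window {i−1, i} × {i+1, i+2}. Lower IS =
stronger insulation. The window placement relative to the border barcode is
a genuine convention choice (the sliding-square description does not fix
the offset); upstream assignment is used consistently, and the profile is
reported as a length-B vector with NaN at the B−(B−3) positions where the
window does not fit. A window containing any missing distance yields a
missing score rather than a partial sum: the 3.5 cutoff used for the
"fraction of nuclei insulated at the border" is an absolute sum, and
partial sums would bias toward apparent insulation. When an imputed stack
is supplied (same imputation as for the embedding), no window is missing.

Population profiles are per-position medians; uncertainty bands are
percentile intervals of the median over bootstrap resamples of nuclei
(1000 resamples, 95% by default — conventional choices, as no values are
prescribed by the underlying procedure).

## TAD distances, demixing, contacts

Per nucleus: the intra-TAD median over distances within the focal TAD and
the inter-TAD median over cross-TAD distances, each after excluding
distances above 1.0 µm and each reported only when at least 3 such
distances exist. The demixing score is log₂(intra/inter): values near zero
or positive mean the TADs intermingle, strongly negative values mean they
are demixed. (The orientation is fixed by requiring "larger = more
intermingled".) Contacts are cross-TAD pairs with distance strictly below
0.25 µm, each unordered pair counted once. Group comparisons use two-sided
Welch's t-tests (unequal variances, Welch–Satterthwaite df).

## Conformational space

Nuclei are admitted per cohort by a dropout cutoff (e.g. at most 7 of 20
barcodes undetected for one cohort, 6 for the other — cutoffs chosen to
roughly balance cohort sizes; the package exposes but never auto-tunes
them). A barcode counts as detected when it participates in at least one
defined distance. Missing distances of admitted nuclei are imputed from the
ensemble map — by default the ensemble of the nucleus's own cohort, since
imputing from a pooled map would pull cohorts toward each other (a
switchable choice; the source is not prescribed). Imputed, vectorized maps
are embedded with UMAP: n_neighbors = 50, min_dist = 0.1, n_epochs = 500,
metric = canberra, with a mandatory, logged seed (embeddings are stochastic;
segregation statements are evaluated across ≥ 5 seeds).

Category territories: per category, a Gaussian KDE of its embedded points
(bandwidth 0.5 in embedding units) is evaluated on a 256×256 grid over the
padded bounding box. Each density is normalized to **unit peak** before
thresholding. This deviates from a unit-mass (probability-density)
normalization deliberately: UMAP coordinates carry no absolute scale, so a
fixed absolute density threshold is only meaningful relative to the
density's own maximum — with unit-mass densities the same thresholds
enclose a different fraction of points whenever the embedding stretches or
shrinks, and on a reference construction (two unit-sd point clouds 10 units
apart) they enclose only ~90% of each category instead of the intended
dense core (analytically, 1 − exp(−r²/2) at the threshold radius). A
category's territory is the region where its normalized density exceeds the
other's by more than `diff_threshold` (0.02; 0.01 for denser, higher
resolution libraries) while itself exceeding `density_threshold` (0.02).
Region boundaries are extracted as closed contours and kept as polygons;
composition percentages count boundary points as inside, credit points
falling in both territories to their own category, and partition each
cohort into own / other / outside summing to 100%.

Leiden clustering runs on the symmetrized k-NN graph (euclidean, k = 50) of
the **2D embedding coordinates** — not the high-dimensional vectors — with
resolution 0.25 and a fixed seed, via igraph + leidenalg (RB-configuration
quality function, the same objective scanpy drives).

## Synthetic generator

The generator produces what the analysis needs to see, not a mechanistic
polymer model. Per nucleus: (1) an ideal-chain backbone — cumulative
isotropic Gaussian steps, σ = 0.15 µm per axis per step, so adjacent
barcodes sit ~0.26 µm apart rms and the 20-barcode locus spans ~0.8 µm,
matching the sub-µm scale of a two-TAD insect locus; (2) each TAD block
contracted toward its centroid by a compaction factor in (0, 1]; (3) each
downstream block displaced away from its upstream neighbour's centroid by
border_strength × σ along the centre-to-centre axis (the rest of the chain
follows, keeping it connected). Observation: barcodes drop out
independently (default detection 0.9) and survivors get isotropic Gaussian
localization noise (default σ = 0.05 µm, typical of high-precision FISH
localization). Cell-to-cell heterogeneity arises entirely from the
stochastic coil. One master seed per cohort; per-nucleus substreams are
spawned by counter, so cohorts reproduce independently of generation order.

What the generator does **not** emulate: loop extrusion or any
epigenomic-state polymer energetics, nuclear confinement, excluded volume,
correlated (fiducial-drift-like) localization errors, or intensity-dependent
detection. Passing tests therefore demonstrate that the statistics recover
planted compaction/insulation/segregation structure under realistic noise
and dropout — not that they would resolve any particular biological locus.

## Problem sizes and numerics

Default validation runs use cohorts of 200–500 nuclei (2000 for scaling
checks of the ideal-chain law), 20 replicate cohorts for border-recovery
rates, and 5 embedding seeds for segregation statements — sizes at which
every statistic's sampling error is well below the asserted margins.
Degenerate inputs are defined rather than crashed on: empty sample sets
give missing values, a nucleus with fewer than two detected barcodes keeps
an all-missing matrix (with a warning), and zero distances are excluded
from reciprocal-based statistics. All tolerances used in tests are stated
in the tests themselves.
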