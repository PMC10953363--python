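# Methods

polarscope implements the two computational arms of a comparative study
of cultured human macrophage subtypes (unstimulated MØ, IFNγ-driven M1,
IL-4-driven M2a, dexamethasone-driven M2c): (1) processing of multiplexed
(TMT-style) protein-abundance tables into a core/differential proteome
partition and a surfaceome view, and (2) label-free quantification of
cell motility from phase-contrast time-lapse videos. Both arms ship with
synthetic-data generators carrying exact ground truth, so every stage is
verifiable without external downloads.

## Proteome processing model

The input is a nonnegative proteins × samples abundance matrix with a
design table assigning each sample a subtype, donor and control flag.
The chain is deterministic and parameter-light:

1. **Total-abundance normalization.** Each sample column is rescaled so
   all column totals equal the mean of the original totals. This absorbs
   loading/labeling differences exactly (multiplying any raw column by a
   positive constant provably leaves every downstream log2FC unchanged)
   while preserving within-sample proportions.
2. **Control-referenced fold change.** For every non-control sample,
   each protein's abundance is divided by the mean abundance of that
   protein across the control (MØ) samples, then log2-transformed. Any
   number n ≥ 1 of controls is supported. Proteins with a zero control
   mean have no defined reference and are dropped with a report; no
   pseudo-count is added, because any imputation would silently
   manufacture fold changes for exactly the proteins where the data are
   weakest. Zero abundances in non-control samples become missing values
   rather than −∞.
3. **Median centering.** Each sample column's median log2FC is
   subtracted, making per-sample medians exactly zero. Under the
   assumption that most proteins are unchanged, this removes residual
   per-sample offsets.
4. **Subtype aggregation.** Per-subtype mean log2FC across donors;
   when a replicate is missing, the mean of the finite replicates is
   used and a completeness count is recorded.
5. **Polarity calls.** A protein is *up* in a subtype when its mean
   log2FC ≥ +1 and *down* when ≤ −1 (thresholds and boundary
   inclusivity configurable). The boundary is inclusive by default; the
   distinction is immaterial for continuous data but is pinned down and
   tested exactly. The *core proteome* is the set of proteins unchanged
   in every subtype; its complement is the differential set. The two
   sets always partition the classified proteins.
6. **Surfaceome filtering.** An identifier whitelist (a cell-surface
   protein atlas, e.g. CSPA-style gene-symbol lists) restricts any
   fold-change matrix or identifier set, with case-insensitive matching
   and a retained/total report. Matching is by gene symbol by default;
   the caller owns namespace consistency.
7. **Views.** Hierarchical clustering leaf order (complete linkage on
   Euclidean distances by default — the common default of heatmap
   tools; configurable) and PCA of samples on centered protein features
   with a deterministic sign convention (the largest-magnitude loading
   of each component is made positive).

"Differential" here is the threshold rule, not a hypothesis test: the
sets this workflow reports downstream (heatmaps, overlap counts, the
core proteome) are defined by the |mean log2FC| ≥ 1 cut. A
nonparametric group-comparison wrapper is available separately in
`assay_stats` but is not part of the canonical counts.

## Imaging model

Per-frame detection follows a marker-controlled watershed chain on
phase-contrast frames, preceded by translation-only drift correction:

- **Drift.** Subpixel phase cross-correlation of each frame against
  frame 0 yields per-frame (dx, dy); frames are realigned by the negated
  shift (linear interpolation). The estimator's contract — planted
  translations recovered within 0.5 px — is what the tests pin down.
  Registration presumes some static scene content (plate texture,
  debris), which real fields and the synthetic renderer both provide.
- **Foreground.** Gaussian-weighted local variance (σ = 5 px; E[x²] −
  E[x]² under a Gaussian window) lifts textured cells off the
  homogeneous background; Otsu thresholding and hole filling give the
  binary mask. The variance window inflates each object by a halo
  roughly σ wide; areas are therefore reported in detector px², and the
  cell/cluster size cuts below are applied to these detected areas.
- **Landscape.** Difference of Gaussians, blur(σ=1) − blur(σ=7),
  inverted and min–max rescaled to the full 8-bit range, so cell bodies
  become deep minima. DoG conventions with a single quoted σ vary
  between tools; both σ values are exposed.
- **Markers.** Extended minima in the classical sense: regional minima
  of the h-minima transform (morphological reconstruction by erosion of
  landscape + h over the landscape), with default depth h = 10 of 255.
  This definition merges basins separated by ridges shallower than h —
  including the ridge pixels — which is what makes seeding insensitive
  to h across a broad band (results are stable for h ∈ [5, 30] on the
  synthetic fixtures).
- **Splitting and classing.** Foreground components smaller than
  2000 px² are split by marker-controlled watershed restricted to the
  component (markerless components pass through whole); components at or
  above 2000 px² are left unsplit, because watershed output on dense
  clumps is unreliable, and are classed as *clusters*. Objects below
  200 px² are discarded as noise; [200, 2000) px² are *cells*. Both
  boundaries are inclusive on the low side and tested at exact integer
  areas. Splitting never alters the union of foreground pixels.
- **Tracking.** Frame-to-frame linear assignment on squared centroid
  distances (Jaqaman-style LAP): links beyond `max_link_distance`
  (default 50 px) are forbidden, and each detection may start/end a
  track at alternative cost `max_link_distance²`. On instances small
  enough to enumerate, the assignment provably matches the brute-force
  optimum. Cells and clusters are linked in separate pools; there is no
  gap closing, merging or splitting by default (a one-frame gap option
  exists). Tracks observed in fewer than 5 frames are discarded.
- **Motility statistics.** Per track: mean speed (mean consecutive-step
  displacement per frame interval; the default interval is 20 min),
  total path length, and Euclidean start-to-end distance (always ≤ path
  length). Per field: arithmetic means over retained tracks; fields with
  no tracks are reported missing, not zero. Cluster tracks are excluded
  from field means unless requested.

## Assay utilities

`auc_trapezoid` integrates a chemiluminescence time series (e.g. a
100-min respiratory-burst recording at 2.5-min intervals) by the
trapezoidal rule; linearity and interval additivity are exact.
`compare_groups` wraps the Kruskal–Wallis omnibus test with Dunn's
rank-based pairwise z-tests (tie-corrected, Bonferroni-adjusted by
default; the adjustment method is a parameter). The Dunn statistics are
computed directly from pooled ranks — a few lines over scipy's rank
machinery — and the omnibus test and multiplicity adjustment delegate to
scipy and statsmodels. A paired mode (Friedman + Wilcoxon) is provided
for completeness.

## Synthetic data: what it emulates, and what it does not

**Proteome generator.** Baseline abundances are log-normal (log2 mean
10, sd 2), spanning a realistic TMT dynamic range. A planted core
fraction (default 0.5) carries zero effect; each remaining protein is
assigned to exactly one subtype with a ±`effect_log2fc` (default 2)
effect of random sign. Replicate values multiply in log-normal noise
(default sd 0.3 log2 units) and a per-sample loading factor drawn
uniformly from [1 − spread, 1 + spread]. The default design — three
subtypes, three donors, two controls — mirrors a single multiplexed
batch. A `frac_surface` of 0.15 of proteins is flagged surface-localized
to exercise atlas filtering. Not emulated: missing-value mechanisms
beyond zeros, reporter-ion interference between channels, batch
structure across plexes, or correlated (pathway-level) effects — so
recovery rates here speak to the processing chain's correctness, not to
performance on biology with correlated effect structure.

**Video generator.** Cells are static textured patches — a bright
radial dome (the cell body a band-pass detector keys on) over fine
speckle giving high local variance — moved over a background composed of
a frozen spatial texture (illumination mottle/plate debris) plus
per-frame temporal noise. Motion is a persistent random walk with exact
step length `speed` (heading blends the previous direction with a
random one at weight `persistence`, default 0.9); cells reflect at the
borders and the truth records the reflected positions. Optional stage
drift translates the entire rendered scene — background texture
included — while truth tracks stay drift-free. A cluster fraction
places cells touching a partner and co-moving so the pair stays merged.
Rendering quantizes cell positions to integer pixels; the subpixel
truth is kept, which bounds per-frame centroid error at ~0.5 px and is
part of why recovered speeds sit within a few percent of planted
values. Not emulated: phase-contrast halo artifacts, cell shape change,
division/death, or photobleaching. Default scale (10 cells of radius
12 px in 512 × 512 over 40 frames at 20 min/frame) keeps density low;
at high densities frequent contacts would make identity switches more
likely than these tests show.

## Numerical and design choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical parameters + seed give
  byte-identical outputs.
- Coordinates are 0-based pixel centers, x = column, y = row, origin
  top-left; areas in px²; speeds in px per frame interval with px/min
  derived via the frame interval. No physical (µm) calibration is
  assumed.
- Variance filtering operates on the raw intensity scale (no
  pre-rescaling); the 8-bit conversion applies only to the DoG
  landscape, whose min–max rescale uses each frame's own range.
- Connected components and watershed use 8-connectivity by default
  (configurable to 4).
- Ties in hierarchical clustering follow scipy's deterministic
  lowest-index-first behavior; PCA signs follow the
  largest-loading-positive convention.
- Problem sizes in the test and acceptance runs (1000-protein matrices;
  one 40-frame 512² video) were chosen as the smallest scales at which
  the planted-recovery statements are stable across seeds.

## Known limitations

- The threshold classifier reports no uncertainty; donor-level
  variability only enters through the mean.
- Drift estimation assumes a translation-only model and some static
  scene content; rotating or scaling drift is out of scope.
- The tracker has no gap closing beyond one optional frame and no
  merge/split events, so a cell lost for two frames starts a new track.
- Segmentation areas are detector areas (variance halo included), so
  absolute areas are not directly comparable to hand-annotated cell
  outlines, though the size-class boundaries are applied consistently.
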