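# Methods

## The model

A brick plot summarizes the phenotype of one cell cluster as a 2-D "barcode":
every measured marker is a square brick, positioned by how that marker
co-varies with every other marker *across the whole dataset*, and sized by the
cluster's own expression of it. The inputs are a clusters-by-markers table of
median expression — anything downstream of any clustering tool (x-shift,
FlowSOM, Phenograph, ...) that can export such a table works.

The pipeline has two halves with a clean contract between them.

### Dataset-level marker layout (computed once, reused by every cluster)

1. **Transform.** Raw ion counts are transformed cell-wise with
   `asinh(x / cofactor)`. The cofactor (default 5, the CyTOF convention, in
   ion counts) sets where the transform stops being linear; the transform is
   skipped if the caller declares the table pre-transformed.
2. **Correlation.** Pearson correlation between every pair of marker columns,
   across clusters, giving a symmetric matrix in [-1, 1]. This is computed
   *before* the zeroing threshold: zeroing is a display-noise rule, and
   applying it first would censor exactly the low-expression variation the
   correlations need. Spearman is available behind a flag for heavy-tailed
   panels. A marker with zero variance across clusters has no defined
   correlation; it gets 0 off-diagonal with a warning rather than being
   dropped, so the table and the layout stay aligned (its bricks are
   typically zeroed anyway).
3. **PCA.** Markers are the observations and each marker's row of
   correlations is its feature vector. Rows are column-centered but not
   re-scaled — they already share the [-1, 1] scale, and re-scaling would
   inflate noise directions. PC1/PC2 coordinates place the markers;
   `var_pct_k = 100 * lambda_k / sum(lambda)` annotates the axes. Two markers
   with identical co-expression profiles land on exactly the same point,
   which is the property the layout exists to convey. Eigenvectors are
   sign-ambiguous, so each component is flipped to make its
   largest-magnitude loading (first such index on ties) positive; with that
   rule the layout is reproducible to 1e-12 across runs and BLAS builds.
4. **Grouping.** K-means (squared Euclidean, 10 seeded k-means++ restarts per
   k) is run over up to 30 integer k values evenly spaced between 1 and the
   number of markers, and the elbow of the WCSS curve selects k. The elbow is
   formalized as the interior k maximizing the discrete second difference of
   **log** WCSS, ties to the smallest k. The log scale matters: WCSS decays
   roughly geometrically on clustered data, so on the raw scale the enormous
   absolute drop from k=1 to k=2 dominates the curvature and drags the elbow
   to k=2 regardless of the true structure; the log second difference is
   scale-invariant and, on the synthetic block fixtures below, recovers the
   planted block count in every seed tested where the raw-scale rule failed a
   quarter of the time. When fewer than three k values are testable (e.g.
   all markers coincide), the smallest k reaching the minimum WCSS is used.
   K-means runs on the 2-D (PC1, PC2) coordinates by default — the groups
   are a coloring of the plotted positions, so clustering the positions keeps
   colors and geometry consistent; clustering the full correlation rows is
   available behind a flag. Group labels are renumbered 1..k in order of
   first appearance in marker order, another determinism guarantee.

### Per-cluster geometry

5. **Threshold.** Arcsinh values strictly below `zero_cutoff` (default 1.0,
   an empirical ceiling for background signal; user-adjustable per panel) are
   set to exactly zero, per cell — a marker may be zeroed in one cluster and
   present in another. The boundary survives: "below" is read as strict
   less-than. Zero value = no brick.
6. **Sizing.** Brick *area* is proportional to the thresholded value:
   `area = s * value` with one scale factor `s` for the entire dataset,
   chosen so the single largest brick anywhere has side
   `max_area_fraction * span` (default fraction 0.2; span = the larger
   coordinate range of the layout). A single global `s` is what makes the
   same marker's brick comparable *between* cluster plots; per-marker
   max-normalization — comparable within a marker, not between markers — is
   available behind a flag. Bricks are squares (`side = sqrt(area)`); a
   width/height aspect knob exists for stylistic tweaks.
7. **Overlap resolution.** Correlated markers sit close together, so bricks
   overlap. Resolution is a deterministic local rule, not a global
   optimization: bricks that overlap nothing are immovable; the remaining
   bricks are placed largest-first (ties by marker name), and a brick landing
   on an already-placed one is translated along the ray from the blocker's
   center through its own original center until exactly edge-adjacent
   (coincident centers fall back to +x). Cascading collisions repeat the
   push up to 64 times, after which a deterministic ring search around the
   original center (32 fixed angles, radius growing in quarter-side steps)
   takes the nearest free spot. Displacement never rescales — area
   proportionality is exact post-resolution — and "disjoint" means open
   interiors disjoint with 1e-9 slack, so shared edges are allowed. If the
   search budget is exhausted (total brick area exceeding the canvas) the
   error advises a smaller `max_area_fraction`.

Rendering is a pure consumer of the serialized plot: one rectangle per
non-zeroed brick (tagged `gid="brick__<marker>"` in the SVG, so structure is
machine-checkable), filled by group color, equal-aspect axes labeled
"PC1/PC2 (x% variance)". Label collisions are deliberately not auto-resolved
beyond a fixed below-brick offset.

## Synthetic data generator

`brickplot.synthetic` emulates the structure the method assumes: blocks of
markers that rise and fall together across clusters (lineage programs), plus
always-negative markers. Each block shares a per-cluster latent factor
`z_c ~ N(0,1)`:

    value(c, m) = max(0, base + noise_sd * (sqrt(rho) * z_c + sqrt(1 - rho) * eps))

which gives population correlation exactly `rho` between block-mates and 0
between blocks. Negative markers are drawn uniformly in
`[0, 0.5 * zero_cutoff]` so thresholding removes them entirely. Defaults —
40 clusters, three 5-marker blocks at arcsinh baselines 3.0/2.2/1.6,
`rho = 0.9`, `noise_sd = 0.3`, two negative markers — are the scale of a
15-20 parameter panel, with the lowest block deliberately straddling the
zeroing cutoff. The zero-clip slightly biases correlations when `noise_sd`
is large relative to the baselines; defaults keep it negligible.

What the generator does *not* emulate: instrument effects (spillover, bead
drift, barcoding artifacts), non-Gaussian expression distributions,
overlapping or hierarchical marker programs, and negative between-block
correlations. Tests passing on these fixtures therefore demonstrate that the
algorithms are implemented correctly and recover planted structure under the
model's own assumptions — not that real panels always present such clean
block structure.

## Numerical choices and degenerate inputs

- Correlation entries are clipped to [-1, 1] and symmetrized to kill
  float-roundoff asymmetry; the diagonal is exactly 1.
- Fewer than 3 clusters is an error for correlation (on 2 points every
  correlation is +/-1); fewer than 3 markers is an error for layout.
- A rank-0 centered correlation matrix (all markers identical) is an error:
  there is no layout to draw.
- Even-count medians are the midpoint of the two central order statistics.
- Missing/non-numeric cells are rejected with their (row, col) location,
  never imputed — silent imputation would corrupt the correlations.
- Seeds feed `numpy` generators and scikit-learn's `KMeans` directly; every
  derived seed is masked below 2^31.

## Problem sizes used in the test suite

Tests run at desk scale: 100-table oracle sweeps at 10 clusters x 12 markers,
recovery studies at 50 seeds of 40 clusters x 15 markers, 200 randomized
overlap configurations of up to 20 bricks, and one 50-cluster x 40-marker
end-to-end run (8 blocks of 5), the size of a large CyTOF panel.

## Known limitations

- The elbow rule cannot select the endpoints of the tested k range (second
  differences need an interior point); with very few distinct marker
  positions the fallback rule applies.
- Overlap resolution is a local adjacency rule; it minimizes nothing
  globally, and crowded plots (many mutually correlated, highly expressed
  markers) can push bricks far from their layout positions — the `displaced`
  flag records exactly which ones.
- Brick label overlap is not resolved; dense plots may need manual label
  adjustment in a vector editor.
- Group colors cycle when k exceeds the palette length.
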