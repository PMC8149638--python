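# Methods

## Model and procedure

The package tests cross-type spatial attraction between two point
patterns on a masked raster: markers (cells) and references (objects),
both given as 0-based integer (row, col) pixel coordinates inside a
binary ROI. Sub-pixel input coordinates are snapped to the nearest
pixel center, ties rounding half away from zero.

**Distance transform.** The per-pixel distance to the nearest reference
is the geodesic chessboard distance: the minimum number of 8-connected
steps, each of unit cost whether axial or diagonal, along a path that
stays on ROI pixels. This is implemented as a multi-source
breadth-first search computed one distance level at a time with a full
3×3 binary dilation masked to the ROI, which is exact for unit step
costs. Design points that matter:

- 8-connectivity with unit diagonal cost *is* the chessboard (Chebyshev)
  metric; on an obstacle-free mask the transform equals
  max(|Δr|, |Δc|) to the nearest seed, which the tests check exactly.
- References are single-pixel seeds by default (dot annotations); a
  boolean raster can be passed instead for multi-pixel objects.
- Seed pixels remain traversable — paths may cross reference pixels.
- Pixels with no ROI-internal path to any seed carry an `inf` sentinel,
  written as NaN in the float-TIFF serialization. Markers on such
  pixels are excluded from the mean and their count is reported; the
  null replicates apply the same exclusion, so both sides of the test
  see the same rule.
- Distances are computed in pixel steps and multiplied by the pixel
  size (µm/px) only at reporting time.

**Statistic and null.** The per-sample statistic is the mean of the
finite per-marker distances. The null fixes the references, computes
their distance field once, and redraws the same number of marker
positions independently and uniformly over ROI pixels (with
replacement; coincidences with each other or with reference pixels are
allowed) B times, recording each replicate's mean. The empirical
one-sided p-value uses the add-one rule p = (1 + #{D̄_b ≤ D̄_obs})/(B+1):
never zero, ties counted conservatively. Which set is randomized is
configurable; the default randomizes the markers and keeps the
references fixed, matching the plotted analysis this mirrors. The
flipped convention recomputes a distance field per replicate and is
B times more expensive.

**Follow-up tests.**
- *Pooled per-cell test*: unpaired two-sided Student's t (pooled
  variance; Welch behind a flag) of the n observed per-marker distances
  against the k·n distances pooled from the first k replicates
  (k default 10, the replicate order being part of the seeded RNG
  stream). With n = 28 markers this gives the 28-vs-280 design.
- *Per-sample cohort test*: paired two-sided Student's t across samples
  of observed mean vs the sample's own null mean-of-means (unpaired by
  flag; pairing is the natural choice since each sample is matched to
  its own randomizations). All-zero differences report t = 0, p = 1
  rather than failing.
- *Count correlation*: Spearman rank correlation (average ranks for
  ties, Pearson on ranks) of per-sample marker counts vs reference
  counts, with a permutation p-value for small cohorts — exact
  enumeration for n ≤ 8, 9999 seeded Monte-Carlo pairings for n = 9–10,
  t approximation above. Constant inputs are reported as undefined
  (NaN) rather than raising.

**Load quantification.** A grayscale image is segmented by a strict
`value > threshold` comparison (the threshold is a required input; no
automatic selection). Load is the percentage of region pixels positive
in the resulting mask. Per-object local regions are discs of fixed
physical diameter (default 100 µm) around each object center,
membership by pixel-center Euclidean test (inclusive), clipped — not
rejected — at image borders.

## Synthetic data generator

The generator emulates the study-scale inputs so every stage runs
without any download, and doubles as the calibration/power harness.
Per sample it produces:

- an ROI: a full rectangle, or a blob obtained by thresholding a
  radially decaying field perturbed by smoothed Gaussian noise, reduced
  to its largest 8-connected component, with 1–3 disc-shaped interior
  holes standing in for excluded artefacts. A guard keeps the interior
  at ≥ 30% of the grid.
- references: uniform draws over ROI pixels.
- markers: CSR (uniform over ROI pixels), or clustered — with
  probability 1 − π₀ a marker picks a reference uniformly and lands at
  an isotropic half-normal displacement (radius |N(0, σ)|, uniform
  angle), re-drawing the displacement up to 100 times until it lands on
  the ROI and falling back to CSR after that, so counts are exact; with
  probability π₀ it is CSR ("background" cells).

Defaults are the study-scale conditions: 5 samples on 512×512 grids,
131 references and 642 markers per sample (the AD preset pins the exact
totals 655 and 3209 by largest-remainder splitting, hence one sample
with 641 markers), σ = 10 px, π₀ = 0.1. The control preset has 5
samples, 55 CSR markers in total and 3 references per sample — a
minimal reference count chosen only so the pipeline runs on
control-like data. The half-normal kernel was chosen as the simplest
isotropic attraction model with a single scale parameter; π₀ spans
effect sizes for power studies. Optional Poisson jitter of per-sample
counts is off by default so preset totals stay exact.

What the generator does *not* emulate: image intensities for the
proximity test (annotations are the inputs), anisotropy, spatial
inhomogeneity of the background intensity, object size/shape, edge
effects beyond the ROI mask, or any mechanistic biology. Passing tests
therefore show the statistical machinery is correct and calibrated
under these point-process assumptions, not that the biological claim
holds in new tissue.

## Numerical and reproducibility choices

- RNG: NumPy PCG64 generators throughout. Cohort generation spawns one
  child stream per sample from the master seed; the pipeline derives
  per-sample test seeds as `SeedSequence([master_seed, sample_index])`
  reduced below 2³¹. Identical config + seed yields bit-identical null
  distributions and byte-identical report files (no timestamps;
  floating-point report fields rounded to 6 decimals on write).
- The empirical p-value is exactly uniform on {1/(B+1), …, 1} under
  exchangeability, hence slightly conservative at thresholds between
  grid points; with B = 500 the attainable minimum is 1/501.
- Degenerate inputs: empty ROI, empty seed set, empty marker set, and
  off-ROI points raise validation errors naming the offending point or
  line; a failing sample inside a cohort run is recorded and the run
  continues, with the partial failure flagged in the report and exit
  code.
- Problem sizes for the heavier checks: type-I calibration uses 200
  single-sample CSR cohorts at 256×256 with 131/642 points and B = 200;
  the power study uses 50 seeds per σ ∈ {40, 20, 10} px at the
  512×512 defaults with B = 199 (p resolution 0.005). These sizes are
  the package's chosen trade-off between Monte-Carlo resolution and
  runtime on a single CPU.

## Known limitations

- 2-D only; no Euclidean distance transform (the chessboard metric
  over-counts diagonals by up to √2 relative to Euclidean length).
- No segmentation: cell and object annotations are inputs.
- No tissue-edge correction beyond the ROI mask itself, and no
  multiple-testing correction across samples.
- No spatial summary curves (Ripley K, G-function envelopes); the test
  addresses one alternative (marker–reference attraction) through one
  statistic, and a CSR null over ROI pixels ignores e.g. exclusion
  between cells.
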