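"""Proximity test on a single synthetic sample.

Generates one AD-like tissue sample (an irregular ROI with holes, 131
plaque-like reference points, 642 marker cells clustered around them),
measures each marker's shortest geodesic chessboard distance to the
nearest reference, and compares the mean against 500 randomizations of
the marker positions over the ROI.
"""

import numpy as np

from plaqueprox import (
    SyntheticConfig,
    empirical_p,
    make_roi,
    null_distribution,
    observed_statistic,
    place_markers,
    place_references,
)

cfg = SyntheticConfig(grid_shape=(512, 512), sigma=10.0, seed=0)
rng = np.random.default_rng(cfg.seed)

roi = make_roi(cfg, rng, sample_id="demo")
references = place_references(roi, cfg.n_references, rng)
markers = place_markers(roi, references, cfg, rng)

observed = observed_statistic(roi, references, markers)
null = null_distribution(roi, references, n_markers=len(markers), B=500, seed=1)
p = empirical_p(observed, null)

print(f"ROI: {roi.n_interior} of {roi.grid.size} pixels analysable")
print(f"{len(markers)} markers vs {len(references)} references")
print(f"observed mean shortest distance: {observed.mean_distance:.2f} px")
print(f"null mean over 500 randomizations: {null.null_mean:.2f} px "
      f"(range {null.replicate_stats.min():.2f}-{null.replicate_stats.max():.2f})")
print(f"empirical p = {p:.4g}")
print("-> markers sit far closer to the references than a uniform "
      "re-scatter of the same number of cells would place them.")
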