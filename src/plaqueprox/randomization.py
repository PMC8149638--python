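"""Monte-Carlo proximity test against a fixed-reference randomization null.

The observed statistic for a sample is the mean shortest geodesic
(chessboard) distance from each marker cell to the nearest reference
object.  The null fixes the reference positions, redraws the same number
of marker positions uniformly over the ROI pixels B times (default 500),
and records the replicate means; the empirical one-sided p-value uses the
add-one rule

    p = (1 + #{replicate mean <= observed mean}) / (B + 1),

so p is never zero and ties count conservatively.  Two follow-up tests
mirror the study design: a pooled unpaired t-test of the observed
per-marker distances against the per-marker distances pooled from the
first k replicates (k default 10), and a paired t-test across samples of
observed mean vs null mean-of-means.  A Spearman correlation of marker
counts against reference counts across samples completes the summary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import (
    PointSet,
    ProximityResult,
    ROIMask,
    geodesic_distance_transform,
    shortest_distances,
)

__all__ = [
    "NullDistribution",
    "TestResult",
    "CohortSummary",
    "observed_statistic",
    "randomize_markers",
    "null_distribution",
    "empirical_p",
    "pooled_first_k_test",
    "per_sample_cohort_test",
    "count_correlation",
    "spearman_rho",
]


@dataclass
class NullDistribution:
    """B randomized-replicate statistics for one sample.

    ``replicate_stats`` holds the B per-replicate mean distances;
    ``replicate_distances`` retains the per-marker distances of the first
    ``first_k`` replicates (rows) for the pooled test.  ``p_value`` is
    filled in by :func:`empirical_p`.
    """

    sample_id: str
    B: int
    replicate_stats: np.ndarray
    replicate_distances: np.ndarray
    rng_seed: int | None
    n_markers: int
    p_value: float | None = None

    @property
    def first_k_retained(self) -> int:
        return int(self.replicate_distances.shape[0])

    @property
    def null_mean(self) -> float:
        """Mean of the replicate means (the null expectation estimate)."""
        return float(np.nanmean(self.replicate_stats))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_observed: int
    n_random: int


@dataclass
class CohortSummary:
    """Per-sample table plus the pooled cohort-level test outputs."""

    per_sample: pd.DataFrame
    paired_statistic: float
    paired_p: float
    rho: float | None = None
    rho_p: float | None = None


def observed_statistic(
    roi: ROIMask, references: PointSet, markers: PointSet
) -> ProximityResult:
    """Mean shortest geodesic distance from each marker to the references.

    One distance-transform pass from the reference set, then a per-marker
    lookup; markers unreachable from every reference are excluded from
    the mean and counted.
    """
    field_ = geodesic_distance_transform(roi, references)
    return shortest_distances(field_, markers, roi=roi)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def randomize_markers(roi: ROIMask, n: int, rng_state) -> PointSet:
    """Draw ``n`` marker positions independently and uniformly over ROI pixels.

    Draws are with replacement: random markers may coincide with each
    other or with reference pixels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng_state)
    rows, cols = np.nonzero(roi.grid)
    idx = rng.integers(0, rows.size, size=n)
    return PointSet(
        np.column_stack([rows[idx], cols[idx]]), kind="marker", sample_id=roi.sample_id
    )


def null_distribution(
    roi: ROIMask,
    references: PointSet,
    n_markers: int,
    B: int = 500,
    seed=None,
    first_k: int = 10,
) -> NullDistribution:
    """Fixed-reference randomization null for the mean-distance statistic.

    The distance field from the references is computed once; each of the
    B replicates samples ``n_markers`` ROI pixels uniformly with
    replacement and records the mean of the finite per-marker distances
    (the same exclusion rule as the observed statistic).  Per-marker
    distances of the first ``first_k`` replicates are retained.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = _as_rng(seed)
    field_ = geodesic_distance_transform(roi, references)
    roi_dists = field_.values[roi.grid]  # flat distances over ROI pixels

    draws = rng.integers(0, roi_dists.size, size=(B, n_markers))
    rep = roi_dists[draws]
    finite = np.isfinite(rep)
    n_fin = finite.sum(axis=1)
    sums = np.where(finite, rep, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        stats_ = np.where(n_fin > 0, sums / np.maximum(n_fin, 1), np.nan)

    return NullDistribution(
        sample_id=roi.sample_id,
        B=B,
        replicate_stats=stats_,
        replicate_distances=rep[: min(first_k, B)].copy(),
        rng_seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_markers=n_markers,
    )


def null_distribution_randomized_references(
    roi: ROIMask,
    markers: PointSet,
    n_references: int,
    B: int = 500,
    seed=None,
    first_k: int = 10,
) -> NullDistribution:
    """Flipped convention: fix the markers, redraw the references.

    Each replicate needs its own distance transform, so this is B times
    the cost of :func:`null_distribution`; it exists because the study's
    written protocol can be read either way.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = _as_rng(seed)
    stats_ = np.empty(B)
    kept: list[np.ndarray] = []
    for b in range(B):
        refs = randomize_markers(roi, n_references, rng)
        refs = PointSet(refs.points, kind="reference", sample_id=roi.sample_id)
        res = observed_statistic(roi, refs, markers)
        stats_[b] = res.mean_distance
        if b < first_k:
            kept.append(res.distances)
    return NullDistribution(
        sample_id=roi.sample_id,
        B=B,
        replicate_stats=stats_,
        replicate_distances=np.array(kept) if kept else np.empty((0, len(markers))),
        rng_seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_markers=len(markers),
    )


def empirical_p(observed: ProximityResult, null: NullDistribution) -> float:
    """One-sided empirical p-value with the add-one correction.

    p = (1 + #{replicate mean <= observed mean}) / (B + 1); ties count as
    "<=", so the smallest attainable p is 1/(B+1) and the largest is 1.
    """
    k = int(np.sum(null.replicate_stats <= observed.mean_distance))
    p = (1 + k) / (null.B + 1)
    null.p_value = p
    return p


def pooled_first_k_test(
    observed: ProximityResult,
    null: NullDistribution,
    k: int = 10,
    welch: bool = False,
) -> TestResult:
    """Two-sided t-test of observed vs first-k pooled replicate distances.

    Compares the n observed per-marker distances against the k*n
    per-marker distances pooled from the first k replicates, with a
    pooled-variance Student's t by default (Welch by flag).  Identical
    groups report t = 0, p = 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > null.first_k_retained:
        raise ValueError(
            f"k={k} exceeds the {null.first_k_retained} replicates retained "
            "with per-marker distances"
        )
    obs = observed.finite_distances
    pool = null.replicate_distances[:k].ravel()
    pool = pool[np.isfinite(pool)]
    if obs.size == 0 or pool.size == 0:
        raise ValueError("no finite distances to compare")
    if np.ptp(obs) == 0 and np.ptp(pool) == 0 and obs[0] == pool[0]:
        return TestResult(0.0, 1.0, obs.size, pool.size)
    t, p = stats.ttest_ind(obs, pool, equal_var=not welch)
    return TestResult(float(t), float(p), int(obs.size), int(pool.size))


def per_sample_cohort_test(
    results: list[tuple[ProximityResult, NullDistribution]],
    paired: bool = True,
) -> CohortSummary:
    """Cohort-level comparison of observed means against null means.

    A paired two-sided Student's t-test across samples between each
    sample's observed mean distance and the mean of its own replicate
    means (unpaired by flag).  All differences zero (degenerate paired t)
    reports t = 0, p = 1.
    """
    if len(results) < 2:
        raise ValueError("cohort test needs at least 2 samples")
    rows = []
    for res, null in results:
        p = null.p_value if null.p_value is not None else empirical_p(res, null)
        rows.append(
            {
                "sample_id": res.sample_id,
                "n_markers": res.n_markers,
                "n_unreachable": res.n_unreachable,
                "observed_mean": res.mean_distance,
                "null_mean": null.null_mean,
                "B": null.B,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    obs = table["observed_mean"].to_numpy()
    nul = table["null_mean"].to_numpy()
    if paired:
        diffs = obs - nul
        if np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        elif np.ptp(diffs) == 0:  # constant non-zero difference: off-scale t
            t, p = math.copysign(math.inf, diffs[0]), 0.0
        else:
            t, p = stats.ttest_rel(obs, nul)
    else:
        t, p = stats.ttest_ind(obs, nul)
    return CohortSummary(per_sample=table, paired_statistic=float(t), paired_p=float(p))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation via average-rank transform + Pearson."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def count_correlation(
    per_sample_counts, seed: int = 0
) -> tuple[float, float]:
    """Spearman correlation of per-sample marker counts vs reference counts.

    For small cohorts (n <= 10) the two-sided p-value is computed by
    permutation of the pairing -- exactly for n <= 8, by 9999 seeded
    Monte-Carlo resamples for n = 9-10; larger n uses the usual
    t approximation.  A constant count vector has undefined rho, reported
    as NaN with p NaN.
    """
    pairs = np.asarray(list(per_sample_counts), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected a list of (n_markers, n_references) pairs")
    n = pairs.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")
    x, y = pairs[:, 0], pairs[:, 1]
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return rho, float("nan")

    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = spearman_rho(x, y[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif n <= 10:
        rng = np.random.default_rng(seed)
        m = 9999
        count = 0
        for _ in range(m):
            r = spearman_rho(x, rng.permutation(y))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (1 + count) / (m + 1)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(min(p, 1.0))
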