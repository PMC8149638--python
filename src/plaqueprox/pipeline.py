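"""Top-level pipeline: observed statistic -> null -> p-values -> summary.

Runs the full per-sample analysis (distance transform from the
references, per-marker shortest distances, B-fold randomization null,
empirical p), then the cohort-level comparisons: the pooled first-k
per-marker t-test, the paired per-sample t-test of observed mean vs null
mean-of-means, and the Spearman correlation of marker vs reference
counts.  Reports are deterministic for a given config + seed: per-sample
RNG streams are spawned from the master seed and no timestamps are
written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .randomization import (
    CohortSummary,
    NullDistribution,
    count_correlation,
    empirical_p,
    null_distribution,
    null_distribution_randomized_references,
    observed_statistic,
    per_sample_cohort_test,
    pooled_first_k_test,
)
from .spatial import PointSet, ProximityResult, ROIMask

log = logging.getLogger("plaqueprox")

__all__ = ["RunConfig", "SampleRun", "PipelineResult", "run_sample", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``randomize`` selects which point set the null redraws: ``"markers"``
    (references fixed; the default, matching the plotted analysis) or
    ``"references"`` (markers fixed; the flipped reading of the written
    protocol, B times more expensive).
    """

    B: int = 500
    first_k: int = 10
    seed: int = 0
    randomize: str = "markers"
    pixel_size: float | None = None
    welch: bool = False
    paired: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 1 <= self.first_k <= self.B:
            raise ValueError("first_k must satisfy 1 <= first_k <= B")
        if self.randomize not in ("markers", "references"):
            raise ValueError("randomize must be 'markers' or 'references'")


@dataclass
class SampleRun:
    sample_id: str
    observed: ProximityResult | None
    null: NullDistribution | None
    p_value: float | None
    pooled: "TestResult | None"
    n_references: int
    error: str | None = None


@dataclass
class PipelineResult:
    samples: list[SampleRun]
    summary: CohortSummary | None
    config: RunConfig
    n_failed: int

    @property
    def ok(self) -> bool:
        return self.n_failed == 0


def _sample_seed(master_seed: int, index: int) -> int:
    # stable per-sample seed below 2**31, independent of sample order changes upstream
    ss = np.random.SeedSequence([master_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sample(
    roi: ROIMask,
    references: PointSet,
    markers: PointSet,
    config: RunConfig,
    seed: int | None = None,
) -> SampleRun:
    """Full single-sample analysis: observed statistic, null, p, pooled test."""
    seed = config.seed if seed is None else seed
    observed = observed_statistic(roi, references, markers)
    if config.randomize == "markers":
        null = null_distribution(
            roi, references, n_markers=len(markers), B=config.B, seed=seed, first_k=config.first_k
        )
    else:
        null = null_distribution_randomized_references(
            roi, markers, n_references=len(references), B=config.B, seed=seed, first_k=config.first_k
        )
    p = empirical_p(observed, null)
    pooled = pooled_first_k_test(observed, null, k=config.first_k, welch=config.welch)
    log.info(
        "sample %s: n=%d markers, %d references, observed mean %.3f px, "
        "null mean %.3f px, p=%.4g (B=%d, seed=%d)",
        roi.sample_id, len(markers), len(references), observed.mean_distance,
        null.null_mean, p, config.B, seed,
    )
    return SampleRun(
        sample_id=roi.sample_id,
        observed=observed,
        null=null,
        p_value=p,
        pooled=pooled,
        n_references=len(references),
    )


def run_pipeline(samples, config: RunConfig) -> PipelineResult:
    """Run every sample, then the cohort-level tests; write reports if asked.

    ``samples`` is an iterable of ``(roi, references, markers)``.  A
    failing sample (e.g. missing reference points) is recorded and the
    run continues; ``PipelineResult.n_failed`` flags partial failure.
    """
    runs: list[SampleRun] = []
    for i, (roi, refs, marks) in enumerate(samples):
        try:
            runs.append(run_sample(roi, refs, marks, config, seed=_sample_seed(config.seed, i)))
        except (ValueError, RuntimeError) as exc:
            log.error("sample %s failed: %s", roi.sample_id, exc)
            runs.append(
                SampleRun(roi.sample_id, None, None, None, None, n_references=0, error=str(exc))
            )

    good = [r for r in runs if r.error is None]
    summary = None
    if len(good) >= 2:
        summary = per_sample_cohort_test(
            [(r.observed, r.null) for r in good], paired=config.paired
        )
        if len(good) >= 3:
            rho, rho_p = count_correlation(
                [(r.observed.n_markers + r.observed.n_unreachable, r.n_references) for r in good]
            )
            summary.rho, summary.rho_p = rho, rho_p
        summary.per_sample["n_references"] = [r.n_references for r in good]
        summary.per_sample["pooled_t"] = [r.pooled.statistic for r in good]
        summary.per_sample["pooled_p"] = [r.pooled.p_value for r in good]

    result = PipelineResult(
        samples=runs, summary=summary, config=config, n_failed=len(runs) - len(good)
    )
    if config.out_dir is not None:
        write_report(result, config.out_dir)
    return result


def _round6(x):
    if x is None:
        return None
    x = float(x)
    if not np.isfinite(x):
        return None
    return round(x, 6)


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write report.json, summary.csv and per-sample null histograms.

    Output is byte-identical across runs with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(result.config)
    cfg.pop("out_dir")  # a path, not analysis configuration; keeps reports comparable

    report: dict = {"version": __version__, "config": cfg, "samples": [], "n_failed": result.n_failed}
    hist_rows = []
    for r in result.samples:
        if r.error is not None:
            report["samples"].append({"sample_id": r.sample_id, "error": r.error})
            continue
        px = r.observed.pixel_size
        entry = {
            "sample_id": r.sample_id,
            "n_markers": r.observed.n_markers,
            "n_unreachable": r.observed.n_unreachable,
            "n_references": r.n_references,
            "observed_mean_px": _round6(r.observed.mean_distance),
            "null_mean_px": _round6(r.null.null_mean),
            "empirical_p": _round6(r.p_value),
            "pooled_t": _round6(r.pooled.statistic),
            "pooled_p": _round6(r.pooled.p_value),
            "pooled_n_observed": r.pooled.n_observed,
            "pooled_n_random": r.pooled.n_random,
            "B": r.null.B,
            "rng_seed": r.null.rng_seed,
        }
        if px != 1.0:
            entry["observed_mean_um"] = _round6(r.observed.mean_distance * px)
            entry["null_mean_um"] = _round6(r.null.null_mean * px)
        report["samples"].append(entry)

        finite = r.null.replicate_stats[np.isfinite(r.null.replicate_stats)]
        counts, edges = np.histogram(finite, bins=30)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append(
                {"sample_id": r.sample_id, "bin_low": round(float(lo), 6),
                 "bin_high": round(float(hi), 6), "count": int(c)}
            )

    if result.summary is not None:
        report["cohort"] = {
            "paired_t": _round6(result.summary.paired_statistic),
            "paired_p": _round6(result.summary.paired_p),
            "count_correlation_rho": _round6(result.summary.rho),
            "count_correlation_p": _round6(result.summary.rho_p),
            "n_samples": int(len(result.summary.per_sample)),
        }
        result.summary.per_sample.round(6).to_csv(out / "summary.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(hist_rows).to_csv(out / "null_histogram.csv", index=False)
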