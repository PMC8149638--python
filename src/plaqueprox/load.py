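"""Threshold-mask area quantification ("load").

Load is the percentage of a region's area occupied by above-threshold
staining: a grayscale image is segmented by a strict ``> threshold``
comparison into a binary mask and the positive fraction is measured over
the region's pixels.  Discs of fixed physical diameter (default 100 µm)
centered on reference objects support per-object local loads; discs are
clipped, not rejected, at image borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial import ROIMask

__all__ = [
    "AreaMeasurement",
    "threshold_mask",
    "load_percentage",
    "disc_region",
    "disc_loads",
    "area_correlation",
]

DEFAULT_DISC_DIAMETER_UM = 100.0


@dataclass(frozen=True)
class AreaMeasurement:
    """Positive-area fraction of one region.

    ``load`` is ``positive_area / region_area * 100`` in percent;
    ``*_um2`` fields scale pixel counts by ``pixel_size**2``.
    """

    region_id: str
    region_area: int
    positive_area: int
    load: float
    pixel_size: float = 1.0

    @property
    def region_area_um2(self) -> float:
        return self.region_area * self.pixel_size**2

    @property
    def positive_area_um2(self) -> float:
        return self.positive_area * self.pixel_size**2


def threshold_mask(image, threshold: float) -> np.ndarray:
    """Binary segmentation: pixel True iff its value is strictly above threshold."""
    return np.asarray(image) > threshold


def load_percentage(mask, region: ROIMask) -> AreaMeasurement:
    """Percent of region pixels that are positive in the binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != region.shape:
        raise ValueError(f"mask shape {mask.shape} != region shape {region.shape}")
    region_area = region.n_interior
    positive = int((mask & region.grid).sum())
    return AreaMeasurement(
        region_id=region.sample_id,
        region_area=region_area,
        positive_area=positive,
        load=100.0 * positive / region_area,
        pixel_size=region.pixel_size,
    )


def disc_region(
    center: tuple[int, int],
    radius_um: float,
    pixel_size: float,
    bounds: tuple[int, int],
    region_id: str = "",
) -> ROIMask:
    """Disc of given physical radius around a pixel, clipped to the raster.

    A pixel belongs to the disc when its center lies within Euclidean
    distance ``radius_um / pixel_size`` (in pixels, inclusive) of the
    given center.  The default study usage is a 100 µm-diameter
    circumference drawn at each plaque center.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    nr, nc = bounds
    r0, c0 = center
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ValueError(f"disc center {center} outside bounds {bounds}")
    radius_px = radius_um / pixel_size
    rr, cc = np.ogrid[:nr, :nc]
    grid = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    return ROIMask(grid, pixel_size=pixel_size, sample_id=region_id)


def disc_loads(
    mask,
    centers,
    pixel_size: float,
    diameter_um: float = DEFAULT_DISC_DIAMETER_UM,
) -> list[AreaMeasurement]:
    """Per-object local loads in fixed-diameter discs around each center."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    for i, (r, c) in enumerate(np.asarray(centers, dtype=int)):
        disc = disc_region(
            (int(r), int(c)), diameter_um / 2.0, pixel_size, mask.shape, region_id=f"disc_{i}"
        )
        out.append(load_percentage(mask, disc))
    return out


def area_correlation(pairs, method: str = "spearman") -> tuple[float, float]:
    """Correlation between two per-region area measurements.

    Spearman by default (the study correlates Thio-S+ area with IB4+
    area per region), Pearson by flag.  Constant input has undefined
    correlation, reported as (NaN, NaN).
    """
    from scipy import stats

    from .randomization import count_correlation

    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected a list of (area_a, area_b) pairs")
    if pairs.shape[0] < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if method == "spearman":
        return count_correlation(pairs)
    if method == "pearson":
        x, y = pairs[:, 0], pairs[:, 1]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    raise ValueError(f"unknown method {method!r}")
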