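"""Grid geometry and the geodesic chessboard distance transform.

The analysable tissue region is a binary raster (:class:`ROIMask`); marker
cells and reference objects (e.g. amyloid plaques) are integer pixel point
sets (:class:`PointSet`).  Distances are measured in 8-connected steps of
unit cost -- the chessboard (Chebyshev) metric -- along paths confined to
the ROI, so excluded artefact regions and holes force detours.  On an
obstacle-free grid the geodesic distance reduces to the closed form
``max(|dr|, |dc|)`` to the nearest seed.

Pixels with no ROI-internal path to any seed carry the sentinel
:data:`UNREACHABLE` (``inf``), which is mapped to NaN on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "UNREACHABLE",
    "ROIMask",
    "PointSet",
    "DistanceField",
    "ProximityResult",
    "build_roi",
    "geodesic_distance_transform",
    "shortest_distances",
    "round_half_away",
]

#: Sentinel distance for pixels not path-connected to any seed.
UNREACHABLE: float = float("inf")

_FULL_3X3 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

_POINT_KINDS = ("marker", "reference")


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going away from zero.

    Sub-pixel coordinates in input tables are snapped to pixel centers with
    this rule (``np.round`` rounds half to even, which would shift ties).
    """
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass(frozen=True)
class ROIMask:
    """Binary raster of analysable tissue pixels for one sample.

    Parameters
    ----------
    grid
        2-D boolean array; ``True`` marks pixels inside the region of
        interest (tissue minus artefacts and empty regions).
    pixel_size
        Physical side length of a pixel in µm.  Distances are computed in
        pixel steps and scaled by this factor only at reporting time.
    sample_id
        Free-text sample label carried through to results.
    """

    grid: np.ndarray
    pixel_size: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("ROI raster must be a non-empty 2-D array")
        grid = grid.astype(bool).copy()
        if not grid.any():
            raise ValueError(f"empty ROI: no interior pixels (sample {self.sample_id!r})")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_interior(self) -> int:
        """Number of interior (True) pixels."""
        return int(self.grid.sum())


@dataclass(frozen=True)
class PointSet:
    """Labelled set of integer pixel coordinates tied to one sample.

    ``points`` is an ``(n, 2)`` array of 0-based ``(row, col)`` indices;
    duplicates are allowed and ``n`` may be zero.  ``kind`` is either
    ``"marker"`` (the cells whose proximity is tested) or ``"reference"``
    (the objects distances are measured to).
    """

    points: np.ndarray
    kind: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _POINT_KINDS:
            raise ValueError(f"kind must be one of {_POINT_KINDS}, got {self.kind!r}")
        pts = np.asarray(self.points)
        if pts.size == 0:
            pts = np.empty((0, 2), dtype=np.int64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if not np.issubdtype(pts.dtype, np.integer):
            if not np.allclose(pts, np.round(pts)):
                raise ValueError(
                    "points must be integer pixel indices; use PointSet.from_floats "
                    "to snap sub-pixel coordinates"
                )
            pts = pts.astype(np.int64)
        else:
            pts = pts.astype(np.int64, copy=True)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_floats(cls, coords, kind: str, sample_id: str = "") -> "PointSet":
        """Build a point set from possibly sub-pixel coordinates.

        Coordinates are rounded to the nearest pixel center, ties away
        from zero.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.size == 0:
            coords = np.empty((0, 2))
        return cls(round_half_away(coords), kind=kind, sample_id=sample_id)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    def validate_on(self, roi: ROIMask) -> None:
        """Raise if any point is out of bounds or off the ROI, naming it."""
        rows, cols = self.points.T if len(self) else (np.empty(0, int), np.empty(0, int))
        nr, nc = roi.shape
        oob = (rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)
        if oob.any():
            i = int(np.argmax(oob))
            raise ValueError(
                f"{self.kind} point {tuple(int(v) for v in self.points[i])} outside raster bounds "
                f"{roi.shape} (sample {self.sample_id or roi.sample_id!r})"
            )
        off = ~roi.grid[rows, cols]
        if off.any():
            i = int(np.argmax(off))
            raise ValueError(
                f"{self.kind} point {tuple(int(v) for v in self.points[i])} lies off the ROI "
                f"(sample {self.sample_id or roi.sample_id!r})"
            )


@dataclass(frozen=True)
class DistanceField:
    """Per-pixel geodesic chessboard distances from a seed set.

    ``values`` is a float array over the full raster: 0 at seed pixels,
    the minimum number of 8-connected ROI-internal steps to any seed on
    reachable ROI pixels, and :data:`UNREACHABLE` elsewhere (off-ROI
    pixels and ROI components containing no seed).
    """

    values: np.ndarray
    seeds: PointSet
    metric: str = "chessboard-geodesic"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class ProximityResult:
    """Per-marker shortest distances and the per-sample mean statistic.

    ``distances`` keeps one entry per input marker (``inf`` where the
    marker sits in an ROI component with no reference); ``mean_distance``
    averages the finite entries only, ``n_markers`` counts them and
    ``n_unreachable`` counts the excluded ones.
    """

    sample_id: str
    distances: np.ndarray
    mean_distance: float
    n_markers: int
    n_unreachable: int
    pixel_size: float = 1.0

    @property
    def mean_distance_um(self) -> float:
        return self.mean_distance * self.pixel_size

    @property
    def finite_distances(self) -> np.ndarray:
        return self.distances[np.isfinite(self.distances)]


def build_roi(raster, pixel_size: float = 1.0, sample_id: str = "") -> ROIMask:
    """Validate a binary raster into an :class:`ROIMask`.

    Raises ``ValueError`` with message ``"empty ROI..."`` when the raster
    contains no True pixel.
    """
    return ROIMask(np.asarray(raster), pixel_size=pixel_size, sample_id=sample_id)


def _seed_grid(roi: ROIMask, seeds) -> np.ndarray:
    """Boolean seed raster from a PointSet or a multi-pixel object mask."""
    if isinstance(seeds, PointSet):
        if len(seeds) == 0:
            raise ValueError("no reference objects: seed set is empty")
        seeds.validate_on(roi)
        grid = np.zeros(roi.shape, dtype=bool)
        grid[seeds.points[:, 0], seeds.points[:, 1]] = True
        return grid
    mask = np.asarray(seeds, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError(f"seed mask shape {mask.shape} != ROI shape {roi.shape}")
    grid = mask & roi.grid
    if not grid.any():
        raise ValueError("no reference objects: seed mask has no ROI pixel")
    return grid


def geodesic_distance_transform(roi: ROIMask, seeds) -> DistanceField:
    """Geodesic chessboard distance from a seed set, masked to the ROI.

    ``seeds`` is a :class:`PointSet` of single-pixel objects (the usual
    dot annotations) or a boolean raster for multi-pixel objects.  The
    transform is a multi-source breadth-first search on the 8-connected
    grid graph restricted to ROI pixels, computed one distance level at a
    time with a full 3x3 binary dilation, so every step (axial or
    diagonal) costs exactly one -- the chessboard metric.

    Seed pixels stay traversable: paths may run across them.
    """
    seed_grid = _seed_grid(roi, seeds)

    values = np.full(roi.shape, UNREACHABLE, dtype=float)
    reached = seed_grid  # seeds already validated to lie on the ROI
    values[reached] = 0.0
    level = 0
    while True:
        grown = ndimage.binary_dilation(reached, structure=_FULL_3X3, mask=roi.grid)
        fresh = grown & ~reached
        if not fresh.any():
            break
        level += 1
        values[fresh] = level
        reached = grown

    if isinstance(seeds, PointSet):
        seed_ps = seeds
    else:
        rr, cc = np.nonzero(seed_grid)
        seed_ps = PointSet(np.column_stack([rr, cc]), kind="reference", sample_id=roi.sample_id)
    return DistanceField(values=values, seeds=seed_ps)


def shortest_distances(
    field: DistanceField, markers: PointSet, roi: ROIMask | None = None
) -> ProximityResult:
    """Look up each marker's shortest geodesic distance to the seed set.

    Markers in ROI components with no seed get ``inf`` and are excluded
    from the mean; their count is reported in ``n_unreachable``.
    """
    if len(markers) == 0:
        raise ValueError("no markers: marker set is empty")
    if roi is not None:
        markers.validate_on(roi)
    nr, nc = field.values.shape
    rows, cols = markers.points.T
    if ((rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)).any():
        raise ValueError("marker outside distance-field bounds")
    dists = field.values[rows, cols]
    finite = np.isfinite(dists)
    n_unreach = int((~finite).sum())
    mean = float(dists[finite].mean()) if finite.any() else float("nan")
    return ProximityResult(
        sample_id=markers.sample_id,
        distances=dists,
        mean_distance=mean,
        n_markers=int(finite.sum()),
        n_unreachable=n_unreach,
        pixel_size=roi.pixel_size if roi is not None else 1.0,
    )
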