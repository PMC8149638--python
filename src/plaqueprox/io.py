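"""Readers and writers for the pipeline's on-disk formats.

Point tables are CSV/TSV with the mandatory header
``sample_id, kind, row, col`` (kind in {marker, reference}; sub-pixel
coordinates are snapped to pixel centers).  ROI masks are single-channel
TIFF or PNG rasters, nonzero = ROI.  Distance fields round-trip as
32-bit float TIFF with NaN encoding the unreachable sentinel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .spatial import DistanceField, PointSet, ROIMask, UNREACHABLE, round_half_away

__all__ = [
    "read_points",
    "write_points",
    "points_by_sample",
    "read_mask",
    "write_mask",
    "read_distance_field",
    "write_distance_field",
    "read_cohort",
]

_REQUIRED_COLUMNS = ("sample_id", "kind", "row", "col")
_KINDS = ("marker", "reference")


def read_points(path: str | Path) -> list[PointSet]:
    """Read a point table, grouped into one PointSet per (sample, kind).

    Validation errors name the offending data line (1-based, counting
    the header as line 1).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty point table") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: point table has a header but no rows")

    bad_kind = ~df["kind"].isin(_KINDS)
    if bad_kind.any():
        i = int(np.argmax(bad_kind.to_numpy()))
        raise ValueError(
            f"{path}: line {i + 2}: invalid kind {df['kind'].iloc[i]!r} "
            f"(expected one of {_KINDS})"
        )
    for col in ("row", "col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.argmax(vals.isna().to_numpy()))
            raise ValueError(
                f"{path}: line {i + 2}: non-numeric {col} value {df[col].iloc[i]!r}"
            )
        df[col] = vals

    out = []
    for (sid, kind), grp in df.groupby(["sample_id", "kind"], sort=True):
        coords = grp[["row", "col"]].to_numpy(dtype=float)
        out.append(PointSet(round_half_away(coords), kind=str(kind), sample_id=str(sid)))
    return out


def write_points(pointsets, path: str | Path) -> None:
    """Write one or more PointSets as a CSV/TSV table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frames = []
    for ps in pointsets:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ps.sample_id,
                    "kind": ps.kind,
                    "row": ps.points[:, 0],
                    "col": ps.points[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def points_by_sample(pointsets) -> dict[str, dict[str, PointSet]]:
    """Index a list of PointSets as {sample_id: {kind: PointSet}}."""
    out: dict[str, dict[str, PointSet]] = {}
    for ps in pointsets:
        out.setdefault(ps.sample_id, {})[ps.kind] = ps
    return out


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask raster from TIFF or PNG (nonzero = True)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim == 3:  # collapse any stray channel axis
        arr = arr[..., 0]
    return arr != 0


def write_mask(mask, path: str | Path) -> None:
    """Write a boolean raster as uint8 TIFF/PNG (255 = True)."""
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_distance_field(field: DistanceField | np.ndarray, path: str | Path) -> None:
    """Write a distance field as float32 TIFF, unreachable -> NaN."""
    vals = field.values if isinstance(field, DistanceField) else np.asarray(field)
    out = np.asarray(vals, dtype=np.float32).copy()
    out[~np.isfinite(out)] = np.nan
    tifffile.imwrite(Path(path), out)


def read_distance_field(path: str | Path) -> np.ndarray:
    """Read a float TIFF distance raster, NaN -> unreachable sentinel."""
    arr = tifffile.imread(Path(path)).astype(float)
    arr[np.isnan(arr)] = UNREACHABLE
    return arr


def read_cohort(
    directory: str | Path, pixel_size: float | None = None
) -> list[tuple[ROIMask, PointSet, PointSet]]:
    """Load a cohort directory written by the synthetic generator.

    Returns ``(roi, references, markers)`` per sample, in manifest order.
    Point tables are checked against the mask bounds; a shape mismatch
    raises with the sample named.
    """
    directory = Path(directory)
    manifest_path = directory / "cohort.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        entries = manifest["samples"]
        if pixel_size is None:
            pixel_size = float(manifest.get("pixel_size", 1.0))
    else:
        entries = [
            {
                "sample_id": p.name[: -len("_roi.tif")],
                "roi": p.name,
                "markers": p.name.replace("_roi.tif", "_markers.csv"),
                "references": p.name.replace("_roi.tif", "_references.csv"),
            }
            for p in sorted(directory.glob("*_roi.tif"))
        ]
    if pixel_size is None:
        pixel_size = 1.0
    if not entries:
        raise ValueError(f"{directory}: no cohort samples found")

    out = []
    for e in entries:
        sid = e["sample_id"]
        roi = ROIMask(read_mask(directory / e["roi"]), pixel_size=pixel_size, sample_id=sid)
        refs = _single(read_points(directory / e["references"]), "reference", sid)
        marks = _single(read_points(directory / e["markers"]), "marker", sid)
        refs.validate_on(roi)
        marks.validate_on(roi)
        out.append((roi, refs, marks))
    return out


def _single(pointsets: list[PointSet], kind: str, sample_id: str) -> PointSet:
    matches = [p for p in pointsets if p.kind == kind and p.sample_id == sample_id]
    if len(matches) != 1:
        raise ValueError(
            f"expected exactly one {kind} set for sample {sample_id!r}, found {len(matches)}"
        )
    return matches[0]
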