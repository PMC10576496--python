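"""Elevation rasters, benthic masks, and the grid operations that prepare them.

A DEM is a square-celled grid of elevations in metres; the paired benthic
mask labels each cell Live / Dead / Other (coral tissue, bare skeleton,
non-coral substrate).  No-data cells are carried as NaN in memory and as a
sentinel value on disk.  Supported on-disk formats are single-band GeoTIFF
(ModelPixelScale / ModelTiepoint / GDAL_NODATA tags) and ESRI ASCII grid;
polygon masks come in as GeoJSON with a ``category`` property.

Grid convention: arrays are row-major from the top-left; the geotransform
origin refers to the grid's lower-left corner in metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    AlignmentError,
    EmptyInputError,
    MalformedInputError,
    UnsupportedFormatError,
)

# Benthic category codes used on disk (0 is reserved for no-data).
LIVE, DEAD, OTHER, NODATA_LABEL = 1, 2, 3, 0
CATEGORY_NAMES = {LIVE: "Live", DEAD: "Dead", OTHER: "Other"}

_GEOTIFF_EXT = {".tif", ".tiff"}
_ASCII_EXT = {".asc"}


@dataclass
class ElevationRaster:
    """Square-celled elevation grid in metres.

    ``values`` holds elevations with NaN marking no-data.  ``gsd`` is the
    native ground sampling distance of the photogrammetric export
    (metres / pixel) carried as provenance metadata; it defines the
    detection limit for compositional zeros downstream.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    gsd: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("elevation grid must be 2-D with at least 2x2 cells")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        # normalise the on-disk sentinel to NaN
        if np.isfinite(self.nodata):
            self.values = np.where(self.values == self.nodata, np.nan, self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def with_values(self, values: np.ndarray) -> "ElevationRaster":
        return replace(self, values=values)


@dataclass
class BenthicMask:
    """Categorical grid over {Live, Dead, Other, no-data}, aligned to a DEM."""

    labels: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be 2-D")
        bad = ~np.isin(self.labels, [NODATA_LABEL, LIVE, DEAD, OTHER])
        if bad.any():
            raise ValueError("mask contains labels outside {0,1,2,3}")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != NODATA_LABEL


@dataclass
class CompositionRecord:
    """One colony's benthic areas (m²) plus its zero-detection limit."""

    colony_id: str
    live_area: float
    dead_area: float
    other_area: float
    detection_limit_area: float
    total_area: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for a in (self.live_area, self.dead_area, self.other_area):
            if a < 0:
                raise ValueError("areas must be non-negative")
        if not self.detection_limit_area > 0:
            raise ValueError("detection_limit_area must be positive")
        total = self.live_area + self.dead_area + self.other_area
        if self.total_area is None:
            self.total_area = total
        elif abs(self.total_area - total) > 1e-9:
            raise ValueError("total_area inconsistent with part sum")


def check_aligned(raster: ElevationRaster, mask: BenthicMask) -> None:
    """Raise AlignmentError unless DEM and mask share grid geometry."""
    if raster.shape != mask.shape or not np.isclose(
        raster.cell_size, mask.cell_size, rtol=0, atol=1e-12
    ):
        raise AlignmentError(
            f"DEM grid {raster.shape}@{raster.cell_size} m does not match "
            f"mask grid {mask.shape}@{mask.cell_size} m"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_geotiff(path: Path):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags.get("ModelPixelScaleTag")
        if scale is None:
            raise MalformedInputError(f"{path}: missing ModelPixelScale tag")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise UnsupportedFormatError(
                f"{path}: non-square cells ({sx} x {sy} m) are not supported"
            )
        tiepoint_tag = tags.get("ModelTiepointTag")
        tiepoint = tuple(tiepoint_tag.value) if tiepoint_tag is not None else None
        nodata_tag = tags.get(42113)  # GDAL_NODATA
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
    if data.ndim == 3:
        if data.shape[2] != 1 and data.shape[0] != 1:
            raise MalformedInputError(f"{path}: expected a single elevation band")
        data = data.reshape(sorted(data.shape, reverse=True)[:2])
    if data.ndim != 2:
        raise MalformedInputError(f"{path}: no 2-D elevation band found")
    data = data.astype(float)
    nrows = data.shape[0]
    if tiepoint is not None:
        # tiepoint anchors the top-left corner; convert to lower-left origin
        x0, ytop = float(tiepoint[3]), float(tiepoint[4])
        origin = (x0, ytop - nrows * sy)
    else:
        origin = (0.0, 0.0)
    return data, sx, origin, nodata


def _write_geotiff(raster: ElevationRaster, path: Path) -> None:
    import tifffile

    nrows = raster.shape[0]
    cs = raster.cell_size
    x0, y0 = raster.origin
    data = np.where(raster.valid_mask, raster.values, raster.nodata).astype(np.float32)
    extratags = [
        (33550, "d", 3, (cs, cs, 0.0)),                       # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, y0 + nrows * cs, 0.0)),  # ModelTiepoint
        (42113, "s", 0, str(raster.nodata)),                  # GDAL_NODATA
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_ascii_grid(path: Path):
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value", "dx", "dy"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    if "dx" in header or "dy" in header:
        dx, dy = header.get("dx"), header.get("dy")
        if dx is None or dy is None or abs(dx - dy) > 1e-9 * max(dx, dy):
            raise UnsupportedFormatError(f"{path}: non-square cells (dx != dy)")
        header["cellsize"] = dx
    for k in ("ncols", "nrows", "cellsize"):
        if k not in header:
            raise MalformedInputError(f"{path}: missing ASCII grid header field {k!r}")
    data = np.array([v for row in rows for v in row], dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise MalformedInputError(f"{path}: expected {nrows * ncols} values, got {data.size}")
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return data, header["cellsize"], origin, nodata


def _write_ascii_grid(raster: ElevationRaster, path: Path) -> None:
    nrows, ncols = raster.shape
    data = np.where(raster.valid_mask, raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.10g}\n")
        fh.write(f"yllcorner {raster.origin[1]:.10g}\n")
        fh.write(f"cellsize {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_dem(path: str | Path, gsd: float | None = None) -> ElevationRaster:
    """Read a DEM from GeoTIFF or ESRI ASCII grid.

    ``gsd`` optionally records the native photogrammetric resolution when it
    differs from the stored cell size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in _GEOTIFF_EXT:
        data, cs, origin, nodata = _read_geotiff(path)
    elif ext in _ASCII_EXT:
        data, cs, origin, nodata = _read_ascii_grid(path)
    else:
        raise UnsupportedFormatError(f"unsupported DEM extension {ext!r}")
    if min(data.shape) < 4:
        raise MalformedInputError(f"{path}: DEM smaller than 4x4 cells")
    return ElevationRaster(data, cs, origin, nodata, gsd=gsd if gsd is not None else cs)


def write_dem(raster: ElevationRaster, path: str | Path) -> Path:
    """Write a DEM as GeoTIFF (.tif/.tiff) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _GEOTIFF_EXT:
        _write_geotiff(raster, path)
    elif ext in _ASCII_EXT:
        _write_ascii_grid(raster, path)
    else:
        raise UnsupportedFormatError(f"unsupported DEM extension {ext!r}")
    return path


def read_mask(path: str | Path, like: ElevationRaster | None = None) -> BenthicMask:
    """Read a benthic mask from categorical GeoTIFF or GeoJSON polygons.

    GeoJSON rasterization needs ``like`` to supply the target grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in _GEOTIFF_EXT:
        data, cs, origin, _ = _read_geotiff(path)
        labels = np.where(np.isfinite(data), data, NODATA_LABEL).astype(np.uint8)
        return BenthicMask(labels, cs, origin)
    if ext in {".json", ".geojson"}:
        if like is None:
            raise ValueError("rasterizing polygon masks requires a template raster")
        return rasterize_polygons(path, like)
    raise UnsupportedFormatError(f"unsupported mask extension {ext!r}")


def write_mask(mask: BenthicMask, path: str | Path) -> Path:
    """Write a mask as single-band categorical GeoTIFF (0=no-data,1=Live,2=Dead,3=Other)."""
    import tifffile

    path = Path(path)
    if path.suffix.lower() not in _GEOTIFF_EXT:
        raise UnsupportedFormatError("categorical masks are written as GeoTIFF")
    nrows = mask.shape[0]
    cs = mask.cell_size
    x0, y0 = mask.origin
    extratags = [
        (33550, "d", 3, (cs, cs, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, y0 + nrows * cs, 0.0)),
        (42113, "s", 0, str(NODATA_LABEL)),
    ]
    tifffile.imwrite(path, mask.labels.astype(np.uint8), extratags=extratags)
    return path


_CATEGORY_BY_NAME = {"live": LIVE, "dead": DEAD, "other": OTHER}


def rasterize_polygons(path: str | Path, like: ElevationRaster) -> BenthicMask:
    """Rasterize GeoJSON category polygons onto the DEM grid.

    Cell membership is by cell-center point; where polygons overlap, the one
    listed first wins (mirroring manual digitization order).
    """
    import shapely
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    nrows, ncols = like.shape
    cs = like.cell_size
    x0, y0 = like.origin
    xs = x0 + (np.arange(ncols) + 0.5) * cs
    ys = y0 + (nrows - np.arange(nrows) - 0.5) * cs  # row 0 is the top
    xx, yy = np.meshgrid(xs, ys)
    labels = np.full((nrows, ncols), NODATA_LABEL, dtype=np.uint8)
    for feat in feats:
        cat = str(feat.get("properties", {}).get("category", "")).lower()
        if cat not in _CATEGORY_BY_NAME:
            raise MalformedInputError(f"polygon without a Live/Dead/Other category: {cat!r}")
        geom = shape(feat["geometry"])
        inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(nrows, ncols)
        unassigned = labels == NODATA_LABEL
        labels[inside & unassigned] = _CATEGORY_BY_NAME[cat]
    return BenthicMask(labels, cs, like.origin)


# ---------------------------------------------------------------------------
# Grid operations
# ---------------------------------------------------------------------------

def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = a.shape[0] // factor, a.shape[1] // factor
    return a[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)


def resample_to_grid(raster: ElevationRaster, target_cell: float) -> ElevationRaster:
    """Block-mean aggregate a DEM to a coarser square grid.

    Conservative no-data rule: any no-data cell inside a block makes the
    whole output block no-data.  Trailing rows/columns that do not fill a
    complete block are dropped.
    """
    cs = raster.cell_size
    if target_cell < cs - 1e-12:
        raise ValueError("target_cell must be >= the raster cell size")
    ratio = target_cell / cs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target cell {target_cell} is not an integer multiple of {cs}"
        )
    if factor == 1:
        return raster.with_values(raster.values.copy())
    blocks = _block_view(raster.values, factor)
    with np.errstate(invalid="ignore"):
        means = blocks.mean(axis=(1, 3))  # NaN propagates: conservative rule
    return ElevationRaster(
        means, target_cell, raster.origin, raster.nodata, gsd=raster.gsd
    )


def aggregate_clip(raster: ElevationRaster, factor: int) -> ElevationRaster:
    """Edge-trim a DEM with the aggregation rule used before multiscale metrics.

    The grid is partitioned into ``factor``×``factor`` blocks from the
    top-left.  Any block that contains a no-data cell, or that extends past
    the grid edge, is nulled in full at the original resolution; cells in
    fully valid blocks are untouched.  Grid dimensions are unchanged and the
    operation is idempotent for a fixed factor.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    nrows, ncols = raster.shape
    if factor > min(nrows, ncols):
        raise ValueError(f"factor {factor} exceeds grid dimensions {raster.shape}")
    out = raster.values.copy()
    if factor > 1:
        valid = raster.valid_mask
        nr, nc = nrows // factor, ncols // factor
        block_ok = _block_view(valid, factor).all(axis=(1, 3))
        keep = np.zeros((nrows, ncols), dtype=bool)
        keep[: nr * factor, : nc * factor] = np.repeat(
            np.repeat(block_ok, factor, axis=0), factor, axis=1
        )
        out[~keep] = np.nan
    return raster.with_values(out)


def quantify_areas(
    mask: BenthicMask, colony_id: str, detection_limit_area: float
) -> CompositionRecord:
    """Per-category planform areas by cell counting: area = n_cells · cell²."""
    if not mask.valid_mask.any():
        raise EmptyInputError("mask has no valid cells")
    cell_area = mask.cell_size ** 2
    counts = {c: int((mask.labels == c).sum()) for c in (LIVE, DEAD, OTHER)}
    return CompositionRecord(
        colony_id=colony_id,
        live_area=counts[LIVE] * cell_area,
        dead_area=counts[DEAD] * cell_area,
        other_area=counts[OTHER] * cell_area,
        detection_limit_area=detection_limit_area,
    )
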