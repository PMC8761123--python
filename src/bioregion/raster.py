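"""Georeferenced single-band raster grids, stacks and pixel tables.

The data model is deliberately small: a grid is a float array plus a nodata
mask plus an affine geotransform ``(origin_x, origin_y, pixel_width,
pixel_height)`` with row 0 at the northern edge (``pixel_height`` < 0 for
north-up grids).  The cell centre of ``(r, c)`` is at
``(origin_x + (c + 0.5) * pixel_width, origin_y + (r + 0.5) * pixel_height)``.

GeoTIFF I/O is written against :mod:`tifffile` using the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA, GeoAsciiParams); only
single-band files are supported.  No reprojection engine is provided — the
CRS is carried as an opaque label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "RasterStack",
    "PixelTable",
    "ClusterMap",
    "read_raster",
    "write_raster",
    "write_cluster_map",
    "read_cluster_map",
    "resample_to_template",
    "build_pixel_table",
    "read_manifest",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113

_FLOAT_NODATA = -3.4e38
_INT_NODATA = 0


@dataclass
class RasterGrid:
    """A single-band georeferenced grid with an explicit nodata mask."""

    values: np.ndarray
    nodata_mask: np.ndarray
    geotransform: tuple[float, float, float, float]
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata mask shape does not match values")
        ox, oy, pw, ph = self.geotransform
        if not (pw > 0 and ph != 0):
            raise ValueError("pixel_width must be > 0 and pixel_height nonzero")
        self.geotransform = (float(ox), float(oy), float(pw), float(ph))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres (1-D per axis)."""
        ox, oy, pw, ph = self.geotransform
        rows, cols = self.shape
        x = ox + (np.arange(cols) + 0.5) * pw
        y = oy + (np.arange(rows) + 0.5) * ph
        return x, y

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's extent."""
        ox, oy, pw, ph = self.geotransform
        rows, cols = self.shape
        xs = sorted((ox, ox + cols * pw))
        ys = sorted((oy, oy + rows * ph))
        return xs[0], ys[0], xs[1], ys[1]

    def masked_values(self) -> np.ndarray:
        """Values with nodata replaced by NaN (copy)."""
        out = self.values.astype(float, copy=True)
        out[self.nodata_mask] = np.nan
        return out


@dataclass
class RasterStack:
    """An ordered collection of aligned, named layers."""

    layers: list[tuple[str, RasterGrid]] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.layers]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate variable codes in stack")
        if self.layers:
            ref = self.layers[0][1]
            for code, grid in self.layers[1:]:
                if grid.shape != ref.shape:
                    raise ValueError(f"layer {code!r} shape differs from stack")
                if not np.allclose(grid.geotransform, ref.geotransform):
                    raise ValueError(f"layer {code!r} geotransform differs from stack")

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, code: str) -> RasterGrid:
        for c, g in self.layers:
            if c == code:
                return g
        raise KeyError(code)

    @property
    def variable_codes(self) -> list[str]:
        return [c for c, _ in self.layers]

    def add(self, code: str, grid: RasterGrid) -> None:
        self.layers.append((code, grid))
        self.__post_init__()

    def subset(self, codes: list[str]) -> "RasterStack":
        return RasterStack([(c, self[c]) for c in codes])

    def combined_mask(self) -> np.ndarray:
        """True where ANY layer is nodata (intersection of valid cells)."""
        if not self.layers:
            raise ValueError("empty stack")
        mask = np.zeros(self.layers[0][1].shape, dtype=bool)
        for _, g in self.layers:
            mask |= g.nodata_mask
        return mask


@dataclass
class PixelTable:
    """Valid-pixel-by-variable matrix with a reversible pixel index."""

    matrix: np.ndarray
    index: np.ndarray  # (n_valid, 2) array of (row, col)
    variable_codes: list[str]
    shape: tuple[int, int]
    geotransform: tuple[float, float, float, float]
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.index = np.asarray(self.index, dtype=np.intp)
        if self.matrix.shape[0] != self.index.shape[0]:
            raise ValueError("matrix and index row counts differ")
        if self.matrix.shape[1] != len(self.variable_codes):
            raise ValueError("matrix columns do not match variable codes")

    @property
    def n_valid(self) -> int:
        return self.matrix.shape[0]

    def scatter(self, row_values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-row vector back onto the full grid."""
        row_values = np.asarray(row_values)
        out = np.full(self.shape, fill, dtype=row_values.dtype if fill == 0 else float)
        out[self.index[:, 0], self.index[:, 1]] = row_values
        return out

    def subset(self, codes: list[str]) -> "PixelTable":
        cols = [self.variable_codes.index(c) for c in codes]
        return replace(self, matrix=self.matrix[:, cols], variable_codes=list(codes))


@dataclass
class ClusterMap:
    """Integer-labelled grid: 0 = nodata/outside, 1..K = cluster ids."""

    labels: np.ndarray
    K: int
    geotransform: tuple[float, float, float, float]
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = np.unique(self.labels)
        if present.size and (present.min() < 0 or present.max() > self.K):
            raise ValueError("labels outside 0..K")
        for k in range(1, self.K + 1):
            if not (self.labels == k).any():
                raise ValueError(f"cluster {k} is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cluster_ids(self) -> list[int]:
        return list(range(1, self.K + 1))

    def as_grid(self) -> RasterGrid:
        return RasterGrid(
            values=self.labels.astype(float),
            nodata_mask=self.labels == 0,
            geotransform=self.geotransform,
            crs_label=self.crs_label,
        )


def _parse_gdal_nodata(raw) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, bytes):
        raw = raw.decode("ascii", "ignore")
    raw = str(raw).strip().rstrip("\x00").strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def read_raster(path: str) -> RasterGrid:
    """Read a single-band GeoTIFF into a :class:`RasterGrid`.

    The file must carry the GeoTIFF ModelPixelScale and ModelTiepoint tags;
    a missing georeference is an explicit error naming the file.
    """
    import tifffile

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise ValueError(f"cannot read {path!r} as a TIFF raster: {exc}") from exc

    if values.ndim == 3 and values.shape[2] == 1:
        values = values[:, :, 0]
    if values.ndim != 2:
        raise ValueError(f"{path!r}: only single-band rasters are supported")

    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is None or tiepoint is None:
        raise ValueError(f"{path!r} carries no georeference (GeoTIFF tags missing)")
    sx, sy = float(scale[0]), float(scale[1])
    # tiepoint: raster (i, j, k) -> model (x, y, z); anchored at pixel (0, 0)
    origin_x = float(tiepoint[3]) - float(tiepoint[0]) * sx
    origin_y = float(tiepoint[4]) + float(tiepoint[1]) * sy
    geotransform = (origin_x, origin_y, sx, -sy)

    crs_label = tags.get(_TAG_GEO_ASCII) or "unknown"
    if isinstance(crs_label, bytes):
        crs_label = crs_label.decode("ascii", "ignore")
    crs_label = str(crs_label).rstrip("\x00|").strip() or "unknown"

    nodata = _parse_gdal_nodata(tags.get(_TAG_GDAL_NODATA))
    if nodata is None:
        mask = ~np.isfinite(values.astype(float))
    else:
        mask = (values == nodata) | ~np.isfinite(values.astype(float))
    return RasterGrid(values=values, nodata_mask=mask, geotransform=geotransform, crs_label=crs_label)


def _geo_extratags(geotransform, crs_label, nodata) -> list:
    ox, oy, pw, ph = geotransform
    crs = (crs_label or "unknown") + "|"
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (pw, abs(ph), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GEO_ASCII, "s", len(crs), crs),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata) if isinstance(nodata, int) else f"{nodata:g}"),
    ]


def write_raster(grid: RasterGrid, path: str, dtype=np.float32) -> None:
    """Write a grid as a single-band GeoTIFF with an explicit nodata tag."""
    import tifffile

    values = grid.values.astype(dtype, copy=True)
    nodata = _INT_NODATA if np.issubdtype(np.dtype(dtype), np.integer) else _FLOAT_NODATA
    values[grid.nodata_mask] = nodata
    tifffile.imwrite(
        path,
        values,
        extratags=_geo_extratags(grid.geotransform, grid.crs_label, nodata),
    )


def write_cluster_map(cmap: ClusterMap, path: str) -> None:
    """Write a cluster map as an int32 GeoTIFF with 0 as nodata."""
    grid = RasterGrid(
        values=cmap.labels,
        nodata_mask=np.zeros_like(cmap.labels, dtype=bool),
        geotransform=cmap.geotransform,
        crs_label=cmap.crs_label,
    )
    write_raster(grid, path, dtype=np.int32)


def read_cluster_map(path: str) -> ClusterMap:
    """Read an integer label GeoTIFF written by :func:`write_cluster_map`."""
    grid = read_raster(path)
    labels = grid.values.astype(np.int32)
    labels[grid.nodata_mask] = 0
    K = int(labels.max()) if labels.size else 0
    return ClusterMap(labels=labels, K=K, geotransform=grid.geotransform, crs_label=grid.crs_label)


def resample_to_template(grid: RasterGrid, template: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Resample ``grid`` onto ``template``'s shape and geotransform.

    ``nearest`` takes the validity of the sampled source cell; ``bilinear``
    marks a target cell nodata when any contributing source cell is nodata.
    Disjoint extents are an error.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    gx0, gy0, gx1, gy1 = grid.bounds()
    tx0, ty0, tx1, ty1 = template.bounds()
    if gx1 <= tx0 or tx1 <= gx0 or gy1 <= ty0 or ty1 <= gy0:
        raise ValueError("grid and template extents are disjoint")

    ox, oy, pw, ph = grid.geotransform
    tx, ty = template.cell_centers()
    # fractional source indices of the template cell centres
    cols = (tx - ox) / pw - 0.5
    rows = (ty - oy) / ph - 0.5
    cc, rr = np.meshgrid(cols, rows)

    if method == "nearest":
        ri = np.rint(rr).astype(int)
        ci = np.rint(cc).astype(int)
        inside = (ri >= 0) & (ri < grid.shape[0]) & (ci >= 0) & (ci < grid.shape[1])
        values = np.zeros(template.shape, dtype=grid.values.dtype)
        mask = ~inside
        ris, cis = ri[inside], ci[inside]
        values[inside] = grid.values[ris, cis]
        mask[inside] |= grid.nodata_mask[ris, cis]
    else:
        src = grid.masked_values()
        values = ndimage.map_coordinates(
            src, [rr, cc], order=1, mode="constant", cval=np.nan, prefilter=False
        )
        mask = ~np.isfinite(values)
        values = np.where(mask, 0.0, values)
    return RasterGrid(values=values, nodata_mask=mask, geotransform=template.geotransform, crs_label=grid.crs_label)


def build_pixel_table(stack: RasterStack) -> PixelTable:
    """Flatten a stack into a valid-pixel × variable matrix.

    A pixel enters the table only if it is valid in every layer; column
    order follows the stack's layer order.
    """
    if not len(stack):
        raise ValueError("empty stack")
    mask = stack.combined_mask()
    valid = ~mask
    if not valid.any():
        raise ValueError("no pixel is valid across all layers")
    rows, cols = np.nonzero(valid)
    matrix = np.column_stack([g.values.astype(float)[rows, cols] for _, g in stack.layers])
    ref = stack.layers[0][1]
    return PixelTable(
        matrix=matrix,
        index=np.column_stack([rows, cols]),
        variable_codes=stack.variable_codes,
        shape=ref.shape,
        geotransform=ref.geotransform,
        crs_label=ref.crs_label,
    )


def read_manifest(path: str) -> RasterStack:
    """Read a two-column (variable_code, path) CSV manifest into a stack.

    Relative raster paths are resolved against the manifest's directory.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "variable_code" not in cols or "path" not in cols:
        raise ValueError(f"manifest {path!r} needs 'variable_code' and 'path' columns")
    df.columns = cols
    base = os.path.dirname(os.path.abspath(path))
    layers = []
    for _, row in df.iterrows():
        p = str(row["path"])
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        layers.append((str(row["variable_code"]), read_raster(p)))
    return RasterStack(layers)
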