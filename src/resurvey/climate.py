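"""Gridded temperature fusion, bias correction and lapse-rate downscaling.

Monthly temperature stacks are ``xarray.DataArray`` objects with dims
``(year, month, y, x)`` on regular, cell-center-registered grids; single
fields and DEMs use ``(y, x)``.  Regridding builds an explicit linear
operator so that monthly stacks can be mapped between grids cheaply.

The ``patch_like`` regridding method approximates higher-order patch
recovery: a biquadratic least-squares polynomial is fitted around each
source cell and the surrounding patches are blended at the target point
with inverse-distance weights.  It reproduces constant and linear fields
exactly, which is the property the downscaling step relies on.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: Months entering each temperature index.  The winter half-year crosses the
#: year boundary and is assigned to the calendar year of its January-March
#: part.
INDEX_MONTHS = {
    "annual": tuple(range(1, 13)),
    "summer_half": (4, 5, 6, 7, 8, 9),
    "winter_half": (10, 11, 12, 1, 2, 3),
    "spring": (3, 4, 5, 6),
}

DEFAULT_GRADIENT = -6.68  # K per km


def monthly_grid(
    values: np.ndarray, years, x, y
) -> xr.DataArray:
    """Wrap a (year, month, y, x) array as a validated DataArray."""
    arr = xr.DataArray(
        np.asarray(values, dtype=float),
        dims=("year", "month", "y", "x"),
        coords={
            "year": np.asarray(list(years), dtype=int),
            "month": np.arange(1, 13),
            "y": np.asarray(y, dtype=float),
            "x": np.asarray(x, dtype=float),
        },
        name="temperature",
    )
    if np.isnan(arr.values).any():
        raise ValueError("monthly grid contains NaN inside the domain")
    return arr


def _check_regular(coord: np.ndarray, name: str) -> float:
    steps = np.diff(coord)
    if coord.size > 1 and not np.allclose(steps, steps[0]):
        raise ValueError(f"{name} coordinate is not regular")
    return float(steps[0]) if coord.size > 1 else 1.0


class RegridOperator:
    """Sparse-ish linear map from a source grid to arbitrary target points."""

    def __init__(self, weights: np.ndarray, src_shape: tuple[int, int],
                 tgt_shape: tuple[int, int]):
        self.weights = weights  # (n_tgt, n_src)
        self.src_shape = src_shape
        self.tgt_shape = tgt_shape

    def apply(self, field: np.ndarray) -> np.ndarray:
        flat = np.asarray(field, dtype=float).reshape(-1)
        return (self.weights @ flat).reshape(self.tgt_shape)


def _quad_basis(dx, dy):
    return np.column_stack(
        [np.ones_like(dx), dx, dy, dx * dx, dx * dy, dy * dy]
    )


def build_regrid_operator(
    src_x: np.ndarray,
    src_y: np.ndarray,
    tgt_x: np.ndarray,
    tgt_y: np.ndarray,
    method: str = "patch_like",
) -> RegridOperator:
    """Precompute regridding weights from a regular source grid.

    Target nodes outside the source domain are handled by the nearest
    patch / edge cell, with a warning.
    """
    if method not in ("patch_like", "bilinear"):
        raise ValueError(f"unknown regrid method {method!r}")
    src_x = np.asarray(src_x, dtype=float)
    src_y = np.asarray(src_y, dtype=float)
    dx = _check_regular(src_x, "x")
    dy = _check_regular(src_y, "y")
    nx, ny = src_x.size, src_y.size
    n_src = nx * ny
    tgt_x = np.asarray(tgt_x, dtype=float)
    tgt_y = np.asarray(tgt_y, dtype=float)
    n_tgt = tgt_x.size * tgt_y.size
    weights = np.zeros((n_tgt, n_src))

    def flat(iy, ix):
        return iy * nx + ix

    outside = 0
    # precompute patch pseudo-inverses per source cell (patch_like only)
    patch_cache: dict[tuple[int, int], tuple] = {}

    def patch(iy, ix):
        # shifted (never clipped) 3x3 block keeps the quadratic basis
        # unisolvent, which is what makes linear fields exact at edges
        key = (iy, ix)
        if key in patch_cache:
            return patch_cache[key]
        y0 = min(max(iy - 1, 0), max(ny - 3, 0))
        x0 = min(max(ix - 1, 0), max(nx - 3, 0))
        ys = range(y0, min(y0 + 3, ny))
        xs = range(x0, min(x0 + 3, nx))
        pts = [(jy, jx) for jy in ys for jx in xs]
        ddx = np.array([(src_x[jx] - src_x[ix]) / dx for _jy, jx in pts])
        ddy = np.array([(src_y[jy] - src_y[iy]) / dy for jy, _jx in pts])
        basis = _quad_basis(ddx, ddy)
        keep_cols = np.ones(6, dtype=bool)
        if len(set(xs)) < 3:  # degenerate thin grids: drop quadratic terms
            keep_cols[[3, 4]] = False
        if len(set(ys)) < 3:
            keep_cols[[4, 5]] = False
        pinv = np.linalg.pinv(basis[:, keep_cols])
        idx = np.array([flat(jy, jx) for jy, jx in pts])
        patch_cache[key] = (pinv, idx, keep_cols)
        return patch_cache[key]

    row = 0
    for ty in tgt_y:
        fy = (ty - src_y[0]) / dy if ny > 1 else 0.0
        for tx in tgt_x:
            fx = (tx - src_x[0]) / dx if nx > 1 else 0.0
            if fx < 0 or fx > nx - 1 or fy < 0 or fy > ny - 1:
                outside += 1
            cfx = min(max(fx, 0.0), nx - 1)
            cfy = min(max(fy, 0.0), ny - 1)
            ix0 = int(np.floor(cfx))
            iy0 = int(np.floor(cfy))
            ix1 = min(ix0 + 1, nx - 1)
            iy1 = min(iy0 + 1, ny - 1)
            wx = cfx - ix0
            wy = cfy - iy0
            if method == "bilinear":
                for iy, wyy in ((iy0, 1 - wy), (iy1, wy)):
                    for ix, wxx in ((ix0, 1 - wx), (ix1, wx)):
                        if wyy * wxx:
                            weights[row, flat(iy, ix)] += wyy * wxx
            else:
                cells = {(iy0, ix0), (iy0, ix1), (iy1, ix0), (iy1, ix1)}
                dists = {}
                for (iy, ix) in cells:
                    d = np.hypot(
                        (tx - src_x[ix]) / dx, (ty - src_y[iy]) / dy
                    )
                    dists[(iy, ix)] = d
                exact = [c for c, d in dists.items() if d < 1e-12]
                if exact:
                    blend = {exact[0]: 1.0}
                else:
                    inv = {c: 1.0 / d**2 for c, d in dists.items()}
                    tot = sum(inv.values())
                    blend = {c: v / tot for c, v in inv.items()}
                for (iy, ix), w_cell in blend.items():
                    pinv, idx, keep_cols = patch(iy, ix)
                    phi = _quad_basis(
                        np.array([(tx - src_x[ix]) / dx]),
                        np.array([(ty - src_y[iy]) / dy]),
                    )[0][keep_cols]
                    weights[row, idx] += w_cell * (phi @ pinv)
            row += 1
    if outside:
        logger.warning(
            "build_regrid_operator: %d target node(s) outside the source "
            "domain use the nearest edge patch", outside,
        )
    return RegridOperator(weights, (ny, nx), (tgt_y.size, tgt_x.size))


def regrid(
    field: xr.DataArray,
    tgt_x: np.ndarray,
    tgt_y: np.ndarray,
    method: str = "patch_like",
    operator: RegridOperator | None = None,
) -> xr.DataArray:
    """Regrid a (y, x) field or a (..., y, x) stack to a target grid."""
    if operator is None:
        operator = build_regrid_operator(
            field["x"].values, field["y"].values, tgt_x, tgt_y, method
        )
    data = field.values
    lead = data.shape[:-2]
    flatten = data.reshape((-1,) + data.shape[-2:])
    out = np.stack([operator.apply(f) for f in flatten])
    out = out.reshape(lead + (len(tgt_y), len(tgt_x)))
    coords = {d: field[d] for d in field.dims[:-2]}
    coords["y"] = np.asarray(tgt_y, dtype=float)
    coords["x"] = np.asarray(tgt_x, dtype=float)
    return xr.DataArray(out, dims=field.dims, coords=coords, name=field.name)


@dataclasses.dataclass
class BiasModel:
    """Per cell-month affine map from the coarse to the fine dataset."""

    slope: xr.DataArray  # (month, y, x)
    intercept: xr.DataArray
    overlap_years: tuple[int, ...]


def fit_bias(
    coarse_on_fine: xr.DataArray,
    fine: xr.DataArray,
    overlap_years,
    min_years: int = 10,
) -> BiasModel:
    """OLS fit ``fine = slope * coarse + intercept`` per cell and month.

    Cells with zero predictor variance fall back to an intercept-only model
    (slope 0, intercept = mean of the fine series) with a warning.
    """
    overlap_years = tuple(int(y) for y in overlap_years)
    if len(overlap_years) < min_years:
        raise ValueError(
            f"bias model needs >= {min_years} overlap years, "
            f"got {len(overlap_years)}"
        )
    cx = coarse_on_fine.sel(year=list(overlap_years))
    fx = fine.sel(year=list(overlap_years))
    cm = cx.mean("year")
    fm = fx.mean("year")
    cov = ((cx - cm) * (fx - fm)).mean("year")
    var = ((cx - cm) ** 2).mean("year")
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = xr.where(var > 0, cov / var, 0.0)
    degenerate = int((var <= 0).sum())
    if degenerate:
        logger.warning(
            "fit_bias: %d cell-month(s) with zero predictor variance use an "
            "intercept-only model", degenerate,
        )
    intercept = fm - slope * cm
    return BiasModel(slope=slope, intercept=intercept,
                     overlap_years=overlap_years)


def apply_bias(
    coarse_on_fine: xr.DataArray,
    model: BiasModel,
    fine: xr.DataArray | None = None,
    splice_year: int = 1961,
) -> xr.DataArray:
    """Bias-correct years before the splice year; use the fine data after.

    Without a fine stack, all years are corrected.
    """
    corrected = model.slope * coarse_on_fine + model.intercept
    if fine is None:
        return corrected.transpose("year", "month", "y", "x")
    years = coarse_on_fine["year"].values
    pre = corrected.sel(year=years[years < splice_year])
    post_years = [y for y in fine["year"].values if y >= splice_year]
    post = fine.sel(year=post_years)
    out = xr.concat([pre, post], dim="year").sortby("year")
    return out.transpose("year", "month", "y", "x")


def temperature_index(
    monthly: xr.DataArray, index_name: str, period_years
) -> xr.DataArray:
    """30-year (or arbitrary-period) mean of a named temperature index.

    Per year the index is the mean of its constituent monthly means; the
    yearly values are then averaged over the period.  The winter half-year
    of year Y uses October-December of Y-1 and January-March of Y.
    """
    if index_name not in INDEX_MONTHS:
        raise ValueError(f"unknown index {index_name!r}")
    months = INDEX_MONTHS[index_name]
    years = [int(y) for y in period_years]
    avail = set(int(y) for y in monthly["year"].values)
    cross_year = index_name == "winter_half"
    need = set(years) | ({y - 1 for y in years} if cross_year else set())
    if not need <= avail:
        raise ValueError(f"period not fully covered: missing {sorted(need - avail)}")
    fields = []
    for yr in years:
        parts = []
        for m in months:
            src_year = yr - 1 if (cross_year and m >= 10) else yr
            parts.append(monthly.sel(year=src_year, month=m, drop=True))
        fields.append(sum(parts) / len(parts))
    out = sum(fields) / len(fields)
    out.name = index_name
    out.attrs["months"] = months
    out.attrs["period"] = (min(years), max(years))
    return out


def downscale(
    index_field: xr.DataArray,
    src_elev: xr.DataArray,
    dem: xr.DataArray,
    gradient: float = DEFAULT_GRADIENT,
    method: str = "patch_like",
    operator: RegridOperator | None = None,
) -> xr.DataArray:
    """Lapse-rate downscaling of an index field onto a fine DEM.

    The vertical dependency ``gradient * elevation`` is removed on the
    source grid, the residual is regridded, and the dependency is added
    back with the fine DEM.  ``gradient`` is in K per km, elevations in m.
    """
    if gradient >= 0:
        raise ValueError("vertical temperature gradient must be negative")
    resid = index_field - gradient * src_elev / 1000.0
    resid_fine = regrid(
        resid, dem["x"].values, dem["y"].values, method=method,
        operator=operator,
    )
    out = resid_fine + gradient * dem / 1000.0
    out.name = index_field.name
    out.attrs.update(index_field.attrs)
    out.attrs["gradient"] = gradient
    return out


def equivalent_shift(delta_t: float, gradient: float = DEFAULT_GRADIENT) -> float:
    """Elevation shift (m) equivalent to a temperature change (K)."""
    if gradient == 0:
        raise ValueError("gradient must be nonzero")
    return float(delta_t / abs(gradient) * 1000.0)


def zone_means(
    field: xr.DataArray, dem: xr.DataArray, zones
) -> pd.Series:
    """Mean field value over DEM cells inside each elevation zone [lo, hi]."""
    out = {}
    for lo, hi in zones:
        mask = (dem.values >= lo) & (dem.values <= hi)
        if not mask.any():
            raise ValueError(f"elevation zone [{lo}, {hi}] is empty")
        out[f"{lo:g}-{hi:g}"] = float(field.values[mask].mean())
    return pd.Series(out, name=field.name)


def glacier_change(area_old_km2: float, area_new_km2: float) -> float:
    """Percent reduction of glaciated area (negative if it grew)."""
    if area_old_km2 <= 0 or area_new_km2 <= 0:
        raise ValueError("areas must be positive")
    return 100.0 * (area_old_km2 - area_new_km2) / area_old_km2
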