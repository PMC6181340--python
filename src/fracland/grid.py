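"""Pixel data model, design-matrix construction, pixel geometry and sample filters.

The estimation problem nests 5-arc-minute pixels inside administrative units:
Level-1 units (states/provinces) carry the observed crop shares; pixels carry
the biophysical covariates. This module holds the containers for both sides,
the covariate transformations that build the regression design, the spherical
pixel-area formula, the coarse-to-fine block downscaling of 30' covariates,
and the sample-selection filters applied before estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, DesignError, EmptyUnitError, GridError, SelectionError

logger = logging.getLogger(__name__)

#: mean Earth radius, km (spherical model used for all pixel areas)
EARTH_RADIUS_KM = 6371.0

RESERVED_COLUMNS = ("pixel_id", "unit_l1", "unit_l2", "lat", "lon", "area", "excluded")


class PixelTable:
    """Pixels nested in administrative units, with covariates and masks.

    Wraps a :class:`pandas.DataFrame` with the reserved columns
    ``pixel_id, unit_l1, [unit_l2], lat, lon, area, excluded``; every other
    column is treated as a covariate. Invariants (unique pixel ids, positive
    areas, Level-2 nesting inside Level-1) are validated on construction.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"pixel_id", "unit_l1", "lat", "lon", "area", "excluded"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"pixel table missing columns: {sorted(missing)}")
        if frame["pixel_id"].duplicated().any():
            dups = frame.loc[frame["pixel_id"].duplicated(), "pixel_id"].unique()
            raise DataError(f"duplicate pixel_id values: {list(dups[:5])}")
        if (frame["area"] <= 0).any():
            bad = frame.loc[frame["area"] <= 0, "pixel_id"].tolist()
            raise DataError(f"non-positive pixel areas for pixels {bad[:5]}")
        if frame["unit_l1"].isna().any():
            raise DataError("every pixel must belong to exactly one Level-1 unit")
        if "unit_l2" in frame.columns and frame["unit_l2"].notna().any():
            nest = frame.dropna(subset=["unit_l2"]).groupby("unit_l2")["unit_l1"].nunique()
            crossing = nest[nest > 1]
            if len(crossing):
                raise DataError(
                    f"Level-2 units crossing Level-1 boundaries: {list(crossing.index[:5])}"
                )
        self.frame = frame.reset_index(drop=True)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESERVED_COLUMNS]

    @property
    def n_pixels(self) -> int:
        return len(self.frame)

    @property
    def units(self) -> np.ndarray:
        return np.asarray(pd.unique(self.frame["unit_l1"]))

    @property
    def has_level2(self) -> bool:
        return "unit_l2" in self.frame.columns and self.frame["unit_l2"].notna().all()

    def subset(self, mask: np.ndarray) -> "PixelTable":
        return PixelTable(self.frame.loc[np.asarray(mask)])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PixelTable({self.n_pixels} pixels, {len(self.units)} Level-1 units, "
            f"covariates={self.covariate_names})"
        )


class AggregateShares:
    """Per-unit observed land-share fractions y_jk over K categories.

    Category 1 (first column) is the base: land in any use other than the
    crops of interest. Rows must sum to one.
    """

    #: tolerance on the sum-to-one constraint
    SUM_TOL = 1e-9

    def __init__(self, frame: pd.DataFrame, crops: Sequence[str] | None = None):
        """``frame``: wide table indexed (or keyed by column 'unit_l1') with one
        column per category, base category first."""
        frame = frame.copy()
        if "unit_l1" in frame.columns:
            frame = frame.set_index("unit_l1")
        if crops is not None:
            frame = frame[list(crops)]
        vals = frame.to_numpy(dtype=float)
        if vals.shape[1] < 2:
            raise DataError("need at least 2 categories (base + 1 crop)")
        out_of_range = ((vals < 0) | (vals > 1)).any(axis=1)
        if out_of_range.any():
            raise DataError(
                f"shares must lie in [0, 1]: offending units {list(frame.index[out_of_range][:5])}"
            )
        bad = np.abs(vals.sum(axis=1) - 1.0) > self.SUM_TOL
        if bad.any():
            raise DataError(
                f"unit shares must sum to 1: offending units {list(frame.index[bad][:5])}"
            )
        frame.index.name = "unit_l1"
        self.frame = frame

    @property
    def units(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def crops(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_units(self) -> int:
        return len(self.frame)

    @property
    def K(self) -> int:
        return self.frame.shape[1]

    def reindex(self, units: Iterable) -> "AggregateShares":
        sub = self.frame.loc[list(units)]
        return AggregateShares(sub)

    @classmethod
    def from_long(cls, frame: pd.DataFrame, base: str | None = None) -> "AggregateShares":
        """Build from long format (columns unit_l1, crop, share).

        ``base`` names the base category; if None and a 'base'/'other'
        category is present it is moved first, otherwise the residual
        1 - sum(shares) is added as category 'other'.
        """
        wide = frame.pivot(index="unit_l1", columns="crop", values="share")
        cols = list(wide.columns)
        if base is None:
            for cand in ("base", "other"):
                if cand in cols:
                    base = cand
                    break
        if base is None:
            wide.insert(0, "other", 1.0 - wide.sum(axis=1))
        else:
            cols = [base] + [c for c in cols if c != base]
            wide = wide[cols]
        return cls(wide)

    def to_long(self) -> pd.DataFrame:
        long = self.frame.reset_index().melt(
            id_vars="unit_l1", var_name="crop", value_name="share"
        )
        return long.sort_values(["unit_l1", "crop"], kind="stable").reset_index(drop=True)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AggregateShares({self.n_units} units, crops={self.crops})"


# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One design-matrix term; ``kind`` selects the transformation."""

    kind: str  # linear | square | interaction | hinge_below | hinge_above | indicator
    var: str
    var2: str | None = None
    pivot: float | None = None

    def __post_init__(self):
        kinds = {"linear", "square", "interaction", "hinge_below", "hinge_above", "indicator"}
        if self.kind not in kinds:
            raise DesignError(f"unknown term kind {self.kind!r}")
        if self.kind == "interaction" and self.var2 is None:
            raise DesignError("interaction term needs two variables")
        if self.kind in ("hinge_below", "hinge_above"):
            if self.pivot is None or not np.isfinite(self.pivot):
                raise DesignError("hinge term needs a finite pivot")

    def label(self) -> str:
        if self.kind == "linear":
            return self.var
        if self.kind == "square":
            return f"{self.var}^2"
        if self.kind == "interaction":
            return f"{self.var}:{self.var2}"
        if self.kind == "hinge_below":
            return f"max({self.pivot:g}-{self.var},0)"
        if self.kind == "hinge_above":
            return f"max({self.var}-{self.pivot:g},0)"
        return f"I({self.var})"


def linear(var: str) -> Term:
    return Term("linear", var)


def square(var: str) -> Term:
    return Term("square", var)


def interaction(var_a: str, var_b: str) -> Term:
    return Term("interaction", var_a, var2=var_b)


def hinge_below(var: str, pivot: float) -> Term:
    return Term("hinge_below", var, pivot=float(pivot))


def hinge_above(var: str, pivot: float) -> Term:
    return Term("hinge_above", var, pivot=float(pivot))


def indicator(group: str) -> Term:
    return Term("indicator", group)


@dataclass
class DesignSpec:
    """Ordered covariate transformations W(X) mapping N covariates to M columns.

    The column order of the built matrix follows the term order exactly, with
    an intercept column of ones first when ``intercept`` is true. Indicator
    terms expand to one column per non-base level of the grouping variable
    (first level in sorted order is the base), identical across crops.
    """

    terms: list[Term] = field(default_factory=list)
    intercept: bool = True

    def __post_init__(self):
        if not self.terms and not self.intercept:
            raise DesignError("design must contain at least one term or an intercept")

    def validate(self, pixels: PixelTable) -> None:
        names = set(pixels.covariate_names)
        for t in self.terms:
            for v in filter(None, (t.var, t.var2)):
                if v not in names:
                    raise DesignError(
                        f"design variable {v!r} not among pixel covariates {sorted(names)}"
                    )

    def column_labels(self, pixels: PixelTable) -> list[str]:
        labels = ["intercept"] if self.intercept else []
        for t in self.terms:
            if t.kind == "indicator":
                levels = sorted(pd.unique(pixels.frame[t.var].astype(str)))
                labels.extend(f"{t.var}[{lv}]" for lv in levels[1:])
            else:
                labels.append(t.label())
        return labels

    def fundamental_variables(self) -> list[str]:
        out: list[str] = []
        for t in self.terms:
            for v in filter(None, (t.var, t.var2)):
                if v not in out:
                    out.append(v)
        return out


def build_design(pixels: PixelTable, spec: DesignSpec) -> pd.DataFrame:
    """Build the M-column design matrix W, one row per pixel.

    Deterministic: column order follows the spec's term order. Raises
    :class:`DesignError` for unknown variables and :class:`DataError` naming
    the offending pixel for non-finite covariate values.
    """
    spec.validate(pixels)
    df = pixels.frame
    for t in spec.terms:
        for v in filter(None, (t.var, t.var2)):
            if t.kind == "indicator":
                continue
            col = df[v].to_numpy(dtype=float)
            if not np.isfinite(col).all():
                bad = df.loc[~np.isfinite(col), "pixel_id"].tolist()
                raise DataError(f"non-finite covariate {v!r} at pixels {bad[:5]}")
    cols: dict[str, np.ndarray] = {}
    if spec.intercept:
        cols["intercept"] = np.ones(len(df))
    for t in spec.terms:
        if t.kind == "linear":
            cols[t.label()] = df[t.var].to_numpy(dtype=float)
        elif t.kind == "square":
            x = df[t.var].to_numpy(dtype=float)
            cols[t.label()] = x * x
        elif t.kind == "interaction":
            cols[t.label()] = df[t.var].to_numpy(dtype=float) * df[t.var2].to_numpy(dtype=float)
        elif t.kind == "hinge_below":
            x = df[t.var].to_numpy(dtype=float)
            cols[t.label()] = np.maximum(t.pivot - x, 0.0)
        elif t.kind == "hinge_above":
            x = df[t.var].to_numpy(dtype=float)
            cols[t.label()] = np.maximum(x - t.pivot, 0.0)
        elif t.kind == "indicator":
            g = df[t.var].astype(str)
            levels = sorted(pd.unique(g))
            for lv in levels[1:]:
                cols[f"{t.var}[{lv}]"] = (g == lv).to_numpy(dtype=float)
    W = pd.DataFrame(cols, index=df.index)
    W.index = df["pixel_id"].to_numpy()
    return W


# ---------------------------------------------------------------------------
# Pixel geometry
# ---------------------------------------------------------------------------


def pixel_area(lat_center: float | np.ndarray, resolution: float = 5.0) -> float | np.ndarray:
    """Area in km^2 of a square graticule cell centred at ``lat_center`` degrees.

    Spherical quadrilateral on a sphere of radius :data:`EARTH_RADIUS_KM`:
    ``A = R^2 * dlambda * (sin(phi_top) - sin(phi_bot))`` with ``dlambda`` the
    cell width in radians. ``resolution`` is the cell size in arc-minutes
    (default 5', about 86 km^2 at the equator). Symmetric in +/-lat and
    strictly decreasing in |lat|.
    """
    lat = np.asarray(lat_center, dtype=float)
    half = resolution / 120.0  # half cell height in degrees
    if np.any(np.abs(lat) + half > 90.0 + 1e-12):
        raise GridError(
            f"cell of resolution {resolution}' centred at lat {lat} crosses a pole"
        )
    dlam = np.deg2rad(resolution / 60.0)
    top = np.sin(np.deg2rad(lat + half))
    bot = np.sin(np.deg2rad(lat - half))
    area = EARTH_RADIUS_KM**2 * dlam * (top - bot)
    return float(area) if np.isscalar(lat_center) else area


def block_downscale(
    coarse: pd.DataFrame | np.ndarray,
    fine_lat: np.ndarray,
    fine_lon: np.ndarray,
    *,
    coarse_resolution: float = 30.0,
    origin: tuple[float, float] = (-90.0, -180.0),
    pixel_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Assign each fine pixel centre the value of its parent coarse cell.

    ``coarse`` is a 2-D array (rows = latitude bands south to north, columns =
    longitude west to east) aligned to the global graticule at ``origin`` with
    cells of ``coarse_resolution`` arc-minutes; cells are half-open [lo, hi) so
    boundary centres are unambiguous. A fine centre outside the coarse array,
    or falling in a missing (NaN) coarse cell, raises :class:`GridError`
    naming the pixels.
    """
    vals = np.asarray(coarse, dtype=float)
    if vals.ndim != 2:
        raise GridError("coarse grid must be 2-dimensional (lat x lon)")
    lat = np.asarray(fine_lat, dtype=float)
    lon = np.asarray(fine_lon, dtype=float)
    ids = np.asarray(pixel_ids) if pixel_ids is not None else np.arange(lat.size)
    step = coarse_resolution / 60.0
    rows = np.floor((lat - origin[0]) / step).astype(int)
    cols = np.floor((lon - origin[1]) / step).astype(int)
    outside = (rows < 0) | (rows >= vals.shape[0]) | (cols < 0) | (cols >= vals.shape[1])
    if outside.any():
        raise GridError(
            f"fine pixels outside coarse coverage: {list(ids[outside][:10])}"
        )
    out = vals[rows, cols]
    if np.isnan(out).any():
        raise GridError(
            "fine pixels fall in missing (NaN) coarse cells: "
            f"{list(ids[np.isnan(out)][:10])}"
        )
    return out


# ---------------------------------------------------------------------------
# Sample-selection filters
# ---------------------------------------------------------------------------


def apply_exclusions(pixels: PixelTable) -> PixelTable:
    """Drop pixels flagged as excluded (urban centres, protected areas).

    Logs the count removed per unit; a unit losing all of its pixels cannot be
    modelled and raises :class:`EmptyUnitError`.
    """
    df = pixels.frame
    flagged = df["excluded"].astype(bool)
    if not flagged.any():
        return pixels
    per_unit = df.groupby("unit_l1")["excluded"].agg(["sum", "count"])
    dead = per_unit[per_unit["sum"] == per_unit["count"]]
    if len(dead):
        raise EmptyUnitError(
            f"all pixels excluded for units {list(dead.index[:5])}; cannot model them"
        )
    for unit, row in per_unit[per_unit["sum"] > 0].iterrows():
        logger.info("apply_exclusions: unit %s: removed %d of %d pixels", unit, row["sum"], row["count"])
    return PixelTable(df.loc[~flagged])


def select_units(
    shares: "AggregateShares | pd.DataFrame",
    min_share: float = 0.005,
    crops: Sequence[str] | None = None,
):
    """Keep units growing at least ``min_share`` of their land in every listed
    crop, with listed crop shares summing to at most 1.

    Accepts a validated :class:`AggregateShares` (``crops`` defaults to all
    non-base categories) or a raw wide DataFrame of reported crop shares —
    the form the sum-cap filter exists for, since raw census shares can sum
    past 1 (multiple cropping seasons) and only become a valid composition
    once filtered and a base residual added. The threshold comparison is
    inclusive (share exactly at the threshold is kept). Idempotent and
    deterministic; raises :class:`SelectionError` when nothing survives;
    returns the same type it was given.
    """
    if not 0.0 <= min_share < 1.0:
        raise DataError(f"min_share must lie in [0, 1), got {min_share}")
    raw = isinstance(shares, pd.DataFrame)
    frame = shares if raw else shares.frame
    all_crops = list(frame.columns) if raw else shares.crops
    crop_list = list(crops) if crops is not None else (all_crops if raw else all_crops[1:])
    unknown = set(crop_list) - set(all_crops)
    if unknown:
        raise DataError(f"unknown crops {sorted(unknown)}")
    sub = frame[crop_list]
    keep = (sub >= min_share).all(axis=1) & (sub.sum(axis=1) <= 1.0 + 1e-12)
    if not keep.any():
        raise SelectionError(
            f"no unit has >= {min_share:.4g} share in all of {crop_list}"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("select_units: dropped %d of %d units", dropped, len(keep))
    return frame.loc[keep] if raw else AggregateShares(frame.loc[keep])
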