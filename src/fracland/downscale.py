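"""Pixel-level prediction, Level-1 calibration and harvested-area conversion.

Fitted coefficients give every pixel a predicted share vector (softmax of
the design row), on estimation pixels or on new grids. Because the model
matches unit totals only in quasi-likelihood expectation, predictions are
then rescaled so that the area-weighted aggregate of each crop within each
Level-1 unit equals the observed share exactly: every pixel fraction in
unit j is multiplied by r_jk = y_jk / H_jk. A pixel whose scaled fraction
would exceed 1 is capped at 1 (with a warning and the unit's resulting
shortfall recorded); no redistribution is attempted, so the scaled grid is
calibrated per crop, not a joint composition. Fractions convert to
harvested areas by multiplying with the pixel land area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, PredictionError
from .grid import AggregateShares, DesignSpec, PixelTable, build_design
from .likelihood import ModelSpec, aggregate_shares, pixel_shares

logger = logging.getLogger(__name__)


@dataclass
class PredictionGrid:
    """Per-pixel per-crop fractions: raw model output and (optionally) the
    Level-1 calibrated version, plus membership and area columns."""

    pixels: PixelTable
    crops: list[str]
    raw: pd.DataFrame  # index: pixel_id, columns: crops
    scaled: pd.DataFrame | None = None
    capping: pd.DataFrame | None = field(default=None, repr=False)

    def fractions(self, kind: str = "raw") -> pd.DataFrame:
        if kind == "raw":
            return self.raw
        if kind == "scaled":
            if self.scaled is None:
                raise PredictionError("grid has not been scaled to Level-1 totals")
            return self.scaled
        raise ValueError(f"kind must be 'raw' or 'scaled', got {kind!r}")

    def aggregate(self, level: int = 1, kind: str = "raw") -> pd.DataFrame:
        """Area-weighted unit share aggregates of the chosen fractions."""
        frac = self.fractions(kind)
        col = "unit_l1" if level == 1 else "unit_l2"
        df = self.pixels.frame
        if level == 2 and not self.pixels.has_level2:
            raise PredictionError("pixels carry no complete Level-2 membership")
        units = pd.Index(pd.unique(df[col]))
        codes = units.get_indexer(df[col])
        H = aggregate_shares(
            frac.to_numpy(dtype=float), df["area"].to_numpy(dtype=float), codes, len(units)
        )
        return pd.DataFrame(H, index=units, columns=self.crops)

    def to_long(self) -> pd.DataFrame:
        """Long export: pixel_id, crop, raw_fraction, scaled_fraction, area_km2."""
        df = self.pixels.frame
        out = self.raw.reset_index(names="pixel_id").melt(
            id_vars="pixel_id", var_name="crop", value_name="raw_fraction"
        )
        if self.scaled is not None:
            sc = self.scaled.reset_index(names="pixel_id").melt(
                id_vars="pixel_id", var_name="crop", value_name="scaled_fraction"
            )
            out = out.merge(sc, on=["pixel_id", "crop"])
        else:
            out["scaled_fraction"] = np.nan
        areas = df.set_index("pixel_id")["area"]
        out["area_km2"] = out["pixel_id"].map(areas)
        return out.sort_values(["pixel_id", "crop"], kind="stable").reset_index(drop=True)


def predict_pixels(
    model: ModelSpec,
    pixels: PixelTable,
    design: DesignSpec,
    crops: list[str] | None = None,
) -> PredictionGrid:
    """Raw share predictions for every pixel (works out-of-sample: any pixel
    table carrying the design covariates)."""
    W = build_design(pixels, design)
    G = pixel_shares(W.to_numpy(dtype=float), model)
    names = crops if crops is not None else [f"cat{k + 1}" for k in range(model.K)]
    if len(names) != model.K:
        raise DataError(f"need {model.K} crop names, got {len(names)}")
    raw = pd.DataFrame(G, index=pd.Index(pixels.frame["pixel_id"], name="pixel_id"), columns=names)
    return PredictionGrid(pixels=pixels, crops=list(names), raw=raw)


def scale_to_level1(grid: PredictionGrid, observed: AggregateShares) -> PredictionGrid:
    """Calibrate pixel fractions so Level-1 aggregates match observed shares.

    Per unit j and crop k the ratio r_jk = y_jk / H_jk multiplies every
    member pixel's raw fraction; afterwards the area-weighted aggregate
    equals y_jk exactly unless capping triggered. Scaled fractions above 1
    are capped at 1 with a warning, and the per-unit shortfall
    (y_jk - achieved aggregate) is recorded on ``grid.capping``.
    """
    df = grid.pixels.frame
    crops = [c for c in grid.crops if c in observed.crops]
    pixel_units = pd.unique(df["unit_l1"])
    missing = set(pixel_units) - set(observed.units)
    if missing:
        raise PredictionError(f"units without observed shares: {sorted(map(str, missing))[:5]}")
    H = grid.aggregate(level=1, kind="raw")
    scaled = grid.raw.copy()
    unit_of_pixel = df["unit_l1"].to_numpy()
    cap_records = []
    for k in crops:
        Hk = H[k]
        if (Hk <= 0).any():
            bad = Hk.index[Hk <= 0][:5].tolist()
            raise PredictionError(f"zero aggregate prediction for crop {k!r} in units {bad}")
        yk = observed.frame[k].reindex(Hk.index)
        r = (yk / Hk).to_numpy()
        ratios = pd.Series(r, index=Hk.index)
        scaled[k] = grid.raw[k].to_numpy() * ratios.reindex(unit_of_pixel).to_numpy()
    over = scaled[crops] > 1.0
    if over.to_numpy().any():
        n_over = int(over.to_numpy().sum())
        scaled[crops] = scaled[crops].clip(upper=1.0)
        warnings.warn(
            f"scale_to_level1: capped {n_over} pixel fractions at 1.0; "
            "unit aggregates for affected crops fall short of observed shares",
            RuntimeWarning,
            stacklevel=2,
        )
    out = PredictionGrid(pixels=grid.pixels, crops=grid.crops, raw=grid.raw, scaled=scaled)
    achieved = out.aggregate(level=1, kind="scaled")
    for k in crops:
        short = observed.frame[k].reindex(achieved.index) - achieved[k]
        for unit, s in short[short.abs() > 1e-9].items():
            cap_records.append({"unit_l1": unit, "crop": k, "shortfall": float(s)})
            logger.warning(
                "scale_to_level1: unit %s crop %s shortfall %.4g after capping", unit, k, s
            )
    out.capping = pd.DataFrame(cap_records, columns=["unit_l1", "crop", "shortfall"])
    return out


def harvested_area(
    grid: PredictionGrid, kind: str = "raw"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Convert fractions to harvested areas (km^2).

    Returns (per-pixel areas, Level-1 unit totals, Level-2 unit totals or
    None). Pixel crop area = fraction x pixel land area; unit totals sum
    member pixels and are additive across nesting levels.
    """
    frac = grid.fractions(kind)
    df = grid.pixels.frame
    areas = df.set_index("pixel_id")["area"]
    per_pixel = frac.mul(areas.reindex(frac.index), axis=0)
    by_l1 = per_pixel.groupby(df.set_index("pixel_id")["unit_l1"].reindex(frac.index)).sum()
    by_l1.index.name = "unit_l1"
    by_l2 = None
    if grid.pixels.has_level2:
        by_l2 = per_pixel.groupby(df.set_index("pixel_id")["unit_l2"].reindex(frac.index)).sum()
        by_l2.index.name = "unit_l2"
    return per_pixel, by_l1, by_l2


def naive_allocation(level2_shares: AggregateShares, pixels: PixelTable) -> PredictionGrid:
    """Constant-share baseline: every pixel inherits its Level-2 unit's
    observed share vector."""
    df = pixels.frame
    if "unit_l2" not in df.columns or df["unit_l2"].isna().any():
        bad = df.loc[df.get("unit_l2", pd.Series(np.nan, index=df.index)).isna(), "pixel_id"]
        raise PredictionError(
            f"pixels without Level-2 membership: {bad.tolist()[:5] or 'all'}"
        )
    missing = set(pd.unique(df["unit_l2"])) - set(level2_shares.units)
    if missing:
        raise PredictionError(
            f"Level-2 units without observed shares: {sorted(map(str, missing))[:5]}"
        )
    vals = level2_shares.frame.reindex(df["unit_l2"]).to_numpy(dtype=float)
    raw = pd.DataFrame(
        vals,
        index=pd.Index(df["pixel_id"], name="pixel_id"),
        columns=level2_shares.crops,
    )
    return PredictionGrid(pixels=pixels, crops=level2_shares.crops, raw=raw)
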