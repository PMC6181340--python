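"""Delimited-text and structured-document interchange.

Formats:

* pixel table — CSV with columns ``pixel_id, unit_l1, [unit_l2], lat, lon,
  [area], excluded, <covariate columns>``; a missing ``area`` column is
  computed from latitude with the spherical cell formula;
* aggregate shares — long CSV ``unit_l1, crop, share`` (base category
  reconstructed as the residual when absent);
* design specification — plain YAML/JSON mapping (term list + intercept);
* fit results — JSON document holding the coefficient table (crop, term,
  estimate, se, t), log-likelihood, J, options, seed and the covariance
  convention, sufficient to rebuild the fitted model for prediction;
* prediction grids — long CSV ``pixel_id, crop, raw_fraction,
  scaled_fraction, area_km2``;
* validation reports — JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import DataError, DesignError
from .grid import AggregateShares, DesignSpec, PixelTable, Term, pixel_area

PARAM_ORDER_NOTE = (
    "parameters flat, crop-major (first non-base category's M coefficients, "
    "then the next); F and B of the sandwich are per-unit averages"
)


def read_pixel_table(path: str | Path, resolution: float = 5.0) -> PixelTable:
    df = pd.read_csv(path)
    if "area" not in df.columns:
        if "lat" not in df.columns:
            raise DataError("pixel table needs 'lat' (and 'lon') to derive areas")
        df["area"] = pixel_area(df["lat"].to_numpy(dtype=float), resolution)
    if "excluded" not in df.columns:
        df["excluded"] = False
    return PixelTable(df)


def write_pixel_table(pixels: PixelTable, path: str | Path) -> None:
    pixels.frame.to_csv(path, index=False)


def read_shares(path: str | Path, base: str | None = None) -> AggregateShares:
    df = pd.read_csv(path)
    need = {"unit_l1", "crop", "share"}
    if not need <= set(df.columns):
        raise DataError(f"shares file must have columns {sorted(need)}")
    return AggregateShares.from_long(df, base=base)


def write_shares(shares: AggregateShares, path: str | Path) -> None:
    shares.to_long().to_csv(path, index=False)


# -- design spec ------------------------------------------------------------


def design_to_dict(spec: DesignSpec) -> dict:
    terms = []
    for t in spec.terms:
        if t.kind == "interaction":
            terms.append({t.kind: [t.var, t.var2]})
        elif t.kind in ("hinge_below", "hinge_above"):
            terms.append({t.kind: {"var": t.var, "pivot": t.pivot}})
        else:
            terms.append({t.kind: t.var})
    return {"intercept": spec.intercept, "terms": terms}


def design_from_dict(doc: dict) -> DesignSpec:
    terms = []
    for entry in doc.get("terms", []):
        if not isinstance(entry, dict) or len(entry) != 1:
            raise DesignError(f"malformed design term {entry!r}")
        kind, val = next(iter(entry.items()))
        if kind == "interaction":
            terms.append(Term(kind, val[0], var2=val[1]))
        elif kind in ("hinge_below", "hinge_above"):
            terms.append(Term(kind, val["var"], pivot=float(val["pivot"])))
        else:
            terms.append(Term(kind, val))
    return DesignSpec(terms=terms, intercept=bool(doc.get("intercept", True)))


def read_design(path: str | Path) -> DesignSpec:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def write_design(spec: DesignSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(spec), fh, sort_keys=False)


# -- fit results ------------------------------------------------------------


def config_hash(doc: dict) -> str:
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def save_fit(results, path: str | Path, *, seed: int | None = None, options: dict | None = None):
    """Serialize fit results (with enough structure to predict from later)."""
    model = results.model
    doc = {
        "tool": "fracland",
        "version": __version__,
        "seed": seed,
        "options": options or {},
        "convention": PARAM_ORDER_NOTE,
        "crops": model.shares.crops,
        "design": design_to_dict(model.design),
        "n_units": int(results.n_units),
        "n_pixels": int(model.pixels.n_pixels),
        "loglik": float(results.llf),
        "converged": bool(results.converged),
        "iterations": int(results.iterations),
        "grad_norm": float(results.grad_norm),
        "coefficients": results.coef_table().to_dict(orient="records"),
        "vcov": np.asarray(results.cov_params()).tolist(),
    }
    doc["config_hash"] = config_hash(
        {"design": doc["design"], "crops": doc["crops"], "options": doc["options"]}
    )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return doc


def load_fit(path: str | Path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    doc["beta"] = np.array([row["estimate"] for row in doc["coefficients"]])
    return doc


def write_manifest(path: str | Path, doc: dict, *, seed=None) -> dict:
    doc = {"tool": "fracland", "version": __version__, "seed": seed, **doc}
    doc["config_hash"] = config_hash(doc)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
    return doc
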