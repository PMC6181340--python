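"""Marginal effects and odds ratios of covariates on pixel crop fractions.

For the multinomial logit, the effect of covariate x on the share of
category k at a pixel is, by the chain rule,

    dG_k/dx = G_k * (de_k/dx - sum_l G_l * de_l/dx)

where e_k = W(X) b_k is the linear predictor (e_1 = 0). The derivative
de_k/dx collects every design term containing x: b for a linear term,
2*b*x for a square, b*x_other for an interaction, and the subgradient of
hinge terms (-b below the pivot, +b above, 0 exactly at the kink). Effects
sum to zero over categories at every pixel because shares sum to one.

The log odds of category k against the base equal e_k, so the odds ratio
for a one-unit change in x is exp(de_k/dx): exactly exp(b_km) when x enters
through a single linear term, and a per-pixel quantity averaged over the
sample otherwise. Reported averages are unweighted means over the included
(non-excluded) pixels; area weighting is available as an option. Indicator
(group) variables are reported as discrete changes in G, not derivatives.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import DesignError
from .grid import DesignSpec, PixelTable, Term
from .likelihood import ModelSpec, pixel_shares


def _term_width(t: Term, pixels: PixelTable) -> int:
    if t.kind == "indicator":
        return len(pd.unique(pixels.frame[t.var].astype(str))) - 1
    return 1


def linear_predictor_derivative(
    model: ModelSpec, pixels: PixelTable, design: DesignSpec, variable: str
) -> tuple[np.ndarray, bool]:
    """de_k/d(variable) per pixel, shape (n, K); second value is False when
    the variable appears in no design term (derivative identically zero)."""
    B = model.beta_matrix()  # (M, K)
    df = pixels.frame
    n = len(df)
    dEta = np.zeros((n, model.K))
    m = 1 if design.intercept else 0
    found = False
    for t in design.terms:
        if t.kind == "indicator":
            m += _term_width(t, pixels)
            continue
        d = None
        if t.kind == "linear" and t.var == variable:
            d = np.ones(n)
        elif t.kind == "square" and t.var == variable:
            d = 2.0 * df[t.var].to_numpy(dtype=float)
        elif t.kind == "interaction" and variable in (t.var, t.var2):
            other = t.var2 if t.var == variable else t.var
            d = df[other].to_numpy(dtype=float)
            if t.var == t.var2:  # pragma: no cover - degenerate x*x interaction
                d = 2.0 * d
        elif t.kind == "hinge_below" and t.var == variable:
            x = df[t.var].to_numpy(dtype=float)
            d = -(x < t.pivot).astype(float)  # 0 at the kink by convention
        elif t.kind == "hinge_above" and t.var == variable:
            x = df[t.var].to_numpy(dtype=float)
            d = (x > t.pivot).astype(float)
        if d is not None:
            dEta += d[:, None] * B[m][None, :]
            found = True
        m += 1
    return dEta, found


def _hinge_derivative(model: ModelSpec, pixels: PixelTable, design: DesignSpec, label: str):
    """de_k/d(hinge term) treating the hinge-transformed value as the regressor."""
    B = model.beta_matrix()
    m = 1 if design.intercept else 0
    for t in design.terms:
        if t.kind in ("hinge_below", "hinge_above") and t.label() == label:
            return np.broadcast_to(B[m][None, :], (pixels.n_pixels, model.K))
        m += _term_width(t, pixels)
    raise DesignError(f"no hinge term labelled {label!r}")


def marginal_effect(
    model: ModelSpec,
    pixels: PixelTable,
    design: DesignSpec,
    variable: str,
    *,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel effects dG/d(variable), shape (n, K), and their average.

    ``variable`` is a fundamental covariate; all design terms containing it
    contribute via the chain rule. A variable absent from the design yields
    an exact zero effect with a warning. Averages are unweighted by default
    (``weighted=True`` area-weights them).
    """
    W = _design_matrix(pixels, design)
    G = pixel_shares(W, model)
    dEta, found = linear_predictor_derivative(model, pixels, design, variable)
    if not found:
        warnings.warn(
            f"variable {variable!r} appears in no design term; effect is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    per_pixel = G * (dEta - np.einsum("ik,ik->i", G, dEta)[:, None])
    return per_pixel, _average(per_pixel, pixels, weighted)


def _design_matrix(pixels: PixelTable, design: DesignSpec) -> np.ndarray:
    from .grid import build_design

    return build_design(pixels, design).to_numpy(dtype=float)


def _average(per_pixel: np.ndarray, pixels: PixelTable, weighted: bool) -> np.ndarray:
    if weighted:
        w = pixels.frame["area"].to_numpy(dtype=float)
        return (per_pixel * w[:, None]).sum(axis=0) / w.sum()
    return per_pixel.mean(axis=0)


def _is_linear_only(design: DesignSpec, variable: str) -> bool:
    hits = [t for t in design.terms if variable in (t.var, t.var2)]
    return len(hits) == 1 and hits[0].kind == "linear"


def odds_ratio(
    model: ModelSpec,
    pixels: PixelTable,
    design: DesignSpec,
    variable: str,
    crop_index: int,
    *,
    weighted: bool = False,
) -> float:
    """Odds ratio against the base category for a one-unit change in
    ``variable``, for free category ``crop_index`` (1-based over categories,
    so 1 is the first crop after the base).

    Exactly exp(b) when the variable enters through a single linear term;
    otherwise the pixel-average of exp(de_k/dx).
    """
    if not 1 <= crop_index <= model.K - 1:
        raise DesignError(f"crop_index must be in [1, {model.K - 1}]")
    dEta, found = linear_predictor_derivative(model, pixels, design, variable)
    if not found:
        return 1.0
    col = dEta[:, crop_index]
    if _is_linear_only(design, variable):
        return float(np.exp(col[0]))
    if weighted:
        w = pixels.frame["area"].to_numpy(dtype=float)
        return float(np.average(np.exp(col), weights=w))
    return float(np.exp(col).mean())


def indicator_effect(
    model: ModelSpec,
    pixels: PixelTable,
    design: DesignSpec,
    group: str,
    level: str,
    *,
    weighted: bool = False,
) -> np.ndarray:
    """Discrete-change effect of an indicator level: average of
    G(level) - G(base level) over pixels, one entry per category.

    Works on the design-matrix columns directly (every pixel's indicator
    block switched to the base level resp. the target level), so the level
    set — hence the design layout — is unchanged."""
    levels = sorted(pd.unique(pixels.frame[group].astype(str)))
    if level not in levels:
        raise DesignError(f"level {level!r} not among {levels}")
    W = _design_matrix(pixels, design)
    m = None
    for t in design.terms:
        if t.kind == "indicator" and t.var == group:
            m = _indicator_offset(design, pixels, t)
            break
    if m is None:
        raise DesignError(f"no indicator term on {group!r} in the design")
    width = len(levels) - 1
    W_lo = W.copy()
    W_lo[:, m : m + width] = 0.0  # base level: all indicator columns off
    W_hi = W_lo.copy()
    if level != levels[0]:
        W_hi[:, m + levels[1:].index(level)] = 1.0
    G_lo = pixel_shares(W_lo, model)
    G_hi = pixel_shares(W_hi, model)
    return _average(G_hi - G_lo, pixels, weighted)


def effects_table(results, variables=None, weighted: bool = False) -> pd.DataFrame:
    """Average marginal effects and odds ratios per (variable, crop).

    Mirrors the conventional reporting layout: continuous fundamental
    variables get chain-rule derivative effects; each hinge term is reported
    as its own row (the transformed value treated as the regressor, so its
    odds ratio is exactly exp(b)); indicator levels get discrete-change
    effects with exp(b) odds ratios.
    """
    model = results.model_spec
    pixels = results.model.pixels
    design = results.model.design
    crops = results.model.shares.crops[1:]

    rows = []

    def add_rows(label, avg_effect, ors):
        for k, crop in enumerate(crops):
            rows.append(
                {
                    "variable": label,
                    "crop": crop,
                    "marginal_effect": avg_effect[k + 1],
                    "odds_ratio": ors[k],
                }
            )

    continuous = []
    for t in design.terms:
        if t.kind in ("linear", "square", "interaction"):
            for v in filter(None, (t.var, t.var2)):
                if v not in continuous:
                    continuous.append(v)
    if variables is not None:
        continuous = [v for v in continuous if v in variables]

    for v in continuous:
        _, avg = marginal_effect(model, pixels, design, v, weighted=weighted)
        ors = [
            odds_ratio(model, pixels, design, v, k + 1, weighted=weighted)
            for k in range(len(crops))
        ]
        add_rows(v, avg, ors)

    W = _design_matrix(pixels, design)
    G = pixel_shares(W, model)
    for t in design.terms:
        if t.kind not in ("hinge_below", "hinge_above"):
            continue
        if variables is not None and t.label() not in variables and t.var not in variables:
            continue
        dEta = _hinge_derivative(model, pixels, design, t.label())
        per_pixel = G * (dEta - np.einsum("ik,ik->i", G, dEta)[:, None])
        avg = _average(per_pixel, pixels, weighted)
        ors = [float(np.exp(dEta[0, k + 1])) for k in range(len(crops))]
        add_rows(t.label(), avg, ors)

    B = model.beta_matrix()
    for t in design.terms:
        if t.kind != "indicator":
            continue
        levels = sorted(pd.unique(pixels.frame[t.var].astype(str)))
        m = _indicator_offset(design, pixels, t)
        for pos, lv in enumerate(levels[1:]):
            if variables is not None and f"{t.var}[{lv}]" not in variables:
                continue
            avg = indicator_effect(model, pixels, design, t.var, lv, weighted=weighted)
            ors = [float(np.exp(B[m + pos, k + 1])) for k in range(len(crops))]
            add_rows(f"{t.var}[{lv}]", avg, ors)

    return pd.DataFrame(rows, columns=["variable", "crop", "marginal_effect", "odds_ratio"])


def _indicator_offset(design: DesignSpec, pixels: PixelTable, target: Term) -> int:
    m = 1 if design.intercept else 0
    for t in design.terms:
        if t is target:
            return m
        m += _term_width(t, pixels)
    raise DesignError("indicator term not found in design")  # pragma: no cover
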