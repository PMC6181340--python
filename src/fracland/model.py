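"""Quasi-maximum likelihood estimation of the aggregated fractional logit.

:class:`AggFracLogit` is the model object: it binds observed unit-level crop
shares, the pixel table, and a design specification, and exposes
``loglike``/``score`` plus ``fit()``. Fitting maximises the multinomial
quasi-log-likelihood with BFGS using the analytic gradient, starting from
beta = 0 (uniform shares). :class:`AggFracLogitResults` carries the
estimates, their robust (sandwich) covariance, t-values, convergence
diagnostics, and a ``summary()`` table, and is the hub for prediction,
marginal effects and the unit-level block bootstrap.

The sandwich covariance is F^{-1} B F^{-1} / J where F is the (negated)
average per-unit Hessian of the quasi-log-likelihood at the maximiser —
obtained by central finite differences of the analytic score — and B the
average outer product of per-unit scores. Administrative units are the
independent sampling blocks, in both the outer product and the bootstrap
(which resamples units with replacement and carries all pixels of each
sampled unit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import DataError, EstimationError, SeparationError, SingularityError
from .grid import AggregateShares, DesignSpec, PixelTable, apply_exclusions, build_design
from .likelihood import (
    ModelSpec,
    aggregate_shares,
    area_weights,
    pixel_shares,
    quasi_loglik,
    score,
    unit_scores,
)

logger = logging.getLogger(__name__)

#: |beta| beyond which estimation is treated as separated/divergent
SEPARATION_BOUND = 1e3
#: condition number of F beyond which the design is treated as rank deficient
CONDITION_LIMIT = 1e10


class AggFracLogit:
    """Aggregated fractional multinomial logit model.

    Parameters
    ----------
    shares : AggregateShares
        Observed per-unit share fractions, base category first.
    pixels : PixelTable
        Pixels with covariates, areas and unit memberships. Excluded pixels
        (urban/protected) are dropped before estimation unless
        ``drop_excluded=False``.
    design : DesignSpec
        Covariate transformations W(X).
    """

    def __init__(
        self,
        shares: AggregateShares,
        pixels: PixelTable,
        design: DesignSpec,
        *,
        drop_excluded: bool = True,
    ):
        if drop_excluded:
            pixels = apply_exclusions(pixels)
        missing = set(map(str, shares.units)) - set(map(str, pixels.units))
        if missing:
            raise DataError(
                f"units in shares without any (non-excluded) pixel: {sorted(missing)[:5]}"
            )
        # restrict pixels to the estimation units, in the shares' unit order
        keep = pixels.frame["unit_l1"].isin(set(shares.units))
        pixels = PixelTable(pixels.frame.loc[keep])
        self.shares = shares
        self.pixels = pixels
        self.design = design

        self.W_frame = build_design(pixels, design)
        self.exog = self.W_frame.to_numpy(dtype=float)
        self.endog = shares.values
        unit_index = pd.Index(shares.units)
        self.unit_codes = unit_index.get_indexer(pixels.frame["unit_l1"])
        self.n_units = shares.n_units
        self.K = shares.K
        self.M = self.exog.shape[1]
        self.areas = pixels.frame["area"].to_numpy(dtype=float)
        self.weights = area_weights(self.areas, self.unit_codes, self.n_units)
        self.param_names = [
            f"{crop}:{col}" for crop in shares.crops[1:] for col in self.W_frame.columns
        ]
        # per-unit pixel index lists, used by the block bootstrap
        self._unit_pixels = [
            np.flatnonzero(self.unit_codes == j) for j in range(self.n_units)
        ]

    # -- likelihood surface -------------------------------------------------

    def _spec(self, params: np.ndarray) -> ModelSpec:
        return ModelSpec(K=self.K, M=self.M, beta=np.asarray(params, dtype=float))

    def predict_G(self, params: np.ndarray, exog: np.ndarray | None = None) -> np.ndarray:
        """Pixel share matrix G at ``params`` (estimation pixels by default)."""
        W = self.exog if exog is None else np.asarray(exog, dtype=float)
        return pixel_shares(W, self._spec(params))

    def fitted_H(self, params: np.ndarray) -> np.ndarray:
        """Unit share matrix H at ``params`` (area-weighted aggregate of G)."""
        G = self.predict_G(params)
        return aggregate_shares(G, self.areas, self.unit_codes, self.n_units)

    def loglike(self, params: np.ndarray) -> float:
        return quasi_loglik(self.endog, self.fitted_H(params))

    def score(self, params: np.ndarray) -> np.ndarray:
        G = self.predict_G(params)
        return score(self.endog, self.exog, G, self.weights, self.unit_codes)

    def score_obs(self, params: np.ndarray) -> np.ndarray:
        """Per-unit score contributions s_j, shape (J, n_params)."""
        G = self.predict_G(params)
        return unit_scores(self.endog, self.exog, G, self.weights, self.unit_codes)

    # -- estimation ---------------------------------------------------------

    def fit(
        self,
        start_params: np.ndarray | None = None,
        *,
        tol: float = 1e-6,
        max_iter: int = 500,
        cov_type: str = "sandwich",
    ) -> "AggFracLogitResults":
        """Maximise the quasi-log-likelihood by BFGS with the analytic score.

        Converged means the gradient max-norm fell below ``tol``. A
        non-converged fit is returned flagged, with a warning, never
        silently; parameters diverging past :data:`SEPARATION_BOUND` raise
        :class:`SeparationError`.
        """
        x0 = (
            np.zeros((self.K - 1) * self.M)
            if start_params is None
            else np.asarray(start_params, dtype=float)
        )

        def neg_ll(p):
            if np.max(np.abs(p)) > SEPARATION_BOUND:
                raise SeparationError(
                    f"parameters diverging past {SEPARATION_BOUND:g}; "
                    "likely separation or an unidentified design"
                )
            return -self.loglike(p)

        def neg_score(p):
            return -self.score(p)

        res = optimize.minimize(
            neg_ll,
            x0,
            jac=neg_score,
            method="BFGS",
            options={"gtol": tol, "maxiter": max_iter},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = grad_norm < tol
        if not converged:
            warnings.warn(
                f"QMLE did not converge in {res.nit} iterations "
                f"(gradient max-norm {grad_norm:.3g} >= {tol:g})",
                RuntimeWarning,
                stacklevel=2,
            )
        if np.max(np.abs(res.x)) > SEPARATION_BOUND:
            raise SeparationError("estimates exceed the separation bound")
        results = AggFracLogitResults(
            model=self,
            params=res.x,
            llf=float(-res.fun),
            converged=converged,
            iterations=int(res.nit),
            grad_norm=grad_norm,
            tol=tol,
        )
        if cov_type == "sandwich":
            results._vcov = sandwich_cov(self, res.x)
        elif cov_type != "none":
            raise ValueError(f"unknown cov_type {cov_type!r}")
        return results


def hessian_fd(model: AggFracLogit, params: np.ndarray) -> np.ndarray:
    """Hessian of the quasi-log-likelihood by central finite differences of
    the analytic score (step 1e-5 * max(1, |beta_i|) per coordinate)."""
    params = np.asarray(params, dtype=float)
    p = params.size
    Hmat = np.empty((p, p))
    for i in range(p):
        h = 1e-5 * max(1.0, abs(params[i]))
        up = params.copy()
        dn = params.copy()
        up[i] += h
        dn[i] -= h
        Hmat[:, i] = (model.score(up) - model.score(dn)) / (2 * h)
    return (Hmat + Hmat.T) / 2.0


def sandwich_cov(model: AggFracLogit, params: np.ndarray) -> np.ndarray:
    """Robust covariance F^{-1} B F^{-1} / J at ``params``.

    F is the negated average per-unit Hessian (finite differences of the
    analytic score), B the average outer product of per-unit scores; units
    are the sampling blocks. Raises :class:`SingularityError` when F is
    ill-conditioned (collinear design columns are the usual culprit).
    """
    J = model.n_units
    F = -hessian_fd(model, params) / J
    cond = np.linalg.cond(F)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularityError(
            f"Hessian condition number {cond:.3g} exceeds {CONDITION_LIMIT:g}; "
            "check the design for collinear or unidentified columns"
        )
    S = model.score_obs(params)
    B = (S.T @ S) / J
    Finv = np.linalg.inv(F)
    V = Finv @ B @ Finv / J
    V = (V + V.T) / 2.0
    eig = np.linalg.eigvalsh(V)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise EstimationError("sandwich covariance is not positive semi-definite")
    return V


def block_bootstrap_cov(
    model: AggFracLogit,
    params: np.ndarray,
    n_boot: int = 200,
    seed: int | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Unit-level block bootstrap covariance of the QMLE.

    Resamples the J units with replacement, carrying all pixels of each
    sampled unit (so the pixel-to-unit ratio is preserved), refits from the
    full-sample estimate, and returns the covariance of the replicate
    estimates. Non-converged replicates are dropped with a warning; more
    than 20% dropped is an error. Deterministic under a fixed ``seed``.
    """
    if n_boot < 2:
        raise EstimationError("need at least 2 bootstrap replicates to form a covariance")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is small; bootstrap covariance will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    J = model.n_units
    reps = []
    dropped = 0
    for b in range(n_boot):
        draw = rng.integers(0, J, size=J)
        idx = np.concatenate([model._unit_pixels[j] for j in draw])
        codes = np.repeat(np.arange(J), [model._unit_pixels[j].size for j in draw])
        y_b = model.endog[draw]
        W_b = model.exog[idx]
        areas_b = model.areas[idx]
        weights_b = area_weights(areas_b, codes, J)

        def neg_ll(p):
            G = pixel_shares(W_b, ModelSpec(K=model.K, M=model.M, beta=p))
            H = aggregate_shares(G, areas_b, codes, J)
            return -quasi_loglik(y_b, H)

        def neg_score(p):
            G = pixel_shares(W_b, ModelSpec(K=model.K, M=model.M, beta=p))
            return -score(y_b, W_b, G, weights_b, codes)

        try:
            res = optimize.minimize(
                neg_ll,
                np.asarray(params, dtype=float),
                jac=neg_score,
                method="BFGS",
                options={"gtol": tol, "maxiter": max_iter},
            )
        except (SeparationError, DataError):
            dropped += 1
            continue
        if np.max(np.abs(res.jac)) < max(tol, 1e-5) and np.max(np.abs(res.x)) < SEPARATION_BOUND:
            reps.append(res.x)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"block bootstrap: dropped {dropped}/{n_boot} non-converged replicates",
            RuntimeWarning,
            stacklevel=2,
        )
    if dropped > 0.2 * n_boot:
        raise EstimationError(
            f"block bootstrap unreliable: {dropped}/{n_boot} replicates failed to converge"
        )
    R = np.vstack(reps)
    return np.cov(R, rowvar=False, ddof=1)


@dataclass
class AggFracLogitResults:
    """Estimates, uncertainty and diagnostics from :meth:`AggFracLogit.fit`."""

    model: AggFracLogit
    params: np.ndarray
    llf: float
    converged: bool
    iterations: int
    grad_norm: float
    tol: float
    _vcov: np.ndarray | None = None

    # -- uncertainty --------------------------------------------------------

    def cov_params(self) -> np.ndarray:
        if self._vcov is None:
            self._vcov = sandwich_cov(self.model, self.params)
        return self._vcov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def n_units(self) -> int:
        return self.model.n_units

    def bootstrap_cov(self, n_boot: int = 200, seed: int | None = None) -> np.ndarray:
        return block_bootstrap_cov(self.model, self.params, n_boot=n_boot, seed=seed)

    # -- fitted objects -----------------------------------------------------

    @property
    def model_spec(self) -> ModelSpec:
        return ModelSpec(K=self.model.K, M=self.model.M, beta=self.params)

    def fitted_unit_shares(self) -> pd.DataFrame:
        H = self.model.fitted_H(self.params)
        return pd.DataFrame(H, index=self.model.shares.units, columns=self.model.shares.crops)

    def predict(self, pixels: PixelTable | None = None):
        """Raw pixel-level share predictions; see :func:`fracland.downscale.predict_pixels`."""
        from .downscale import predict_pixels

        return predict_pixels(
            self.model_spec,
            pixels if pixels is not None else self.model.pixels,
            self.model.design,
            crops=self.model.shares.crops,
        )

    def marginal_effects(self, variables=None, weighted: bool = False) -> pd.DataFrame:
        from .effects import effects_table

        return effects_table(self, variables=variables, weighted=weighted)

    # -- reporting ----------------------------------------------------------

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table: (crop, term, estimate, se, t)."""
        crops = np.repeat(self.model.shares.crops[1:], self.model.M)
        terms = list(self.model.W_frame.columns) * (self.model.K - 1)
        return pd.DataFrame(
            {
                "crop": crops,
                "term": terms,
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
            }
        )

    def summary(self) -> str:
        tab = self.coef_table()
        lines = [
            "Aggregated fractional multinomial logit (QMLE)",
            "=" * 62,
            f"units (J): {self.n_units:>6}    pixels: {self.model.pixels.n_pixels}",
            f"categories (K): {self.model.K}    design columns (M): {self.model.M}",
            f"log-likelihood: {self.llf:.6f}",
            f"converged: {self.converged}  iterations: {self.iterations}  "
            f"grad max-norm: {self.grad_norm:.3g}",
            "-" * 62,
            tab.to_string(
                index=False,
                formatters={
                    "estimate": "{:10.4f}".format,
                    "se": "{:8.4f}".format,
                    "t": "{:7.2f}".format,
                },
            ),
            "=" * 62,
            "Covariance: unit-block sandwich F^-1 B F^-1 / J "
            "(F, B averaged over units).",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<AggFracLogitResults J={self.n_units} K={self.model.K} M={self.model.M} "
            f"llf={self.llf:.4f} converged={self.converged}>"
        )
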