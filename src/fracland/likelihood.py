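"""Probability model for aggregated fractional multinomial logit.

The model says the expected fraction of pixel i (in unit j) allocated to
category k is a multinomial logit in the transformed covariates W_ij:

    G_ijk = exp(W_ij b_k) / sum_l exp(W_ij b_l),   b_1 = 0.

Pinning the base-category coefficients b_1 at zero identifies the remaining
K-1 coefficient vectors. The observed data are unit-level shares y_jk, so
pixel shares are aggregated by area weight,

    H_jk = sum_{i in j} G_ijk A_ij / sum_{i in j} A_ij,

and the quasi-log-likelihood maximised over the free parameters is the
multinomial form L = sum_j sum_k y_jk ln H_jk. This file holds the share
arithmetic and the analytic score; optimisation lives in :mod:`.model`.

Free parameters are stored flat in crop-major order: the M coefficients of
category 2, then category 3, and so on — covariance matrices returned by the
estimators index the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .exceptions import DataError, EmptyUnitError

SHARE_TOL = 1e-12


@dataclass
class ModelSpec:
    """K-category multinomial logit layout with base-category normalisation.

    ``beta`` holds the K-1 free M-vectors flat, crop-major; the base
    category's coefficients are structurally zero and never estimated.
    """

    K: int
    M: int
    beta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.K < 2:
            raise DataError("need K >= 2 categories")
        if self.beta is None:
            self.beta = np.zeros((self.K - 1) * self.M)
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.beta.size != (self.K - 1) * self.M:
            raise DataError(
                f"beta must have length (K-1)*M = {(self.K - 1) * self.M}, got {self.beta.size}"
            )

    @property
    def n_params(self) -> int:
        return (self.K - 1) * self.M

    def beta_matrix(self) -> np.ndarray:
        """(M, K) coefficient matrix with the base category's zero column first."""
        B = np.zeros((self.M, self.K))
        B[:, 1:] = self.beta.reshape(self.K - 1, self.M).T
        return B


def pixel_shares(W: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Predicted share matrix G (n_pixels x K), rows summing to one.

    Stable for linear predictors up to ~|700| via the usual log-sum-exp
    shift. A single design row is accepted and promoted.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[1] != model.M:
        raise DataError(f"design has {W.shape[1]} columns, model expects {model.M}")
    eta = W @ model.beta_matrix()
    if not np.isfinite(eta).all():
        raise DataError("non-finite linear predictor (check design and coefficients)")
    return softmax(eta, axis=1)


def aggregate_shares(
    G: np.ndarray, areas: np.ndarray, unit_codes: np.ndarray, n_units: int | None = None
) -> np.ndarray:
    """Area-weighted mean of pixel shares per unit: H (J x K).

    ``unit_codes`` are integer unit labels in [0, J). Every unit must own at
    least one pixel and areas must be positive.
    """
    G = np.asarray(G, dtype=float)
    areas = np.asarray(areas, dtype=float)
    codes = np.asarray(unit_codes)
    if np.any(areas <= 0):
        raise DataError("pixel areas must be positive")
    J = int(n_units if n_units is not None else codes.max() + 1)
    tot = np.bincount(codes, weights=areas, minlength=J)
    if np.any(tot == 0):
        empty = np.flatnonzero(tot == 0)
        raise EmptyUnitError(f"units with no pixels: {list(empty[:5])}")
    H = np.empty((J, G.shape[1]))
    for k in range(G.shape[1]):
        H[:, k] = np.bincount(codes, weights=G[:, k] * areas, minlength=J)
    return H / tot[:, None]


def area_weights(areas: np.ndarray, unit_codes: np.ndarray, n_units: int) -> np.ndarray:
    """Per-pixel weights A_ij / sum_{i in j} A_ij (sum to one within a unit)."""
    areas = np.asarray(areas, dtype=float)
    tot = np.bincount(unit_codes, weights=areas, minlength=n_units)
    return areas / tot[unit_codes]


def quasi_loglik(y: np.ndarray, H: np.ndarray) -> float:
    """Multinomial quasi-log-likelihood sum_j sum_k y_jk ln H_jk.

    Terms with y_jk = 0 contribute exactly zero; a zero H under positive y is
    an error (unreachable for interior softmax shares).
    """
    y = np.asarray(y, dtype=float)
    H = np.asarray(H, dtype=float)
    if y.shape != H.shape:
        raise DataError(f"shape mismatch: y {y.shape} vs H {H.shape}")
    pos = y > 0
    if np.any(H[pos] <= 0):
        j, k = np.argwhere(pos & (H <= 0))[0]
        raise DataError(f"H[{j},{k}] = 0 with positive observed share")
    out = np.zeros_like(y)
    out[pos] = y[pos] * np.log(H[pos])
    return float(out.sum())


def unit_scores(
    y: np.ndarray,
    W: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray,
    unit_codes: np.ndarray,
    H: np.ndarray | None = None,
) -> np.ndarray:
    """Per-unit score vectors s_j = dL_j/dbeta, shape (J, (K-1)*M).

    Derivation: dL/dH_jk = y_jk/H_jk, dH_jk/deta_ik' = w_i G_ik (1{k=k'} -
    G_ik'), deta_ik'/dbeta_k'm = W_im, with w_i the within-unit area weight.
    The unit rows sum to the total score, and unit j is the sampling block of
    the sandwich estimator's outer product.
    """
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    J, K = y.shape
    M = W.shape[1]
    if H is None:
        H = aggregate_shares(G, weights, unit_codes, J)  # weights scale cancels
    r = np.zeros_like(y)
    pos = y > 0
    r[pos] = y[pos] / H[pos]
    c = r[unit_codes]  # (n, K)
    t = np.einsum("ik,ik->i", c, G)
    # D[:, k'] = w_i * G_ik' * (c_ik' - t_i) for the K-1 free categories
    D = weights[:, None] * G[:, 1:] * (c[:, 1:] - t[:, None])
    S = np.zeros((J, (K - 1) * M))
    for kk in range(K - 1):
        contrib = D[:, kk][:, None] * W
        np.add.at(S[:, kk * M : (kk + 1) * M], unit_codes, contrib)
    return S


def score(
    y: np.ndarray,
    W: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray,
    unit_codes: np.ndarray,
    H: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic gradient of the quasi-log-likelihood, flat crop-major."""
    y = np.asarray(y, dtype=float)
    J, K = y.shape
    M = np.asarray(W).shape[1]
    if H is None:
        H = aggregate_shares(G, weights, unit_codes, J)
    r = np.zeros_like(y)
    pos = y > 0
    r[pos] = y[pos] / H[pos]
    c = r[unit_codes]
    t = np.einsum("ik,ik->i", c, G)
    D = weights[:, None] * G[:, 1:] * (c[:, 1:] - t[:, None])
    return (np.asarray(W).T @ D).T.ravel()
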