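"""QMLE fitting, sandwich covariance and block bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import logit

import fracland as fl

from conftest import make_dataset, make_pixels


class TestFit:
    def test_noiseless_recovery(self):
        pixels, shares, design, beta = make_dataset(J=60, K=2, seed=3)
        res = fl.AggFracLogit(shares, pixels, design).fit()
        assert res.converged
        assert np.abs(res.params - beta).max() < 1e-3

    def test_three_category_recovery(self):
        pixels, shares, design, beta = make_dataset(J=60, K=3, seed=9)
        res = fl.AggFracLogit(shares, pixels, design).fit()
        assert np.abs(res.params - beta).max() < 1e-3

    def test_ascent_from_uniform_start(self):
        pixels, shares, design, _ = make_dataset(J=25, K=2, seed=5, noise=("dirichlet", 80.0))
        model = fl.AggFracLogit(shares, pixels, design)
        res = model.fit()
        assert res.llf >= model.loglike(np.zeros_like(res.params))

    def test_intercept_only_reproduces_pooled_logit(self):
        # all pixels identical within and across units: H_j = sigmoid(b0),
        # and the maximiser is the logit of the unweighted unit mean share
        pixels = make_pixels(n=12, units=np.repeat(["a", "b", "c", "d"], 3))
        rng = np.random.default_rng(0)
        y2 = rng.uniform(0.2, 0.8, size=4)
        shares = fl.AggregateShares(
            pd.DataFrame({"other": 1 - y2, "crop": y2}, index=["a", "b", "c", "d"])
        )
        design = fl.DesignSpec(terms=[], intercept=True)
        res = fl.AggFracLogit(shares, pixels, design).fit(cov_type="none")
        assert res.params[0] == pytest.approx(float(logit(y2.mean())), abs=1e-6)

    def test_collinear_design_flagged_by_sandwich(self):
        pixels = make_pixels(n=12, units=np.repeat(["a", "b", "c", "d"], 3),
                             covs={"const1": 1.0})
        y2 = np.array([0.3, 0.4, 0.5, 0.6])
        shares = fl.AggregateShares(
            pd.DataFrame({"other": 1 - y2, "crop": y2}, index=["a", "b", "c", "d"])
        )
        design = fl.DesignSpec(terms=[fl.linear("const1")], intercept=True)
        model = fl.AggFracLogit(shares, pixels, design)
        with pytest.raises(fl.SingularityError, match="collinear"):
            model.fit(cov_type="sandwich")

    def test_divergence_guard_raises_separation_error(self):
        # the likelihood refuses evaluation once |beta| passes the bound, so
        # an optimiser wandering off (as under quasi-complete separation)
        # fails loudly instead of returning garbage
        pixels, shares, design, _ = make_dataset(J=10, K=2, seed=14)
        model = fl.AggFracLogit(shares, pixels, design)
        start = np.zeros(model.M)
        start[0] = 2000.0
        with pytest.raises(fl.SeparationError):
            model.fit(start_params=start, cov_type="none")

    def test_nonconvergence_warns_and_flags(self):
        pixels, shares, design, _ = make_dataset(J=40, K=2, seed=6, noise=("dirichlet", 50.0))
        model = fl.AggFracLogit(shares, pixels, design)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = model.fit(max_iter=1, cov_type="none")
        assert not res.converged

    def test_numeric_gradient_refit_agrees(self):
        # independent re-optimisation with finite-difference gradients
        pixels, shares, design, _ = make_dataset(J=40, K=2, seed=12, noise=("dirichlet", 200.0))
        model = fl.AggFracLogit(shares, pixels, design)
        res = model.fit(cov_type="none")
        num = optimize.minimize(
            lambda p: -model.loglike(p), np.zeros_like(res.params),
            method="BFGS", options={"gtol": 1e-8},
        )
        scale = np.abs(res.params).max()
        assert np.abs(num.x - res.params).max() / scale < 1e-6

    def test_equivariance_under_covariate_rescaling(self):
        pixels, shares, design, _ = make_dataset(J=30, K=2, seed=8, noise=("dirichlet", 100.0))
        model = fl.AggFracLogit(shares, pixels, design)
        res = model.fit(cov_type="none")
        scaled_frame = pixels.frame.copy()
        scaled_frame["x1"] = scaled_frame["x1"] * 10.0
        model2 = fl.AggFracLogit(shares, fl.PixelTable(scaled_frame), design)
        res2 = model2.fit(cov_type="none")
        idx = list(model.W_frame.columns).index("x1")
        expect = res.params.copy()
        expect[idx] /= 10.0
        assert np.abs(res2.params - expect).max() < 1e-6
        assert np.abs(model2.fitted_H(res2.params) - model.fitted_H(res.params)).max() < 1e-8

    def test_excluded_pixels_do_not_enter(self):
        pixels, shares, design, beta = make_dataset(J=40, K=2, seed=13, exclusion_rate=0.2)
        # shares were generated from non-excluded pixels only, so the fit
        # (which drops them too) recovers beta
        res = fl.AggFracLogit(shares, pixels, design).fit(cov_type="none")
        assert np.abs(res.params - beta).max() < 1e-3

    def test_units_without_pixels_rejected(self):
        pixels, shares, design, _ = make_dataset(J=10, K=2, seed=1)
        extra = shares.frame.copy()
        extra.loc["ghost"] = extra.iloc[0]
        with pytest.raises(fl.DataError, match="ghost"):
            fl.AggFracLogit(fl.AggregateShares(extra), pixels, design)


class TestSandwich:
    def test_symmetric_psd(self, small_fit):
        model, res, _ = small_fit
        V = res.cov_params()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-10

    def test_se_and_tvalues_consistent(self, small_fit):
        _, res, _ = small_fit
        assert np.allclose(res.bse, np.sqrt(np.diag(res.cov_params())))
        assert np.allclose(res.tvalues * res.bse, res.params, equal_nan=True)

    def test_wald_coverage_on_correct_model(self):
        # 3-sigma intervals on Dirichlet-noise replicates should cover
        # essentially always; 95% intervals most of the time
        pixels, _, design, beta = make_dataset(J=100, K=2, seed=20)
        hits95 = total = 0
        for rep in range(30):
            shares = fl.simulate_shares(pixels, design, beta,
                                        noise=("dirichlet", 300.0), seed=rep)
            res = fl.AggFracLogit(shares, pixels, design).fit()
            z = np.abs(res.params - beta) / res.bse
            hits95 += int((z < 1.96).sum())
            total += z.size
        assert 0.85 <= hits95 / total <= 1.0


@pytest.fixture(scope="module")
def fitted():
    pixels, shares, design, _ = make_dataset(J=40, K=2, seed=30,
                                             noise=("dirichlet", 300.0))
    model = fl.AggFracLogit(shares, pixels, design)
    return model, model.fit(cov_type="none")


class TestBootstrap:
    def test_deterministic_under_seed(self, fitted):
        model, res = fitted
        with pytest.warns(RuntimeWarning, match="small"):
            V1 = fl.block_bootstrap_cov(model, res.params, n_boot=30, seed=7)
            V2 = fl.block_bootstrap_cov(model, res.params, n_boot=30, seed=7)
        assert np.array_equal(V1, V2)

    def test_single_replicate_rejected(self, fitted):
        model, res = fitted
        with pytest.raises(fl.EstimationError, match="replicates"):
            fl.block_bootstrap_cov(model, res.params, n_boot=1)

    def test_matches_sandwich_order_of_magnitude(self, fitted):
        model, res = fitted
        V_sw = fl.sandwich_cov(model, res.params)
        with pytest.warns(RuntimeWarning, match="small"):
            V_bs = fl.block_bootstrap_cov(model, res.params, n_boot=40, seed=3)
        ratio = np.sqrt(np.diag(V_bs)) / np.sqrt(np.diag(V_sw))
        assert np.all(ratio > 0.4) and np.all(ratio < 2.5)


class TestConsistency:
    def test_estimation_error_shrinks_with_more_units(self):
        # root-mean-squared estimation error over seeded Dirichlet replicates
        # falls monotonically as the number of units grows
        errs = []
        for J in (25, 100, 400):
            pixels, _, design, beta = make_dataset(J=J, K=2, seed=40 + J,
                                                   pixels_per_unit=(3, 6), n_covs=1)
            sq = 0.0
            reps = 40
            for rep in range(reps):
                shares = fl.simulate_shares(pixels, design, beta,
                                            noise=("dirichlet", 100.0), seed=rep)
                res = fl.AggFracLogit(shares, pixels, design).fit(cov_type="none")
                sq += np.sum((res.params - beta) ** 2)
            errs.append(np.sqrt(sq / reps))
        assert errs[0] > errs[1] > errs[2]


class TestReporting:
    def test_coef_table_layout(self, small_fit):
        _, res, _ = small_fit
        tab = res.coef_table()
        assert list(tab.columns) == ["crop", "term", "estimate", "se", "t"]
        assert len(tab) == (res.model.K - 1) * res.model.M

    def test_summary_mentions_convergence_and_units(self, small_fit):
        _, res, _ = small_fit
        text = res.summary()
        assert "converged: True" in text
        assert f"units (J): {res.n_units:>6}" in text
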