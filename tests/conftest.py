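import numpy as np
import pandas as pd
import pytest

import fracland as fl


def make_pixels(
    n=10,
    units=None,
    lat=20.0,
    covs=None,
    areas=None,
    excluded=None,
    level2=None,
):
    """Hand-rolled tiny pixel table for unit tests."""
    units = units if units is not None else ["A"] * n
    lat = np.broadcast_to(np.asarray(lat, dtype=float), (n,))
    data = {
        "pixel_id": [f"p{i}" for i in range(n)],
        "unit_l1": units,
        "lat": lat,
        "lon": np.linspace(-100, -99, n),
        "area": areas if areas is not None else np.ones(n),
        "excluded": excluded if excluded is not None else [False] * n,
    }
    if level2 is not None:
        data["unit_l2"] = level2
    for name, vals in (covs or {}).items():
        data[name] = np.broadcast_to(np.asarray(vals, dtype=float), (n,))
    return fl.PixelTable(pd.DataFrame(data))


def make_dataset(J=40, K=2, seed=0, noise="none", pixels_per_unit=(3, 8), beta=None,
                 n_covs=2, exclusion_rate=0.0):
    """Generic standardized-covariate dataset with known coefficients."""
    covs = {f"x{i}": fl.CovariateSpec(0.0, 1.0) for i in range(1, n_covs + 1)}
    covs["latitude"] = fl.CovariateSpec(25.0, 12.0, -40.0, 55.0)
    design = fl.DesignSpec(terms=[fl.linear(f"x{i}") for i in range(1, n_covs + 1)])
    M = n_covs + 1
    if beta is None:
        rng = np.random.default_rng(seed + 1000)
        beta = rng.normal(0.0, 0.6, size=(K - 1) * M)
    cfg = fl.SyntheticConfig(
        J=J, pixels_per_unit=pixels_per_unit, K=K, covariates=covs,
        beta_true=np.asarray(beta, dtype=float), noise=noise,
        exclusion_rate=exclusion_rate, seed=seed,
    )
    pixels, shares, design, beta = fl.simulate_dataset(cfg, design)
    return pixels, shares, design, np.asarray(beta, dtype=float)


@pytest.fixture(scope="session")
def small_fit():
    """A converged fit on a small noiseless 3-category dataset."""
    pixels, shares, design, beta = make_dataset(J=30, K=3, seed=11)
    model = fl.AggFracLogit(shares, pixels, design)
    return model, model.fit(), beta
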