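"""Seeded synthetic landscapes and aggregate shares for testing the estimator.

The generator emulates the data structure the estimator assumes: pixels
nested in Level-1 administrative units (optionally subdivided into Level-2
districts), biophysical covariates with realistic means and spreads, pixel
areas from the spherical graticule formula, exclusion masks, and unit-level
observed shares generated from a known coefficient vector.

Covariates combine a unit-level random intercept with pixel-level noise
(variance split ``unit_corr`` : ``1 - unit_corr``), then clip to the
configured bounds — so covariates cluster spatially by unit the way real
biophysical fields cluster by state, without attempting full spatial
autocorrelation. Regional presets carry means/SDs/bounds typical of North,
Central and South American growing-season climatologies and soils.

Observed shares come from the model's own forward map: noiseless mode
returns y = H(beta_true) exactly (a zero-noise recovery target for the
fitted estimator); Dirichlet mode draws y_j ~ Dirichlet(c * H_j), which
preserves the conditional mean E[y_j] = H_j — exactly the assumption the
QMLE needs — with concentration c controlling signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataError
from .grid import AggregateShares, DesignSpec, PixelTable, build_design, linear, pixel_area
from .likelihood import ModelSpec, aggregate_shares, pixel_shares


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate: normal with clipping bounds."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.sd < 0:
            raise DataError("covariate sd must be non-negative")
        if self.lower >= self.upper:
            raise DataError(f"infeasible bounds [{self.lower}, {self.upper}]")


#: Regional presets: growing-season temperature (C), precipitation (m/yr),
#: elevation (km), soil pH hinge deviations from 6.5, soil carbon (kg/m^2),
#: slope (unitless), and the unit-latitude band (degrees).
PRESETS: dict[str, dict[str, CovariateSpec]] = {
    "north_america": {
        "temperature": CovariateSpec(16.660, 6.087, 1.833, 28.667),
        "precipitation": CovariateSpec(0.813, 0.361, 0.068, 3.258),
        "elevation": CovariateSpec(0.569, 0.601, -0.227, 3.704),
        "ph_below": CovariateSpec(0.466, 0.617, 0.000, 2.300),
        "ph_above": CovariateSpec(0.342, 0.466, 0.000, 1.665),
        "soil_carbon": CovariateSpec(6.351, 2.895, 1.608, 22.356),
        "slope": CovariateSpec(0.056, 0.065, 0.003, 0.375),
        "latitude": CovariateSpec(37.326, 9.612, 14.625, 56.792),
    },
    "central_america": {
        "temperature": CovariateSpec(23.474, 2.514, 15.833, 27.500),
        "precipitation": CovariateSpec(2.256, 0.739, 1.142, 4.678),
        "elevation": CovariateSpec(0.674, 0.609, -0.197, 3.300),
        "ph_below": CovariateSpec(0.611, 0.422, 0.000, 1.400),
        "ph_above": CovariateSpec(0.030, 0.101, 0.000, 0.640),
        "soil_carbon": CovariateSpec(6.900, 1.740, 3.984, 12.724),
        "slope": CovariateSpec(0.134, 0.088, 0.003, 0.375),
        "latitude": CovariateSpec(13.263, 2.156, 7.292, 16.042),
    },
    "south_america": {
        "temperature": CovariateSpec(22.493, 3.967, -0.167, 28.500),
        "precipitation": CovariateSpec(1.181, 0.494, 0.000, 5.667),
        "elevation": CovariateSpec(0.564, 0.709, -0.132, 4.783),
        "ph_below": CovariateSpec(0.690, 0.609, 0.000, 1.869),
        "ph_above": CovariateSpec(0.194, 0.392, 0.000, 1.563),
        "soil_carbon": CovariateSpec(5.147, 1.646, 1.325, 13.183),
        "slope": CovariateSpec(0.054, 0.065, 0.003, 0.375),
        "latitude": CovariateSpec(-18.537, 11.908, -40.958, 11.458),
    },
}


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults describe a mid-sized continental sample: 200 Level-1 units of
    4-12 pixels each, two categories (base + one crop), covariates from the
    North American preset, half the covariate variance at the unit level,
    and no exclusions.
    """

    J: int = 200
    pixels_per_unit: tuple[int, int] = (4, 12)
    K: int = 2
    covariates: dict[str, CovariateSpec] = field(
        default_factory=lambda: dict(PRESETS["north_america"])
    )
    beta_true: np.ndarray | None = None
    noise: str | tuple[str, float] = "none"  # "none" | ("dirichlet", concentration)
    exclusion_rate: float = 0.0
    unit_corr: float = 0.5
    n_level2: int = 3
    resolution: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.J < 2:
            raise DataError("need J >= 2 units")
        lo, hi = self.pixels_per_unit
        if lo < 1 or hi < lo:
            raise DataError("pixels_per_unit must be a range with lower bound >= 1")
        if not 0.0 <= self.exclusion_rate < 1.0:
            raise DataError("exclusion_rate must be in [0, 1)")
        if not 0.0 <= self.unit_corr <= 1.0:
            raise DataError("unit_corr must lie in [0, 1]")


def preset_config(region: str, **overrides) -> SyntheticConfig:
    """Config whose covariates mimic one of the regional presets."""
    if region not in PRESETS:
        raise DataError(f"unknown preset {region!r}; choose from {sorted(PRESETS)}")
    cfg = SyntheticConfig(covariates=dict(PRESETS[region]))
    return replace(cfg, **overrides) if overrides else cfg


def simulate_landscape(config: SyntheticConfig) -> PixelTable:
    """Draw a pixel table per the config; reproducible under its seed.

    Latitudes are assigned per unit (pixels jitter around the unit centre by
    a few cell heights); other covariates get a unit random intercept plus
    pixel noise, clipped to bounds; areas follow the spherical cell-area
    formula at the configured resolution; exclusion flags are Bernoulli.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pixels_per_unit
    n_per_unit = rng.integers(lo, hi + 1, size=config.J)
    n = int(n_per_unit.sum())
    unit_codes = np.repeat(np.arange(config.J), n_per_unit)
    unit_ids = np.array([f"u{j:04d}" for j in range(config.J)])

    lat_spec = config.covariates.get("latitude", CovariateSpec(20.0, 15.0, -55.0, 60.0))
    unit_lat = np.clip(
        rng.normal(lat_spec.mean, lat_spec.sd, size=config.J), lat_spec.lower, lat_spec.upper
    )
    cell = config.resolution / 60.0
    lat = unit_lat[unit_codes] + rng.integers(-3, 4, size=n) * cell
    lat = np.clip(lat, -90.0 + cell, 90.0 - cell)
    lon = rng.uniform(-170.0, -30.0, size=n)

    data: dict[str, np.ndarray] = {
        "pixel_id": np.array([f"p{i:06d}" for i in range(n)]),
        "unit_l1": unit_ids[unit_codes],
        "unit_l2": np.array(
            [
                f"{unit_ids[j]}-d{d}"
                for j, d in zip(unit_codes, rng.integers(0, config.n_level2, size=n))
            ]
        ),
        "lat": lat,
        "lon": lon,
        "area": pixel_area(lat, config.resolution),
        "excluded": rng.random(n) < config.exclusion_rate,
    }
    rho = config.unit_corr
    for name, spec in config.covariates.items():
        if name == "latitude":
            data[name] = lat
            continue
        u = rng.normal(0.0, spec.sd * np.sqrt(rho), size=config.J)
        e = rng.normal(0.0, spec.sd * np.sqrt(1.0 - rho), size=n)
        data[name] = np.clip(spec.mean + u[unit_codes] + e, spec.lower, spec.upper)
    return PixelTable(pd.DataFrame(data))


def simulate_shares(
    pixels: PixelTable,
    design: DesignSpec,
    beta_true: np.ndarray,
    noise: str | tuple[str, float] = "none",
    seed: int | None = None,
    K: int | None = None,
    crops: list[str] | None = None,
) -> AggregateShares:
    """Unit shares from the forward model y_j ~ around H_j(beta_true).

    Noiseless mode returns y = H exactly. Dirichlet mode draws
    y_j ~ Dirichlet(c * H_j), mean-preserving with concentration c > 0.
    Excluded pixels do not enter the aggregation (matching estimation).
    """
    active = pixels.subset(~pixels.frame["excluded"].astype(bool).to_numpy())
    W = build_design(active, design).to_numpy(dtype=float)
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    M = W.shape[1]
    if K is None:
        if beta_true.size % M:
            raise DataError(f"beta length {beta_true.size} not a multiple of M={M}")
        K = beta_true.size // M + 1
    model = ModelSpec(K=K, M=M, beta=beta_true)
    G = pixel_shares(W, model)
    units = pd.Index(pd.unique(active.frame["unit_l1"]))
    codes = units.get_indexer(active.frame["unit_l1"])
    H = aggregate_shares(G, active.frame["area"].to_numpy(dtype=float), codes, len(units))

    if noise == "none":
        y = H
    elif isinstance(noise, tuple) and noise[0] == "dirichlet":
        conc = float(noise[1])
        if conc <= 0:
            raise DataError("Dirichlet concentration must be positive")
        rng = np.random.default_rng(seed)
        y = np.vstack([rng.dirichlet(conc * h) for h in H])
        # guard exact zeros from extreme draws; renormalise
        y = np.clip(y, 1e-12, None)
        y = y / y.sum(axis=1, keepdims=True)
    else:
        raise DataError(f"unknown noise model {noise!r}")
    names = crops if crops is not None else ["other"] + [f"crop{k}" for k in range(1, K)]
    return AggregateShares(pd.DataFrame(y, index=units, columns=names))


def default_design(covariate_names: list[str]) -> DesignSpec:
    """Intercept plus one linear term per named covariate."""
    return DesignSpec(terms=[linear(v) for v in covariate_names], intercept=True)


def simulate_dataset(
    config: SyntheticConfig, design: DesignSpec | None = None
) -> tuple[PixelTable, AggregateShares, DesignSpec, np.ndarray]:
    """Landscape + shares in one call; returns (pixels, shares, design, beta_true).

    When ``design`` is omitted, an intercept + linear design over all
    configured covariates is used. When ``config.beta_true`` is omitted,
    coefficients are drawn once from N(0, 0.5^2) under the config seed.
    """
    pixels = simulate_landscape(config)
    if design is None:
        design = default_design([v for v in config.covariates if v != "latitude"])
    labels = design.column_labels(pixels)
    M = len(labels)
    beta = config.beta_true
    if beta is None:
        rng = np.random.default_rng(config.seed + 1)
        beta = rng.normal(0.0, 0.5, size=(config.K - 1) * M)
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != (config.K - 1) * M:
        raise DataError(
            f"beta_true must have length (K-1)*M = {(config.K - 1) * M}, got {beta.size}"
        )
    shares = simulate_shares(
        pixels, design, beta, noise=config.noise, seed=config.seed + 2, K=config.K
    )
    return pixels, shares, design, beta
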