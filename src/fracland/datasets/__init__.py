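"""Small bundled reference tables.

``americas_maize_coefficients.csv`` holds published QMLE coefficient
estimates (with standard errors) from a continental-scale single-crop maize
application of the aggregated fractional logit over the Americas. The
design is quadratic in temperature, precipitation and latitude, includes a
temperature-precipitation interaction, asymmetric soil-pH hinges around
6.5, and country indicators; the remaining biophysical variables enter
linearly. Useful as a realistic worked example for odds-ratio and
marginal-effect calculations.
"""

from importlib import resources

import pandas as pd

#: terms of the published maize design that enter through a single linear
#: term, so their odds ratio is exactly exp(coefficient)
LINEAR_ONLY_TERMS = [
    "elevation",
    "max(6.5-ph,0)",
    "max(ph-6.5,0)",
    "soil_carbon",
    "slope",
]


def load_americas_maize_coefficients() -> pd.DataFrame:
    """Published single-crop maize coefficient table (term, coefficient, se)."""
    with resources.files(__package__).joinpath("americas_maize_coefficients.csv").open() as fh:
        return pd.read_csv(fh)
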