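"""Synthetic cohort generators for the statistical modules.

The clinical cohort behind the published correlations is not public, so
parameter-recovery studies run on synthetic cohorts instead: feature
tables with a planted latent-class structure (to exercise the factor
analysis) and (BGA, MD) pairs drawn from the published linear conversion
plus Gaussian perimetric noise (to exercise the regression refit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sign pattern of the three latent classes, mirroring how clinical ONH
#: features group: class 1 = cup shape (rim features load negatively),
#: class 2 = RNFL thickness, class 3 = disk size.
TABLE3_BLOCKS: dict[str, dict[str, float]] = {
    "class1": {"w16": 1, "w13": 1, "w6": 1, "w5": 1, "w8": 1,
               "w19": -1, "w7": -1, "w4": -1},
    "class2": {"w22": 1, "w20": 1, "w24": 1, "w25": 1, "w23": 1},
    "class3": {"w10": 1, "w2": 1, "w12": 1, "w11": 1},
}


def make_latent_cohort(n: int = 200, n_factors: int = 3,
                       features_per_factor: int = 3, noise_sd: float = 0.1,
                       seed: int = 0) -> pd.DataFrame:
    """Features that are noisy copies of ``n_factors`` independent latents.

    Each block of ``features_per_factor`` columns equals its factor plus
    N(0, noise_sd) noise, giving near-collinear groups a factor model
    should separate cleanly.
    """
    if n < 3 or n_factors < 1 or features_per_factor < 1:
        raise ValidationError("cohort dimensions must be positive (n >= 3)")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n, n_factors))
    data = {}
    for f in range(n_factors):
        for j in range(features_per_factor):
            data[f"g{f + 1}_x{j + 1}"] = (factors[:, f]
                                          + rng.normal(0.0, noise_sd, n))
    return pd.DataFrame(data)


def make_table3_cohort(n: int = 200, noise_sd: float = 0.3,
                       seed: int = 0, md_column: bool = True) -> pd.DataFrame:
    """Feature table with the three-block sign structure of clinical ONH data.

    Features are signed noisy copies of three latent factors following
    :data:`TABLE3_BLOCKS`. When ``md_column`` is set, a w29 (MD) column is
    generated as a linear function of the cup-shape factor plus noise, so
    class 1 dominates the structure-function correlation.
    """
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n, len(TABLE3_BLOCKS)))
    data = {}
    for k, (_, block) in enumerate(TABLE3_BLOCKS.items()):
        for name, sign in block.items():
            data[name] = sign * factors[:, k] + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(data)
    if md_column:
        df["w29"] = 8.0 * factors[:, 0] + 6.0 + rng.normal(0.0, 2.0, n)
    return df


def make_bga_md_cohort(n: int = 110, slope: float = 24.0, intercept: float = -9.34,
                       noise_sd: float = 4.1, seed: int = 0) -> pd.DataFrame:
    """(BGA, MD) pairs: BGA ~ U(0, 1), MD = slope*BGA + intercept + N(0, sd).

    The default noise s.d. of 4.1 dB makes the population Pearson
    correlation about 0.86 for uniform BGA (signal s.d. 24/sqrt(12)).
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    rng = np.random.default_rng(seed)
    bga = rng.uniform(0.0, 1.0, n)
    md = slope * bga + intercept + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"w_BGA": bga, "w29": md})
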