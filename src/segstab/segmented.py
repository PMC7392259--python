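"""Frequentist least-squares fit of the bi-segmented adaptability model.

Per genotype, environment-mean yields are regressed on the environmental
index with a fixed change point at index zero:

    y_j = b0 + b1 * I_j + b2 * T(I_j) + e_j

so b1 is the response slope in unfavorable environments (I_j <= 0) and
b1 + b2 the slope in favorable ones.  The fit doubles as the source of
informative prior hyperparameters for the Bayesian analysis: prior means are
the point estimates, prior variances are (strength x squared standard error),
and the precision receives a Gamma prior whose mean is the reciprocal of the
residual variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bayes import PriorSpec
from .design import build_design, check_rank
from .errors import DegeneratePriorError, InputError
from .trial_data import EnvironmentIndex

__all__ = ["SegmentedFitResult", "fit_genotype_ols", "elicit_hyperparameters",
           "fits_to_frame"]


@dataclass(frozen=True)
class SegmentedFitResult:
    genotype: str
    b0: float
    b1: float
    b2: float
    se0: float
    se1: float
    se2: float
    sigma2_hat: float
    r_squared: float
    n_env: int


def fit_genotype_ols(
    responses: Mapping[str, float] | pd.Series,
    index: EnvironmentIndex,
    genotype: str = "",
) -> SegmentedFitResult:
    """Least-squares fit of the segmented model for one genotype.

    ``responses`` maps environment -> mean yield; every environment must have
    an index value.  Requires >= 4 environments and both regimes represented.
    """
    responses = pd.Series(responses, dtype=float).sort_index()
    n = len(responses)
    if n < 4:
        raise InputError(f"need >= 4 environments to fit 3 coefficients (got {n})")
    X = build_design(index, responses.index)
    check_rank(X)
    y = responses.to_numpy(float)
    model = sm.OLS(y, X).fit()
    b0, b1, b2 = model.params
    se0, se1, se2 = model.bse
    sse = float(model.ssr)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
    return SegmentedFitResult(
        genotype=genotype or getattr(responses, "name", "") or "",
        b0=float(b0), b1=float(b1), b2=float(b2),
        se0=float(se0), se1=float(se1), se2=float(se2),
        sigma2_hat=sse / (n - 3),
        r_squared=min(max(r2, 0.0), 1.0),
        n_env=n,
    )


def elicit_hyperparameters(
    fit: SegmentedFitResult,
    strength: float = 1.0,
    prior_shape: float = 1.0,
    sigma2_floor: float = 0.0,
) -> PriorSpec:
    """Informative prior hyperparameters from a frequentist fit.

    Coefficient priors are Normal(point estimate, strength x se^2); the
    precision prior is Gamma(shape=prior_shape, rate=prior_shape x sigma2_hat)
    so its mean equals 1/sigma2_hat.  ``strength`` > 1 weakens the priors,
    < 1 sharpens them.  A zero residual variance (noiseless fit) cannot
    define a proper precision prior; pass ``sigma2_floor`` > 0 to substitute
    a floor value in that case.
    """
    if strength <= 0:
        raise InputError("strength must be positive")
    if prior_shape <= 0:
        raise InputError("prior_shape must be positive")
    sigma2 = fit.sigma2_hat
    if sigma2 <= 0:
        if sigma2_floor > 0:
            sigma2 = sigma2_floor
        else:
            raise DegeneratePriorError(
                "sigma2_hat is 0 (noiseless fit); supply sigma2_floor > 0 to "
                "elicit a proper precision prior"
            )
    return PriorSpec(
        mu_beta0=fit.b0, mu_beta1=fit.b1, mu_beta2=fit.b2,
        var_beta0=strength * fit.se0**2,
        var_beta1=strength * fit.se1**2,
        var_beta2=strength * fit.se2**2,
        alpha=prior_shape,
        beta=prior_shape * sigma2,
    )


def fits_to_frame(fits: list[SegmentedFitResult]) -> pd.DataFrame:
    """Tabulate fits (one row per genotype) for CSV export."""
    return pd.DataFrame(
        [
            {
                "genotype": f.genotype,
                "b0": f.b0, "b1": f.b1, "b2": f.b2,
                "se0": f.se0, "se1": f.se1, "se2": f.se2,
                "sigma2_hat": f.sigma2_hat,
                "r_squared": f.r_squared,
                "n_env": f.n_env,
            }
            for f in fits
        ]
    )
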