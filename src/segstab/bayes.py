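"""Bayesian inference for the per-genotype bi-segmented regression model.

Model, per genotype, on environment-mean yields:

    y_j | beta, tau ~ Normal(beta0 + beta1*I_j + beta2*T(I_j), 1/tau)

with independent Normal priors on the three coefficients and a Gamma
(shape alpha, RATE beta) prior on the precision tau = 1/sigma2.  All four
full conditionals are conjugate (Normal for each coefficient, Gamma for the
precision), so posterior draws come from an exact Gibbs sampler with no
tuning parameters.

Derived quantities:

* ``sigma2`` = 1/tau, the genotype's deviation variance around its segmented
  response (on the scale of block-averaged means);
* ``beta12`` = beta1 + beta2, the response slope in favorable environments;
* the stability parameter ``sigma2_d`` = sigma2 - MSR/r, which removes the
  share of sigma2 attributable to plot-level experimental error (MSR from
  the joint ANOVA, r blocks).  It may come out negative — a method-of-moments
  subtraction — and is reported untruncated so that credible-interval tests
  against zero stay unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NumericalError
from .design import build_design, check_rank
from .trial_data import EnvironmentIndex

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSample",
    "PosteriorSummary",
    "minimally_informative_priors",
    "log_likelihood",
    "log_posterior",
    "gibbs_sample",
    "stability_parameter",
    "summarize_posterior",
]

BASE_PARAMS = ("beta0", "beta1", "beta2", "tau", "sigma2", "beta12")


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors on the coefficients and a Gamma(shape, rate) prior on
    the precision tau (prior mean of tau is alpha/beta)."""

    mu_beta0: float
    mu_beta1: float
    mu_beta2: float
    var_beta0: float
    var_beta1: float
    var_beta2: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("var_beta0", "var_beta1", "var_beta2", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")

    @property
    def coef_means(self) -> np.ndarray:
        return np.array([self.mu_beta0, self.mu_beta1, self.mu_beta2])

    @property
    def coef_vars(self) -> np.ndarray:
        return np.array([self.var_beta0, self.var_beta1, self.var_beta2])


def minimally_informative_priors(coef_var: float = 100000.0) -> PriorSpec:
    """Vague priors: Normal(0, coef_var) coefficients, Gamma(0.001, 0.001)
    precision.

    The default coefficient variance of 1e5 follows the convention of the
    published analyses this model family comes from.  Note that 1e5 (SD
    ~316) is only vague relative to slope-sized coefficients: for intercepts
    measured in thousands of kg/ha it shrinks hard toward zero and can drive
    the sampler into a large-variance degenerate mode.  Pass a larger
    ``coef_var`` (e.g. 1e10) when the response is not centered.
    """
    return PriorSpec(
        mu_beta0=0.0, mu_beta1=0.0, mu_beta2=0.0,
        var_beta0=coef_var, var_beta1=coef_var, var_beta2=coef_var,
        alpha=0.001, beta=0.001,
    )


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 5
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise InputError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise InputError("thin must be >= 1")
        if self.chains < 1:
            raise InputError("chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class PosteriorSample:
    """Retained Gibbs draws for one genotype.

    ``draws`` columns: beta0, beta1, beta2, tau, sigma2, beta12, and
    sigma2_d once :func:`attach_stability` has been applied.
    """

    genotype: str
    draws: pd.DataFrame
    config: MCMCConfig
    prior: PriorSpec
    msr: float | None = None
    r: int | None = None

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _prepare(responses, index: EnvironmentIndex):
    responses = pd.Series(responses, dtype=float).sort_index()
    X = build_design(index, responses.index)
    y = responses.to_numpy(float)
    return y, X


def log_likelihood(
    beta0: float,
    beta1: float,
    beta2: float,
    sigma2: float,
    responses: Mapping[str, float] | pd.Series,
    index: EnvironmentIndex,
) -> float:
    """Gaussian log-likelihood of the segmented model over environments."""
    if sigma2 <= 0:
        raise InputError("sigma2 must be positive")
    y, X = _prepare(responses, index)
    mu = X @ np.array([beta0, beta1, beta2])
    a = len(y)
    sse = float(((y - mu) ** 2).sum())
    return -0.5 * a * math.log(2.0 * math.pi * sigma2) - 0.5 * sse / sigma2


def log_posterior(
    params,
    prior: PriorSpec,
    responses: Mapping[str, float] | pd.Series,
    index: EnvironmentIndex,
) -> float:
    """Unnormalized log posterior at params = (beta0, beta1, beta2, tau)."""
    beta0, beta1, beta2, tau = params
    if tau <= 0:
        raise InputError("tau must be positive")
    ll = log_likelihood(beta0, beta1, beta2, 1.0 / tau, responses, index)
    lp = (
        stats.norm.logpdf(beta0, prior.mu_beta0, math.sqrt(prior.var_beta0))
        + stats.norm.logpdf(beta1, prior.mu_beta1, math.sqrt(prior.var_beta1))
        + stats.norm.logpdf(beta2, prior.mu_beta2, math.sqrt(prior.var_beta2))
        + stats.gamma.logpdf(tau, prior.alpha, scale=1.0 / prior.beta)
    )
    return ll + lp


def gibbs_sample(
    responses: Mapping[str, float] | pd.Series,
    index: EnvironmentIndex,
    prior: PriorSpec,
    config: MCMCConfig,
    genotype: str = "",
) -> PosteriorSample:
    """Exact-conditional Gibbs sampler for one genotype.

    Each coefficient is updated from its Normal full conditional (precision-
    weighted combination of prior and data given the other coefficients and
    tau); tau from Gamma(alpha + a/2, beta + SSE(beta)/2).  Draws are
    recorded after burn-in, every ``thin``-th iteration.  Bit-reproducible
    given (seed, config, prior, data).
    """
    y, X = _prepare(responses, index)
    check_rank(X)
    a = len(y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    mu_prior = prior.coef_means
    prec_prior = 1.0 / prior.coef_vars

    rng = np.random.default_rng(config.seed)
    # initialize at the least-squares solution; tau at its implied residual
    # precision (guarded for noiseless data)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    s2 = float(resid @ resid) / max(a - 3, 1)
    tau = 1.0 / max(s2, 1e-12)

    n_ret = config.n_retained
    out = np.empty((n_ret, 4))
    kept = 0
    for it in range(config.iterations):
        for k in range(3):
            prec = tau * XtX[k, k] + prec_prior[k]
            partial = Xty[k] - XtX[k] @ beta + XtX[k, k] * beta[k]
            mean = (tau * partial + prec_prior[k] * mu_prior[k]) / prec
            beta[k] = mean + rng.standard_normal() / math.sqrt(prec)
        sse = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
        sse = max(sse, 0.0)
        tau = rng.gamma(prior.alpha + 0.5 * a, 1.0 / (prior.beta + 0.5 * sse))
        if not np.isfinite(tau) or tau <= 0 or not np.all(np.isfinite(beta)):
            raise NumericalError(f"non-finite draw at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if kept < n_ret:
                out[kept] = (beta[0], beta[1], beta[2], tau)
                kept += 1
    draws = pd.DataFrame(out[:kept], columns=["beta0", "beta1", "beta2", "tau"])
    draws["sigma2"] = 1.0 / draws["tau"]
    draws["beta12"] = draws["beta1"] + draws["beta2"]
    return PosteriorSample(
        genotype=genotype, draws=draws, config=config, prior=prior
    )


def stability_parameter(sigma2_draws, msr: float, r: int) -> np.ndarray:
    """Stability parameter draws: sigma2_d = sigma2 - MSR/r, elementwise.

    Negative values (sampling noise in the method-of-moments subtraction)
    are preserved.
    """
    if r < 1:
        raise InputError("r (number of repetitions) must be >= 1")
    if msr < 0:
        raise InputError("MSR must be non-negative")
    return np.asarray(sigma2_draws, dtype=float) - msr / r


def attach_stability(sample: PosteriorSample, msr: float, r: int) -> PosteriorSample:
    """Return a copy of ``sample`` with sigma2_d draws added."""
    draws = sample.draws.copy()
    draws["sigma2_d"] = stability_parameter(draws["sigma2"].to_numpy(), msr, r)
    return PosteriorSample(
        genotype=sample.genotype, draws=draws, config=sample.config,
        prior=sample.prior, msr=msr, r=r,
    )


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean, SD and equal-tailed 95% interval per parameter, plus
    the coefficient of determination (percent) at posterior-mean coefficients."""

    genotype: str
    table: pd.DataFrame  # index: parameter; columns: mean, sd, lower, upper
    r_squared: float
    ci_level: float = 0.95
    negative_stability_flag: bool = field(default=False)

    def interval(self, param: str) -> tuple[float, float]:
        row = self.table.loc[param]
        return float(row["lower"]), float(row["upper"])

    def mean(self, param: str) -> float:
        return float(self.table.loc[param, "mean"])


def summarize_posterior(
    sample: PosteriorSample,
    responses: Mapping[str, float] | pd.Series,
    index: EnvironmentIndex,
    ci_level: float = 0.95,
) -> PosteriorSummary:
    """Summaries of the retained draws for one genotype.

    The interval is equal-tailed at ``ci_level``; R^2 is evaluated at the
    posterior-mean coefficients and reported as a percentage.
    """
    if sample.n_draws < 100:
        raise InputError(
            f"need >= 100 retained draws to summarize (got {sample.n_draws})"
        )
    if not (0 < ci_level < 1):
        raise InputError("ci_level must be in (0, 1)")
    lo_q, hi_q = 50 * (1 - ci_level), 50 * (1 + ci_level)
    rows = {}
    for col in sample.draws.columns:
        if col == "tau":
            continue
        vals = sample.draws[col].to_numpy()
        lo, hi = np.percentile(vals, [lo_q, hi_q])
        rows[col] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "lower": float(lo),
            "upper": float(hi),
        }
    table = pd.DataFrame(rows).T

    y, X = _prepare(responses, index)
    bhat = np.array([rows["beta0"]["mean"], rows["beta1"]["mean"], rows["beta2"]["mean"]])
    sse = float(((y - X @ bhat) ** 2).sum())
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 100.0 * (1.0 - sse / sstot) if sstot > 0 else 100.0
    neg_flag = "sigma2_d" in rows and rows["sigma2_d"]["mean"] < 0
    return PosteriorSummary(
        genotype=sample.genotype, table=table, r_squared=r2,
        ci_level=ci_level, negative_stability_flag=bool(neg_flag),
    )


def summaries_to_frame(summaries: list[PosteriorSummary]) -> pd.DataFrame:
    """One row per genotype with LI/mean/LS triples per parameter plus R^2."""
    records = []
    for s in summaries:
        rec: dict = {"genotype": s.genotype}
        for param, label in (
            ("beta0", "b0"), ("beta1", "b1"), ("beta12", "b1b2"),
            ("sigma2", "s2"), ("sigma2_d", "s2d"),
        ):
            if param not in s.table.index:
                continue
            row = s.table.loc[param]
            rec[f"{label}_lower"] = row["lower"]
            rec[f"{label}_mean"] = row["mean"]
            rec[f"{label}_upper"] = row["upper"]
        rec["r_squared"] = s.r_squared
        records.append(rec)
    frame = pd.DataFrame(records)
    return frame.sort_values("b0_mean", ascending=False).reset_index(drop=True)
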