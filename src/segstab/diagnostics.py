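"""MCMC convergence diagnostics and DIC model comparison.

Geweke's diagnostic compares the mean of an early window of the chain with
the mean of a late window, standardized by spectral (autocorrelation-robust)
variance estimates; under convergence the z score is approximately standard
normal.  The Raftery-Lewis diagnostic works on the indicator chain
{draw <= q-quantile} approximated as a two-state Markov chain, and reports
the run length needed to estimate the q-quantile to within +/- r with
probability s, together with the dependence factor I = (burn-in + N) / N_min
(I near 1 means the chain mixes like iid sampling).

Model comparison uses the Deviance Information Criterion,

    DIC = Dbar + pD = D(posterior means) + 2 pD,

where Dbar is the posterior mean deviance and pD = Dbar - D(posterior means)
is the effective number of parameters.  Lower DIC is better; the per-genotype
comparison DIC(vague) - DIC(informative) is positive when the informative
prior improves the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import PosteriorSample, _prepare, log_likelihood
from .errors import DegenerateChainError, InputError, NumericalError
from .trial_data import EnvironmentIndex

__all__ = [
    "RafteryLewisResult",
    "DiagnosticsReport",
    "DicResult",
    "geweke_diagnostic",
    "raftery_lewis",
    "diagnose_sample",
    "compute_dic",
    "compare_priors",
]


@dataclass(frozen=True)
class RafteryLewisResult:
    n_min: int            # iid-equivalent minimum run length
    burn_in: int          # recommended burn-in M
    n_required: int       # recommended post-burn-in run length N
    thin: int             # thinning k selected by the order test
    dependence_factor: float  # (M + N) / N_min


@dataclass(frozen=True)
class DiagnosticsReport:
    """Per-parameter Geweke z scores and Raftery-Lewis results for a sample."""

    genotype: str
    table: pd.DataFrame  # index: parameter; columns geweke_z, geweke_pass,
    #                      rl_n_required, rl_dependence_factor

    @property
    def all_pass(self) -> bool:
        return bool(self.table["geweke_pass"].all())


def _spectral_variance(x: np.ndarray) -> float:
    """Autocorrelation-robust variance of the sample mean numerator.

    Bartlett-windowed autocovariance sum with window width round(sqrt(n)).
    Returns an estimate of the long-run variance (spectral density at zero).
    """
    n = len(x)
    x = x - x.mean()
    width = int(round(math.sqrt(n)))
    gamma0 = float(x @ x) / n
    s = gamma0
    for lag in range(1, min(width, n - 1) + 1):
        w = 1.0 - lag / (width + 1.0)
        s += 2.0 * w * float(x[:-lag] @ x[lag:]) / n
    return max(s, 0.0)


def geweke_diagnostic(
    chain, first: float = 0.1, last: float = 0.5
) -> float:
    """Geweke convergence z score for one chain.

    Compares the means of the first ``first`` fraction and the last ``last``
    fraction of the chain, each standardized by its spectral variance.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise InputError(f"chain too short for Geweke diagnostic (n={len(x)})")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise InputError("window fractions must be in (0,1) with first+last <= 1")
    if np.ptp(x) == 0:
        raise DegenerateChainError("constant chain: Geweke z is undefined")
    n = len(x)
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    va = _spectral_variance(a) / len(a)
    vb = _spectral_variance(b) / len(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        raise DegenerateChainError("zero spectral variance in both windows")
    return float((a.mean() - b.mean()) / denom)


def _markov_bic_prefers_first_order(z: np.ndarray, k: int) -> bool:
    """BIC comparison of first- vs second-order Markov chains for the
    indicator chain thinned by k (classical Raftery-Lewis order test)."""
    zk = z[::k]
    n = len(zk)
    if n < 3:
        return True
    # transition counts over triples
    tran = np.zeros((2, 2, 2))
    for i, j, l in zip(zk[:-2], zk[1:-1], zk[2:]):
        tran[i, j, l] += 1
    # G2 statistic for the second-order term
    g2 = 0.0
    for i in range(2):
        for j in range(2):
            for l in range(2):
                if tran[i, j, l] == 0:
                    continue
                fitted = tran[i, j, :].sum() * tran[:, j, l].sum() / tran[:, j, :].sum()
                g2 += 2.0 * tran[i, j, l] * math.log(tran[i, j, l] / fitted)
    bic = g2 - 2.0 * math.log(n - 2)
    return bic < 0


def raftery_lewis(
    chain, q: float = 0.025, r: float = 0.005, s: float = 0.95,
    eps: float = 0.001,
) -> RafteryLewisResult:
    """Raftery-Lewis run-length diagnostic for estimating the q-quantile.

    Defaults ask for the 0.025 quantile within +/- 0.005 with probability
    0.95 (the conventional credible-interval-endpoint setting).
    """
    x = np.asarray(chain, dtype=float)
    phi = stats.norm.ppf(0.5 * (1.0 + s))
    n_min = int(math.ceil(q * (1.0 - q) * phi**2 / r**2))
    if len(x) < n_min:
        raise InputError(
            f"chain of length {len(x)} is shorter than the minimum {n_min} "
            f"required for q={q}, r={r}, s={s}"
        )
    cutoff = np.quantile(x, q)
    z = (x <= cutoff).astype(int)
    # select thinning: smallest k where a first-order chain beats second-order
    k = 1
    while not _markov_bic_prefers_first_order(z, k):
        k += 1
        if k > len(z) // 2:
            break
    zk = z[::k]
    pairs = np.stack([zk[:-1], zk[1:]])
    n01 = int(((pairs[0] == 0) & (pairs[1] == 1)).sum())
    n0 = int((pairs[0] == 0).sum())
    n10 = int(((pairs[0] == 1) & (pairs[1] == 0)).sum())
    n1 = int((pairs[0] == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateChainError("indicator chain never changes state")
    alpha = max(n01 / n0, 1e-12)
    beta = max(n10 / n1, 1e-12)
    ab = alpha + beta
    m = math.ceil(
        math.log(eps * ab / max(alpha, beta)) / math.log(abs(1.0 - ab))
    )
    n_req = math.ceil(alpha * beta * (2.0 - ab) / ab**3 * phi**2 / r**2)
    burn = int(m) * k
    n_total = int(n_req) * k
    return RafteryLewisResult(
        n_min=n_min,
        burn_in=burn,
        n_required=n_total,
        thin=k,
        dependence_factor=(burn + n_total) / n_min,
    )


def diagnose_sample(
    sample: PosteriorSample,
    params: tuple[str, ...] = ("beta0", "beta1", "beta2", "sigma2"),
    z_threshold: float = 1.96,
) -> DiagnosticsReport:
    """Geweke and Raftery-Lewis diagnostics for each monitored parameter."""
    rows = {}
    for p in params:
        chain = sample.draws[p].to_numpy()
        zscore = geweke_diagnostic(chain)
        try:
            rl = raftery_lewis(chain)
            rl_n, rl_i = rl.n_required, rl.dependence_factor
        except InputError:
            rl_n, rl_i = np.nan, np.nan
        rows[p] = {
            "geweke_z": zscore,
            "geweke_pass": abs(zscore) < z_threshold,
            "rl_n_required": rl_n,
            "rl_dependence_factor": rl_i,
        }
    return DiagnosticsReport(genotype=sample.genotype, table=pd.DataFrame(rows).T)


@dataclass(frozen=True)
class DicResult:
    genotype: str
    dic: float
    d_bar: float
    d_hat: float
    p_d: float


def compute_dic(
    sample: PosteriorSample,
    responses,
    index: EnvironmentIndex,
) -> DicResult:
    """DIC for one genotype's posterior sample.

    Dbar averages -2 log L over retained draws; Dhat evaluates it at the
    posterior means of (beta0, beta1, beta2, sigma2).
    """
    draws = sample.draws
    betas = draws[["beta0", "beta1", "beta2"]].to_numpy()
    sigma2 = draws["sigma2"].to_numpy()
    y, X = _prepare(responses, index)
    a = len(y)
    sse = ((y[:, None] - X @ betas.T) ** 2).sum(axis=0)
    devs = a * np.log(2.0 * np.pi * sigma2) + sse / sigma2
    if not np.isfinite(devs).all():
        raise NumericalError("non-finite deviance encountered")
    d_bar = float(devs.mean())
    d_hat = -2.0 * log_likelihood(
        float(betas[:, 0].mean()), float(betas[:, 1].mean()),
        float(betas[:, 2].mean()), float(sigma2.mean()), responses, index,
    )
    p_d = d_bar - d_hat
    return DicResult(
        genotype=sample.genotype, dic=d_bar + p_d, d_bar=d_bar,
        d_hat=float(d_hat), p_d=float(p_d),
    )


def compare_priors(dic_m1: DicResult, dic_m2: DicResult) -> float:
    """DIC difference (vague minus informative); positive favors informative."""
    if dic_m1.genotype != dic_m2.genotype:
        raise InputError(
            f"genotype mismatch: {dic_m1.genotype!r} vs {dic_m2.genotype!r}"
        )
    return dic_m1.dic - dic_m2.dic
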