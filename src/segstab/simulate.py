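"""Synthetic balanced MET trials with known segmented-response truth.

The generator draws a designed environmental index (a configured fraction of
environments favorable), places every genotype's cell means exactly on its
own bi-segmented response surface, and adds block effects and plot-level
experimental error on top:

    y_ijk = beta0_i + beta1_i * I_j + beta2_i * T(I_j) + b_k(j) + eps_ijk

By default the genotype truths are recentred so that the mean slope across
genotypes is exactly 1, the mean slope change is 0 and the mean intercept is
the configured grand mean; under the mean-deviation environmental index this
makes the realized (data-derived) index coincide with the designed one — in
the noiseless case exactly — so generation and analysis share one index
definition.

Default magnitudes mimic a realistic tropical maize trial of 25 hybrids x 22
environments x 2 blocks: grand mean 8683 kg/ha, environment-effect SD 1500,
block SD 300 and plot-error SD around 840 kg/ha (error variance ~7e5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes import PosteriorSummary
from .errors import InputError
from .trial_data import TrialTable, compute_environment_index, transform_T

__all__ = ["GenotypeTruth", "SimulationConfig", "SimulatedStudy",
           "simulate_trial", "truth_recovery_report"]


@dataclass(frozen=True)
class GenotypeTruth:
    genotype: str
    beta0: float
    beta1: float
    beta2: float
    error_sd: float  # plot-level experimental error SD, kg/ha


@dataclass(frozen=True)
class SimulationConfig:
    n_genotypes: int = 25
    n_environments: int = 22
    n_blocks: int = 2
    env_effect_sd: float = 1500.0
    block_sd: float = 300.0
    favorable_fraction: float = 0.5
    grand_mean: float = 8683.0
    seed: int = 0
    truths: tuple[GenotypeTruth, ...] | None = None
    # ranges for default truth sampling (before recentring)
    beta0_range: tuple[float, float] = (7500.0, 9500.0)
    beta1_range: tuple[float, float] = (0.4, 1.6)
    beta2_range: tuple[float, float] = (-1.0, 1.0)
    error_sd_range: tuple[float, float] = (700.0, 1400.0)
    recenter_truths: bool = True

    def __post_init__(self) -> None:
        if self.n_environments < 4:
            raise InputError("need at least 4 environments")
        if self.n_genotypes < 1 or self.n_blocks < 1:
            raise InputError("need at least 1 genotype and 1 block")
        n_fav = round(self.favorable_fraction * self.n_environments)
        if not (1 <= n_fav <= self.n_environments - 1):
            raise InputError(
                "favorable_fraction must leave at least one favorable and one "
                "unfavorable environment"
            )
        for name in ("env_effect_sd", "block_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.truths is not None and len(self.truths) != self.n_genotypes:
            raise InputError("truths must have one entry per genotype")


@dataclass(frozen=True)
class SimulatedStudy:
    table: TrialTable
    config: SimulationConfig
    truths: tuple[GenotypeTruth, ...]
    designed_index: pd.Series   # environment -> designed I_j (sums to 0)
    designed_i_plus_bar: float
    truth_frame: pd.DataFrame = field(repr=False, default=None)


def _default_truths(config: SimulationConfig, rng: np.random.Generator):
    b0 = rng.uniform(*config.beta0_range, config.n_genotypes)
    b1 = rng.uniform(*config.beta1_range, config.n_genotypes)
    b2 = rng.uniform(*config.beta2_range, config.n_genotypes)
    esd = rng.uniform(*config.error_sd_range, config.n_genotypes)
    if config.recenter_truths:
        b0 = b0 - b0.mean() + config.grand_mean
        b1 = b1 - b1.mean() + 1.0
        b2 = b2 - b2.mean()
    return tuple(
        GenotypeTruth(f"G{i + 1:02d}", float(b0[i]), float(b1[i]), float(b2[i]),
                      float(esd[i]))
        for i in range(config.n_genotypes)
    )


def _designed_index(config: SimulationConfig, rng: np.random.Generator):
    """Signed environment effects: n_fav positive, rest negative, sum zero."""
    E = config.n_environments
    n_fav = round(config.favorable_fraction * E)
    for _ in range(100):
        mags = np.abs(rng.normal(0.0, config.env_effect_sd, E))
        mags = np.maximum(mags, 1e-6 * max(config.env_effect_sd, 1.0))
        d = np.where(np.arange(E) < n_fav, mags, -mags)
        # rescale the unfavorable group so the index sums to zero without
        # flipping any sign
        pos_sum = d[d > 0].sum()
        neg_sum = -d[d < 0].sum()
        d[d < 0] *= pos_sum / neg_sum
        if len(np.unique(d)) == E:
            return d
    raise InputError("could not draw a sign-balanced environment index")


def simulate_trial(config: SimulationConfig) -> SimulatedStudy:
    """Generate a balanced trial table plus its truth record.

    Reproducible: identical configs (including seed) give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truths = config.truths or _default_truths(config, rng)
    d = _designed_index(config, rng)
    envs = [f"E{j + 1:02d}" for j in range(config.n_environments)]
    blocks = [f"B{k + 1}" for k in range(config.n_blocks)]
    pos = d[d > 0]
    i_plus_bar = float(pos.mean()) if len(pos) else 0.0
    t = transform_T(d, i_plus_bar)

    block_eff = rng.normal(0.0, config.block_sd,
                           (config.n_environments, config.n_blocks))
    rows = []
    for i, tr in enumerate(truths):
        cell = tr.beta0 + tr.beta1 * d + tr.beta2 * t
        noise = rng.normal(0.0, tr.error_sd,
                           (config.n_environments, config.n_blocks))
        for j, env in enumerate(envs):
            for k, blk in enumerate(blocks):
                rows.append(
                    (tr.genotype, env, blk,
                     cell[j] + block_eff[j, k] + noise[j, k])
                )
    df = pd.DataFrame(rows, columns=["genotype", "environment", "block", "yield"])
    # yields are physical quantities; clip at zero only if noise drove a plot
    # negative (essentially never at realistic settings)
    df["yield"] = df["yield"].clip(lower=0.0)
    table = TrialTable(df, metadata={"simulated": "true", "seed": str(config.seed)})
    truth_frame = pd.DataFrame(
        [
            {"genotype": tr.genotype, "beta0": tr.beta0, "beta1": tr.beta1,
             "beta2": tr.beta2, "error_sd": tr.error_sd}
            for tr in truths
        ]
    )
    return SimulatedStudy(
        table=table, config=config, truths=truths,
        designed_index=pd.Series(d, index=envs, name="index"),
        designed_i_plus_bar=i_plus_bar,
        truth_frame=truth_frame,
    )


def truth_recovery_report(
    study: SimulatedStudy,
    summaries: list[PosteriorSummary],
) -> pd.DataFrame:
    """True vs posterior-mean coefficients and 95%-interval coverage flags."""
    truth_by_geno = {t.genotype: t for t in study.truths}
    sum_by_geno = {s.genotype: s for s in summaries}
    if set(truth_by_geno) != set(sum_by_geno):
        raise InputError("summaries and study cover different genotypes")
    rows = []
    for geno in sorted(truth_by_geno):
        tr, s = truth_by_geno[geno], sum_by_geno[geno]
        row = {"genotype": geno}
        for param, true_val in (
            ("beta0", tr.beta0),
            ("beta1", tr.beta1),
            ("beta12", tr.beta1 + tr.beta2),
        ):
            est = s.mean(param)
            lo, hi = s.interval(param)
            row[f"{param}_true"] = true_val
            row[f"{param}_est"] = est
            row[f"{param}_error"] = est - true_val
            row[f"{param}_covered"] = lo <= true_val <= hi
        rows.append(row)
    return pd.DataFrame(rows)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a config with a different seed (fresh truths and noise)."""
    return replace(config, seed=seed)
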