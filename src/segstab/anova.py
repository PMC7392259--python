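"""Joint analysis of variance for balanced MET data.

Model: y_ijk = mu + r/e_k(j) + e_j + g_i + ge_ij + eps_ijk, with blocks
nested within environments.  For a balanced design (G genotypes x E
environments x r blocks) the sums of squares have the textbook closed forms
used here; the residual mean square (MSR) feeds the Bayesian stability
parameter downstream.

All F tests use the error mean square as denominator, mirroring the joint
ANOVA tables conventional in MET reports, even though environment and
interaction effects are often conceptualized as random; a mixed-model
expected-mean-square ladder is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, StateError
from .trial_data import TrialTable

__all__ = ["AnovaTable", "joint_anova", "residual_mean_square"]


@dataclass(frozen=True)
class AnovaTable:
    """ANOVA decomposition with grand mean and replicate count.

    ``rows`` has columns source, df, ss, ms, F, p; F and p are NaN for
    sources not tested against the error term.
    """

    rows: pd.DataFrame
    grand_mean: float
    r: int

    def __getitem__(self, source: str) -> pd.Series:
        match = self.rows[self.rows["source"] == source]
        if match.empty:
            raise StateError(f"no ANOVA row named {source!r}")
        return match.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out.to_csv(path, index=False, float_format="%.6f")

    def render(self) -> str:
        """Aligned-text table (Source, DF, SS, MS, F, p)."""
        lines = [f"{'Source':<22}{'DF':>6}{'SS':>18}{'MS':>16}{'F':>10}{'p':>10}"]
        for _, row in self.rows.iterrows():
            f = f"{row['F']:.2f}" if np.isfinite(row["F"]) else ""
            p = f"{row['p']:.4f}" if np.isfinite(row["p"]) else ""
            lines.append(
                f"{row['source']:<22}{int(row['df']):>6}{row['ss']:>18.1f}"
                f"{row['ms']:>16.1f}{f:>10}{p:>10}"
            )
        lines.append(f"{'Mean (kg/ha)':<22}{'':>6}{self.grand_mean:>18.2f}")
        return "\n".join(lines)


def joint_anova(table: TrialTable) -> AnovaTable:
    """Balanced fixed-effects joint ANOVA of a MET trial.

    Requires a balanced table with at least two genotypes, environments and
    blocks.  Returns rows for Blocks/Environments, Genotypes, Environments,
    G x E and Error, with F statistics against the error mean square.
    """
    if not table.balanced:
        raise InputError("joint ANOVA requires a balanced trial table")
    G = len(table.genotypes)
    E = len(table.environments)
    r = table.n_blocks
    if G < 2 or E < 2 or r < 2:
        raise InputError(
            f"joint ANOVA needs >=2 levels of every factor (got G={G}, E={E}, r={r})"
        )
    df = table.data
    y = df["yield"].to_numpy(float)
    grand = float(y.mean())
    n = len(y)

    ss_total = float(((y - grand) ** 2).sum())
    env_means = df.groupby("environment", observed=True)["yield"].mean()
    geno_means = df.groupby("genotype", observed=True)["yield"].mean()
    cell_means = df.groupby(["genotype", "environment"], observed=True)["yield"].mean()
    block_means = df.groupby(["environment", "block"], observed=True)["yield"].mean()

    ss_env = G * r * float(((env_means - grand) ** 2).sum())
    ss_geno = E * r * float(((geno_means - grand) ** 2).sum())
    # blocks nested in environments: deviations of block means from their
    # environment mean, each based on G plots
    ss_blocks = G * float(
        ((block_means - env_means.reindex(block_means.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    ge_dev = (
        cell_means
        - geno_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - env_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = r * float((ge_dev**2).sum())
    ss_error = ss_total - ss_env - ss_geno - ss_blocks - ss_ge
    ss_error = max(ss_error, 0.0)

    df_blocks = E * (r - 1)
    df_geno = G - 1
    df_env = E - 1
    df_ge = (G - 1) * (E - 1)
    df_error = (n - 1) - df_blocks - df_geno - df_env - df_ge

    ms_error = ss_error / df_error

    def row(source, dof, ss, tested):
        ms = ss / dof if dof > 0 else np.nan
        if tested and ms_error > 0:
            F = ms / ms_error
            p = float(stats.f.sf(F, dof, df_error))
        else:
            F, p = np.nan, np.nan
        return {"source": source, "df": dof, "ss": ss, "ms": ms, "F": F, "p": p}

    rows = pd.DataFrame(
        [
            row("Blocks/Environments", df_blocks, ss_blocks, False),
            row("Genotypes", df_geno, ss_geno, True),
            row("Environments", df_env, ss_env, True),
            row("Genotypes x Environments", df_ge, ss_ge, True),
            row("Error", df_error, ss_error, False),
        ]
    )
    return AnovaTable(rows=rows, grand_mean=grand, r=r)


def residual_mean_square(anova: AnovaTable) -> float:
    """MSR: the error mean square of the joint ANOVA."""
    err = anova["Error"]
    if err["df"] <= 0:
        raise StateError("Error row has no degrees of freedom")
    return float(err["ms"])
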