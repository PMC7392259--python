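"""Data model and I/O for multi-environment trial (MET) yield tables.

A trial table holds one plot-level record per (genotype, environment, block)
with yield in kg/ha.  From it the module derives the quantities the
bi-segmented adaptability model is built on:

* the coded environmental index ``I_j`` — the mean yield of environment *j*
  (over all genotypes and blocks) minus the grand mean, so favorable
  environments have positive index and the indexes sum to zero in a balanced
  design (the classical Eberhart-Russell / Toler index);
* ``i_plus_bar`` — the mean of the strictly positive indexes, which centers
  the favorable-regime regressor;
* the change-point regressor ``T(I_j)``, zero for ``I_j <= 0`` and
  ``I_j - i_plus_bar`` for ``I_j > 0``.

Genotype and environment labels are opaque strings; block labels only need to
be unique within an environment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, IntegrityError, SchemaError

REQUIRED_COLUMNS = ("genotype", "environment", "block", "yield")

__all__ = [
    "TrialTable",
    "EnvironmentIndex",
    "read_trials",
    "write_trials",
    "compute_environment_index",
    "transform_T",
    "genotype_environment_means",
]


@dataclass(frozen=True)
class TrialTable:
    """Validated long-format MET yield table.

    Parameters
    ----------
    data
        DataFrame with columns ``genotype``, ``environment``, ``block``
        (strings) and ``yield`` (finite, non-negative, kg/ha).
    metadata
        Free-form provenance strings.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("genotype", "environment", "block"):
            df[col] = df[col].astype(str)
            if (df[col].str.len() == 0).any():
                raise SchemaError(f"empty identifier in column {col!r}")
        try:
            df["yield"] = pd.to_numeric(df["yield"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric yield value: {exc}") from exc
        if not np.isfinite(df["yield"].to_numpy(float)).all():
            raise SchemaError("yield contains non-finite values")
        if (df["yield"] < 0).any():
            raise SchemaError("yield contains negative values")
        dup = df.duplicated(subset=["genotype", "environment", "block"])
        if dup.any():
            keys = df.loc[dup, ["genotype", "environment", "block"]].iloc[0]
            raise IntegrityError(
                "duplicate (genotype, environment, block) key: "
                f"({keys['genotype']}, {keys['environment']}, {keys['block']})"
            )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def balanced(self) -> bool:
        """True iff every genotype x environment cell has the same number of blocks."""
        counts = self.data.groupby(["genotype", "environment"], observed=True).size()
        full = len(self.genotypes) * len(self.environments)
        return len(counts) == full and counts.nunique() == 1

    @property
    def n_blocks(self) -> int | None:
        """Common block count r for balanced tables, None otherwise."""
        if not self.balanced:
            return None
        return int(
            self.data.groupby(["genotype", "environment"], observed=True).size().iloc[0]
        )

    @property
    def grand_mean(self) -> float:
        return float(self.data["yield"].mean())


@dataclass(frozen=True)
class EnvironmentIndex:
    """Coded environmental index for a trial.

    ``index`` maps environment -> I_j (kg/ha deviation from the grand mean),
    ``i_plus_bar`` is the mean of strictly positive indexes (0 when none are
    positive) and ``grand_mean`` is the mean of all plot yields.
    """

    index: pd.Series
    i_plus_bar: float
    grand_mean: float

    def t_values(self) -> pd.Series:
        """Change-point regressor T(I_j) for every environment."""
        return pd.Series(
            transform_T(self.index.to_numpy(float), self.i_plus_bar),
            index=self.index.index,
            name="T",
        )

    def to_csv(self, path: str | Path) -> None:
        """Write (environment, index) rows preceded by a metadata comment."""
        with open(path, "w") as fh:
            fh.write(
                f"# grand_mean={self.grand_mean:.6f} i_plus_bar={self.i_plus_bar:.6f}\n"
            )
            self.index.rename_axis("environment").rename("index").to_csv(fh)


def read_trials(
    source: str | Path | io.IOBase,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
) -> TrialTable:
    """Read a long-format MET yield table from CSV or XLSX.

    ``column_map`` maps the canonical names (genotype, environment, block,
    yield) to the names used in the file.
    """
    if format == "csv":
        df = pd.read_csv(source)
    elif format == "xlsx":
        df = pd.read_excel(source, sheet_name=0)
    else:
        raise InputError(f"unsupported format {format!r} (expected csv or xlsx)")
    if column_map:
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise SchemaError(f"mapped column(s) not in file: {', '.join(missing)}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    meta = {"source": str(source), "format": format}
    return TrialTable(df, metadata=meta)


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Write a trial table back to CSV (exact round trip with read_trials)."""
    table.data.to_csv(path, index=False)


def compute_environment_index(table: TrialTable) -> EnvironmentIndex:
    """Environmental index I_j = (mean yield of environment j) - grand mean.

    Environment means are taken over all genotypes and blocks, so for a
    balanced design the indexes sum to zero exactly (up to rounding).
    """
    if table.n_records == 0:
        raise InputError("cannot compute an environmental index from an empty table")
    grand = table.grand_mean
    env_means = table.data.groupby("environment", observed=True)["yield"].mean()
    index = (env_means - grand).rename("index").sort_index()
    positive = index[index > 0]
    i_plus_bar = float(positive.mean()) if len(positive) else 0.0
    return EnvironmentIndex(index=index, i_plus_bar=i_plus_bar, grand_mean=grand)


def transform_T(i_value, i_plus_bar: float):
    """Favorable-regime regressor: 0 for I <= 0, else I - i_plus_bar.

    Accepts scalars or arrays.
    """
    if not np.isfinite(i_plus_bar):
        raise InputError("i_plus_bar must be finite")
    arr = np.asarray(i_value, dtype=float)
    out = np.where(arr <= 0.0, 0.0, arr - i_plus_bar)
    if np.isscalar(i_value) or arr.ndim == 0:
        return float(out)
    return out


def genotype_environment_means(table: TrialTable) -> pd.DataFrame:
    """Cell means over blocks, as a (genotype x environment) DataFrame.

    These block-averaged yields are the responses the segmented regression is
    fitted to.  Raises :class:`InputError` naming the first empty cell if any
    genotype x environment combination has no observations.
    """
    if table.n_records == 0:
        raise InputError("empty trial table")
    means = (
        table.data.groupby(["genotype", "environment"], observed=True)["yield"]
        .mean()
        .unstack("environment")
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    if means.isna().any().any():
        stacked = means.isna().stack()
        geno, env = stacked[stacked].index[0]
        raise InputError(f"empty genotype x environment cell: ({geno}, {env})")
    return means
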