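"""Bundled reference data and loaders for deposited trial data.

``published_posterior_intervals`` returns the posterior summary table of a
published analysis of 25 tropical maize hybrids evaluated in 22 environments
(two blocks), under both a vague ("M1") and an informative ("M2") prior set.
Only the printed summaries (posterior means, 95% credible bounds and R^2 in
percent) are bundled; the underlying plot-level yields were deposited by the
original authors as a supplementary spreadsheet and are not redistributed
here.  ``load_study_trial`` reads that spreadsheet once the user has placed
it in the repository's ``data/`` directory (or passes an explicit path).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import InputError
from .trial_data import TrialTable, read_trials

#: grand mean yield (kg/ha) printed with the published joint ANOVA
PUBLISHED_GRAND_MEAN = 8682.99

_STUDY_FILENAMES = ("maize_met_yields.xlsx", "maize_met_yields.csv")


def published_posterior_intervals(prior_set: str | None = None) -> pd.DataFrame:
    """Published posterior means/95% bounds per genotype and prior set.

    ``prior_set`` filters to "M1" (vague priors) or "M2" (informative);
    default returns both blocks (50 rows).
    """
    with resources.files("segstab.data").joinpath(
        "maize_met_posterior_intervals.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    if prior_set is not None:
        if prior_set not in ("M1", "M2"):
            raise InputError("prior_set must be 'M1' or 'M2'")
        df = df[df["prior_set"] == prior_set].reset_index(drop=True)
    return df


def load_study_trial(path: str | Path | None = None) -> TrialTable:
    """Load the deposited plot-level yield spreadsheet of the reference study.

    Looks for ``data/maize_met_yields.xlsx`` (or ``.csv``) under the current
    working directory unless ``path`` is given.  Expects columns genotype,
    environment, block, yield (kg/ha), one row per plot.
    """
    candidates = (
        [Path(path)] if path is not None
        else [Path("data") / name for name in _STUDY_FILENAMES]
    )
    for cand in candidates:
        if cand.exists():
            fmt = "xlsx" if cand.suffix.lower() == ".xlsx" else "csv"
            return read_trials(cand, format=fmt)
    raise InputError(
        "deposited trial data not found; place the study's plot-level yield "
        "table at data/maize_met_yields.xlsx (or .csv) with columns "
        "genotype, environment, block, yield"
    )
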