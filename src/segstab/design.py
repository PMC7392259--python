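"""Design matrix for the bi-segmented regression: columns {1, I_j, T(I_j)}."""

from __future__ import annotations

import numpy as np

from .errors import EstimabilityError, InputError
from .trial_data import EnvironmentIndex

__all__ = ["build_design", "check_rank"]


def build_design(index: EnvironmentIndex, environments) -> np.ndarray:
    """Design matrix {1, I_j, T(I_j)} over the given environment order."""
    i_vals = index.index.reindex(environments).to_numpy(float)
    if np.isnan(i_vals).any():
        missing = [e for e in environments if e not in index.index.index]
        raise InputError(f"environments without an index value: {missing}")
    t_vals = np.where(i_vals <= 0.0, 0.0, i_vals - index.i_plus_bar)
    return np.column_stack([np.ones_like(i_vals), i_vals, t_vals])


def check_rank(X: np.ndarray) -> None:
    """Reject designs where the two regimes are not both represented."""
    i_vals = X[:, 1]
    if not (i_vals > 0).any():
        raise EstimabilityError(
            "no favorable environments (all I_j <= 0): the change-point "
            "regressor T(I_j) is identically zero"
        )
    if not (i_vals <= 0).any():
        raise EstimabilityError(
            "no unfavorable environments (all I_j > 0): I_j and T(I_j) are collinear"
        )
    if np.linalg.matrix_rank(X) < 3:
        raise EstimabilityError("segmented design matrix is rank deficient")
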