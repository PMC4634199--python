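"""Behavioral outcome variables.

Two derived measures feed the compensation analyses:

* an n-back detection score defined as hit probability minus false-alarm
  probability (a bounded accuracy index in [-1, 1]; note this is the simple
  probability-difference form, not the classical z-transformed d'), and
* a global cognitive composite: the first principal component of nine
  standardized cognitive test scores, sign-oriented so that higher = better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegeneracyError, InvalidCountsError, MissingDataError

__all__ = ["NbackCounts", "dprime", "CompositeResult", "cognitive_composite"]


@dataclass(frozen=True)
class NbackCounts:
    """Response counts for one subject in one n-back condition."""

    n_targets: int
    n_hits: int
    n_nontargets: int
    n_false_alarms: int
    condition: str = "2back"

    def __post_init__(self) -> None:
        if self.n_targets <= 0 or self.n_nontargets <= 0:
            raise InvalidCountsError(
                "n_targets and n_nontargets must be positive (zero denominators)"
            )
        if not 0 <= self.n_hits <= self.n_targets:
            raise InvalidCountsError("need 0 <= n_hits <= n_targets")
        if not 0 <= self.n_false_alarms <= self.n_nontargets:
            raise InvalidCountsError("need 0 <= n_false_alarms <= n_nontargets")


def dprime(counts: NbackCounts) -> float:
    """Hit probability minus false-alarm probability, in [-1, 1]."""
    return counts.n_hits / counts.n_targets - counts.n_false_alarms / counts.n_nontargets


@dataclass
class CompositeResult:
    """First-principal-component cognitive composite.

    ``scores`` are subject scores on the first PC of the standardized (and
    orientation-corrected) battery; ``loadings`` the per-test weights;
    ``explained_variance_ratio`` the share of total variance the component
    carries (always the largest share, by construction of the leading PC).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: float
    test_names: list[str]


def cognitive_composite(
    battery: pd.DataFrame | np.ndarray,
    higher_is_better: Sequence[bool] | None = None,
) -> CompositeResult:
    """Global cognitive composite from a battery of test scores.

    Each column is oriented (columns flagged ``higher_is_better=False`` are
    negated), standardized to mean 0 / sd 1, and the subjects' scores on the
    first principal component are returned, with the component's sign chosen
    so the mean loading is positive (higher composite = better cognition).

    Raises
    ------
    MissingDataError
        If any value is missing; no silent imputation is performed.
    DegeneracyError
        If a column is constant across subjects.
    """
    if isinstance(battery, pd.DataFrame):
        names = [str(c) for c in battery.columns]
        X = battery.to_numpy(dtype=float)
    else:
        X = np.asarray(battery, dtype=float)
        names = [f"test{j + 1}" for j in range(X.shape[1])]
    if X.ndim != 2:
        raise ValueError("battery must be 2D (subjects x tests)")
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    if np.isnan(X).any():
        bad = [names[j] for j in range(p) if np.isnan(X[:, j]).any()]
        raise MissingDataError(f"missing values in columns: {bad}")

    if higher_is_better is not None:
        flags = np.asarray(list(higher_is_better), dtype=bool)
        if flags.shape != (p,):
            raise ValueError("higher_is_better must have one flag per column")
        X = X * np.where(flags, 1.0, -1.0)

    sd = X.std(axis=0, ddof=1)
    const = [names[j] for j in range(p) if sd[j] == 0]
    if const:
        raise DegeneracyError(f"constant columns (PCA degeneracy): {const}")
    Z = (X - X.mean(axis=0)) / sd

    # Leading PC via SVD of the standardized matrix.
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[0]
    if loadings.mean() < 0:
        loadings = -loadings
        U = U.copy()
        U[:, 0] = -U[:, 0]
    scores = U[:, 0] * S[0]
    evr = float(S[0] ** 2 / np.sum(S**2))
    return CompositeResult(scores=scores, loadings=loadings,
                           explained_variance_ratio=evr, test_names=names)
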