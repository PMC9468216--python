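"""Iterative random-forest imputation for categorical tables (missForest scheme).

Missing cells are first filled with column modes, then columns are revisited
in increasing-missingness order: a classification forest is trained on the
rows observed for that column (all other columns as predictors, current
imputations included) and its predictions replace the column's missing
cells. Iteration stops when the fraction of imputed cells that changed
stops decreasing, returning the previous iterate, or at ``max_iter``.

The forest learner sits behind a factory so alternatives can be swapped in;
the default is a bagged random-feature decision forest (100 trees,
sqrt-features per split, Gini impurity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .codebook import MISSING

__all__ = [
    "ImputationResult",
    "initialize_fill",
    "rf_impute",
    "imputation_accuracy",
]


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    iterations: int
    disagreement: list[float] = field(default_factory=list)


def _missing_mask(data: pd.DataFrame) -> pd.DataFrame:
    return data.isna() | (data == MISSING)


def initialize_fill(data: pd.DataFrame) -> pd.DataFrame:
    """Replace every missing cell by its column's observed mode.

    Ties between equally frequent codes resolve to the smallest code. A
    column with no observed value at all cannot be initialized.
    """
    miss = _missing_mask(data)
    out = data.copy()
    for col in data.columns:
        if not miss[col].any():
            continue
        observed = data.loc[~miss[col], col]
        if observed.empty:
            raise ValueError(f"column {col!r} is fully missing; cannot initialize")
        counts = observed.value_counts()
        top = counts[counts == counts.max()].index.min()
        out.loc[miss[col], col] = top
    return out.astype(data.dtypes.to_dict())


def _default_forest(trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=trees,
        max_features="sqrt",
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )


def rf_impute(
    data: pd.DataFrame,
    max_iter: int = 10,
    trees: int = 100,
    seed: int = 0,
    learner_factory: Callable[[int, int], object] = _default_forest,
) -> ImputationResult:
    """missForest-style iterative imputation; deterministic under a fixed seed.

    Returns a complete table in which originally observed cells are
    bit-identical to the input, plus the per-iteration disagreement
    (fraction of imputed cells that changed relative to the previous
    iteration; the first entry compares against the mode fill).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    miss = _missing_mask(data)
    n_missing = int(miss.to_numpy().sum())
    current = initialize_fill(data)
    if n_missing == 0:
        return ImputationResult(completed=current, iterations=1, disagreement=[0.0])

    # missForest convention: revisit columns in increasing missingness order
    order = [c for c in miss.sum().sort_values(kind="stable").index if miss[c].any()]
    rng = np.random.default_rng(seed)
    disagreement: list[float] = []
    previous = current.copy()
    best = current.copy()
    for iteration in range(1, max_iter + 1):
        for col in order:
            train_rows = ~miss[col]
            predictors = [c for c in data.columns if c != col]
            forest = learner_factory(trees, int(rng.integers(0, 2**31 - 1)))
            forest.fit(
                current.loc[train_rows, predictors].to_numpy(),
                current.loc[train_rows, col].to_numpy(),
            )
            pred = forest.predict(current.loc[miss[col], predictors].to_numpy())
            current.loc[miss[col], col] = pred
        changed = int(
            ((current.to_numpy() != previous.to_numpy()) & miss.to_numpy()).sum()
        )
        disagreement.append(changed / n_missing)
        if len(disagreement) >= 2 and disagreement[-1] >= disagreement[-2]:
            # stopped improving: return the previous iterate
            return ImputationResult(
                completed=best, iterations=iteration, disagreement=disagreement
            )
        best = current.copy()
        if disagreement[-1] == 0.0:
            break
        previous = current.copy()
    return ImputationResult(completed=best, iterations=len(disagreement), disagreement=disagreement)


def imputation_accuracy(
    truth: pd.DataFrame, result: ImputationResult | pd.DataFrame, mask: pd.DataFrame
) -> float | None:
    """Fraction of originally-missing cells imputed to the true code.

    Returns ``None`` when the mask is empty (no cells to score) rather
    than a misleading 0.
    """
    completed = result.completed if isinstance(result, ImputationResult) else result
    if truth.shape != completed.shape or truth.shape != mask.shape:
        raise ValueError("truth, completed and mask must share a shape")
    m = mask.to_numpy().astype(bool)
    total = int(m.sum())
    if total == 0:
        return None
    correct = int((completed.to_numpy()[m] == truth.to_numpy()[m]).sum())
    return correct / total
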