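"""G² (likelihood-ratio) test of conditional independence for coded tables.

The statistic is ``2 * sum O * ln(O/E)`` over the x-by-y contingency table
within each stratum of the conditioning set, summed across strata, with
``df = (|x|-1)(|y|-1) * prod |z_i|`` and a chi-square upper-tail p-value.
Zero-count cells contribute nothing. A sample-adequacy heuristic skips the
test (``performed=False``, treated as independence) when n < heuristic x df,
mirroring the standard guard against unreliable high-order conditional
tests. Pearson's X² is available as an alternative statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CITestResult", "g2_test", "infer_levels"]


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    df: int
    p_value: float
    performed: bool = True

    def independent(self, alpha: float) -> bool:
        """Convention: a skipped test counts as independence."""
        return (not self.performed) or self.p_value > alpha


def infer_levels(data: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sorted distinct codes per column, fixed once so df never drifts with subsets."""
    return {c: np.sort(data[c].unique()).astype(int) for c in data.columns}


def _positions(col: np.ndarray, levels: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(levels, col)
    if pos.max(initial=-1) >= len(levels) or not np.array_equal(levels[pos], col):
        raise ValueError("column contains values outside its declared levels")
    return pos


def g2_test(
    data: pd.DataFrame,
    x: str,
    y: str,
    z: Sequence[str] = (),
    levels: Mapping[str, np.ndarray] | None = None,
    statistic: str = "g2",
    adequacy: float = 5.0,
) -> CITestResult:
    """Test X independent of Y given Z on complete categorical data.

    Parameters
    ----------
    levels
        Category codes per variable; inferred from ``data`` when omitted.
        Passing the full-dataset levels keeps degrees of freedom stable when
        testing on subsamples.
    statistic
        ``"g2"`` (likelihood ratio, default) or ``"x2"`` (Pearson).
    adequacy
        Skip the test when ``n < adequacy * df`` (set 0 to always test).
    """
    if x == y or x in z or y in z:
        raise ValueError("x, y and z must be distinct")
    if statistic not in ("g2", "x2"):
        raise ValueError(f"unknown statistic {statistic!r}")
    z = list(z)
    if levels is None:
        levels = infer_levels(data[[x, y, *z]])
    lx, ly = np.asarray(levels[x]), np.asarray(levels[y])
    lz = [np.asarray(levels[v]) for v in z]
    kx, ky = len(lx), len(ly)
    df = (kx - 1) * (ky - 1) * int(np.prod([len(l) for l in lz]))
    n = len(data)
    if df <= 0:
        raise ValueError("degenerate test: a tested variable has one category")
    if n < adequacy * df:
        return CITestResult(statistic=0.0, df=df, p_value=1.0, performed=False)

    xi = _positions(data[x].to_numpy(dtype=int), lx)
    yi = _positions(data[y].to_numpy(dtype=int), ly)
    if z:
        zi = np.zeros(n, dtype=np.int64)
        for v, lv in zip(z, lz):
            zi = zi * len(lv) + _positions(data[v].to_numpy(dtype=int), lv)
        n_strata = int(np.prod([len(l) for l in lz]))
    else:
        zi = np.zeros(n, dtype=np.int64)
        n_strata = 1

    counts = np.bincount(
        (zi * kx + xi) * ky + yi, minlength=n_strata * kx * ky
    ).reshape(n_strata, kx, ky).astype(float)

    n_s = counts.sum(axis=(1, 2), keepdims=True)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(n_s > 0, row * col / np.maximum(n_s, 1.0), 0.0)
        if statistic == "g2":
            terms = np.where(counts > 0, counts * np.log(counts / expected), 0.0)
            stat = 2.0 * float(terms.sum())
        else:
            terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
            stat = float(terms.sum())
    stat = max(stat, 0.0)  # clip -0.0 / rounding noise on exact independence
    p = float(stats.chi2.sf(stat, df))
    return CITestResult(statistic=stat, df=df, p_value=p, performed=True)
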