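"""Multivariable logistic regression baseline (IRLS) with odds-ratio reporting.

The comparison model for the network analysis: the binary multimorbidity
outcome on the ten integer-scored predictors, fitted by Newton/IRLS
maximization of the Bernoulli log-likelihood. Standard errors come from the
inverse observed information; odds ratios are exp(beta) with Wald 95%
intervals exp(beta +- 1.96 SE). Predictors enter as single per-variable
scores (one odds ratio per variable, interpreted per category step);
dummy coding of categories is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LogisticFit",
    "SeparationWarning",
    "fit_logistic_irls",
    "odds_ratio_table",
    "forest_plot_data",
    "dummy_code",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


class SeparationWarning(UserWarning):
    """Diverging coefficients: the MLE does not exist (perfect separation)."""


@dataclass
class LogisticFit:
    names: list[str]
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    log_likelihood: float
    converged: bool
    iterations: int
    separation: bool = False

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients[1:])

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coefficients[1:] - _Z95 * self.standard_errors[1:])

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coefficients[1:] + _Z95 * self.standard_errors[1:])

    @property
    def p_values(self) -> np.ndarray:
        from scipy.stats import norm

        z = np.divide(
            self.coefficients,
            self.standard_errors,
            out=np.zeros_like(self.coefficients),
            where=self.standard_errors > 0,
        )
        return 2 * norm.sf(np.abs(z))


def fit_logistic_irls(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit logit P(y=1) = intercept + X beta by iteratively reweighted least squares.

    Convergence is declared when the largest score-equation component
    (gradient of the log-likelihood) falls below ``tol``. Perfect or
    quasi-perfect separation (coefficients diverging) is flagged and a
    partial result returned with a :class:`SeparationWarning`.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{i + 1}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    n, p = Xm.shape
    A = np.column_stack([np.ones(n), Xm])
    beta = np.zeros(p + 1)
    separation = not (0 < y.sum() < n)  # constant outcome: no finite MLE
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = A.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = A.T @ (A * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # damped Newton: halve the step while the log-likelihood worsens
        def ll(b: np.ndarray) -> float:
            e = A @ b
            return float(y @ e - np.logaddexp(0.0, e).sum())
        ll0 = ll(beta)
        scale = 1.0
        while scale > 1e-8 and ll(beta + scale * step) < ll0 - 1e-10:
            scale /= 2
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 30:
            separation = True
            break
    eta = A @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = A.T @ (A * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    log_lik = float(y @ eta - np.logaddexp(0.0, eta).sum())
    if separation:
        warnings.warn(
            "perfect or quasi-perfect separation: coefficients diverge, "
            "returning a partial fit",
            SeparationWarning,
            stacklevel=2,
        )
        converged = False
    return LogisticFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        log_likelihood=log_lik,
        converged=converged,
        iterations=it,
        separation=separation,
    )


def odds_ratio_table(fit: LogisticFit, decimals: int = 2) -> pd.DataFrame:
    """Tidy per-predictor table: OR, Wald 95% CI and p-value, rounded for reporting."""
    if not fit.converged:
        raise ValueError("odds_ratio_table requires a converged fit")
    return pd.DataFrame(
        {
            "variable": fit.names,
            "odds_ratio": np.round(fit.odds_ratios, decimals),
            "ci_low": np.round(fit.ci_low, decimals),
            "ci_high": np.round(fit.ci_high, decimals),
            "p_value": fit.p_values[1:],
        }
    )


@dataclass
class ForestPlotData:
    rows: pd.DataFrame
    reference: float = 1.0

    def __len__(self) -> int:
        return len(self.rows)


def forest_plot_data(table: pd.DataFrame) -> ForestPlotData:
    """Forest-plot specification: one row per predictor plus the OR=1 reference line.

    A predictor whose confidence interval crosses 1 is flagged as not
    associated with the outcome.
    """
    rows = table.copy()
    if len(rows):
        rows["associated"] = ~((rows["ci_low"] <= 1.0) & (rows["ci_high"] >= 1.0))
    else:
        rows = rows.assign(associated=pd.Series(dtype=bool))
    return ForestPlotData(rows=rows.reset_index(drop=True))


def dummy_code(X: pd.DataFrame, reference: str = "first") -> pd.DataFrame:
    """Expand integer-scored predictors into one-hot columns (reference dropped)."""
    frames = []
    for col in X.columns:
        d = pd.get_dummies(X[col], prefix=col, dtype=float)
        drop = d.columns[0] if reference == "first" else d.columns[-1]
        frames.append(d.drop(columns=drop))
    return pd.concat(frames, axis=1)
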