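"""Reliability correlations and hierarchical regression comparisons.

Two reusable analyses: (1) Spearman rank correlations between two sets
of per-word measure values (e.g. the same measure computed against two
reference lexicons), and (2) a two-step ordinary-least-squares design
in which a baseline model (Zipf frequency + word length) is compared,
by adjusted R-squared, against the same model augmented with one
neighborhood measure (optionally with a quadratic term for the
standardized measure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm


class ConstantVectorError(ValueError):
    """Rank correlation is undefined for a constant vector."""


class InsufficientOverlapError(ValueError):
    """Too few shared words between two measure sets."""


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R-squared: 1 - (1 - R2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations for the adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class ModelComparison:
    """Baseline vs measure-augmented OLS fit, compared by adjusted R2."""

    baseline_r2: float
    baseline_adj_r2: float
    augmented_r2: float
    augmented_adj_r2: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    quadratic: bool

    @property
    def delta(self) -> float:
        return self.augmented_adj_r2 - self.baseline_adj_r2


def _fit_ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix (columns: {names})")
    return sm.OLS(y, X).fit()


def hierarchical_fit(
    data: pd.DataFrame,
    outcome: str,
    added_measure: str,
    quadratic: bool = False,
) -> ModelComparison:
    """Two-step OLS: outcome ~ zipf + length, then + measure (+ measure^2).

    In the linear case the measure enters on its own scale, so its
    coefficient is directly interpretable (and recoverable in
    simulation).  With the quadratic flag the measure is standardized
    before squaring, which limits collinearity between a term and its
    square.  Rows with any missing value in the used columns are
    dropped; at least 10 complete cases are required.
    """
    cols = [outcome, "zipf", "length", added_measure]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"behavioral table lacks columns: {missing}")
    frame = data[cols].dropna()
    n = len(frame)
    if n < 10:
        raise ValueError(f"only {n} complete cases; need at least 10")

    y = frame[outcome].to_numpy(dtype=float)
    base = np.column_stack(
        [np.ones(n), frame["zipf"].to_numpy(float), frame["length"].to_numpy(float)]
    )
    base_names = ["const", "zipf", "length"]
    base_fit = _fit_ols(y, base, base_names)

    meas = frame[added_measure].to_numpy(dtype=float)
    sd = meas.std(ddof=1)
    if sd == 0:
        raise ValueError(f"added measure {added_measure!r} is constant")
    aug_names = base_names + [added_measure]
    if quadratic:
        z = (meas - meas.mean()) / sd
        aug_cols = [z, z**2]
        aug_names.append(f"{added_measure}^2")
    else:
        aug_cols = [meas]
    X = np.column_stack([base, *aug_cols])
    aug_fit = _fit_ols(y, X, aug_names)

    coeffs = dict(zip(aug_names, aug_fit.params))
    ses = dict(zip(aug_names, aug_fit.bse))
    return ModelComparison(
        baseline_r2=float(base_fit.rsquared),
        baseline_adj_r2=float(base_fit.rsquared_adj),
        augmented_r2=float(aug_fit.rsquared),
        augmented_adj_r2=float(aug_fit.rsquared_adj),
        coefficients=coeffs,
        std_errors=ses,
        quadratic=quadratic,
    )


def reliability_report(values_a, values_b) -> tuple[float, int]:
    """Spearman rho between two per-word measure sets over shared words.

    Inputs are mappings or Series keyed by word; the report inner-joins
    on word and returns (rho, number of shared words).
    """
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise InsufficientOverlapError(
            f"only {len(joined)} words shared between the two measure sets"
        )
    return spearman_rho(joined["a"], joined["b"]), len(joined)
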