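"""Pre-modelling screening: crosstabs, chi-square tests, bivariate fits.

Birth weight is first categorized three ways — below 2.5 kg (low),
2.5 to 4.5 kg inclusive (normal), above 4.5 kg (high) — and
cross-tabulated against each categorical covariate with a Pearson
chi-square test (no continuity correction; the tables are multi-level).
Separately, each candidate covariate is screened with a single-term
frequentist quantile regression: a covariate is retained when any of
its level coefficients (or the metrical slope) is significant at the
20% level, a deliberately permissive gate that feeds the multivariable
Bayesian model.  Standard errors come from the usual kernel sparsity
estimate of the check-loss minimizer's asymptotic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .data_model import MISSING_LEVEL, Dataset

__all__ = [
    "WEIGHT_CLASSES",
    "ContingencyTable",
    "categorize_weight",
    "crosstab",
    "chi_square_test",
    "bivariate_screen",
]

WEIGHT_CLASSES = ("low", "normal", "high")


def categorize_weight(y):
    """Three-way birth-weight class; boundaries 2.5 and 4.5 kg belong to
    the middle class."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("birth weight must be positive")
    out = np.where(y < 2.5, "low", np.where(y <= 4.5, "normal", "high"))
    return str(out) if out.ndim == 0 else out


@dataclass
class ContingencyTable:
    """Counts of weight classes per covariate level, with row percentages."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percentages(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


def crosstab(data: Dataset, covariate: str) -> ContingencyTable:
    """Cross-tabulate a categorical covariate against weight class.

    Declared levels never seen in the data keep an all-zero row.
    """
    if covariate not in data.schema.categoricals:
        raise ValueError(f"{covariate!r} is not a categorical covariate")
    classes = categorize_weight(data.y)
    levels = data.category_levels.get(covariate,
                                      sorted(data.df[covariate].unique()))
    tab = pd.crosstab(data.df[covariate].to_numpy(), classes)
    tab = tab.reindex(index=levels, columns=list(WEIGHT_CLASSES), fill_value=0)
    return ContingencyTable(row_labels=levels, col_labels=list(WEIGHT_CLASSES),
                            counts=tab.to_numpy(dtype=float))


def chi_square_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square: X^2 = sum (O-E)^2/E, df = (r-1)(c-1).

    Rows or columns with a zero marginal make an expected count zero and
    are an error (drop empty levels before testing).
    """
    counts = table.counts
    if np.any(counts < 0):
        raise ValueError("negative cell count")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("zero row or column marginal; expected counts vanish")
    stat, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def _design_for(data: Dataset, covariate: str) -> tuple[np.ndarray, list[str]] | None:
    """Intercept + single-term design; None when no contrast exists."""
    df = data.df
    if covariate in data.schema.categoricals:
        ref = data.schema.references[covariate]
        observed = [l for l in data.category_levels[covariate]
                    if (df[covariate] == l).any()]
        if len(observed) < 2:
            return None
        vals = df[covariate].to_numpy()
        cols = [np.ones(len(df))]
        names = ["intercept"]
        for lev in observed:
            if lev == ref:
                continue
            cols.append((vals == lev).astype(float))
            names.append(f"{covariate}={lev}")
        if len(cols) == 1:
            return None
        return np.column_stack(cols), names
    if covariate in data.schema.metricals:
        x = df[covariate].to_numpy(dtype=float)
        obs = np.isfinite(x)
        if np.unique(x[obs]).size < 2:
            return None
        X = np.column_stack([np.ones(len(df)), np.where(obs, x, 0.0)])
        return X, ["intercept", covariate]
    raise ValueError(f"unknown covariate {covariate!r}")


def bivariate_screen(data: Dataset, covariates: list[str], tau: float,
                     alpha: float = 0.20, *,
                     return_report: bool = False):
    """Single-covariate quantile-regression screen at level ``alpha``.

    A covariate is retained when any non-intercept coefficient of its
    bivariate fit at quantile ``tau`` has p < alpha.  For metrical
    covariates, records with a missing value are dropped from that fit.
    Degenerate covariates (a single observed level or constant value)
    are excluded with a warning.  Returns the retained list, or
    ``(retained, report)`` with a per-coefficient DataFrame when
    ``return_report`` is set.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    y_all = data.y
    retained: list[str] = []
    rows = []
    for cov in covariates:
        built = _design_for(data, cov)
        if built is None:
            warnings.warn(f"covariate {cov!r} is degenerate; excluded from screen")
            continue
        X, names = built
        keep = np.ones(len(y_all), dtype=bool)
        if cov in data.schema.metricals:
            keep = np.isfinite(data.df[cov].to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IterationLimitWarning)
            res = QuantReg(y_all[keep], X[keep]).fit(q=tau)
        pvals = np.asarray(res.pvalues)[1:]
        coefs = np.asarray(res.params)[1:]
        hit = bool(np.any(pvals < alpha))
        if hit:
            retained.append(cov)
        for nm, c, pv in zip(names[1:], coefs, pvals):
            rows.append({"covariate": cov, "coefficient": nm, "estimate": c,
                         "p_value": pv, "retained": hit})
    if return_report:
        return retained, pd.DataFrame(
            rows, columns=["covariate", "coefficient", "estimate",
                           "p_value", "retained"])
    return retained
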