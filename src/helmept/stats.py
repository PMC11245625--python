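"""Cohort-level statistics: regressions, correlations and study design.

Univariate analysis follows the standard two-tailed Pearson scheme: ordinary
least-squares line fit, correlation coefficient r, and a p-value from
t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  Sex enters the models
numerically coded M = 1, F = 0, so a positive coefficient reads as a
male-minus-female difference.  Multivariate follow-up is a Gaussian linear
model with per-coefficient t-tests (statsmodels).  Significance is a strict
p < alpha screen with no multiple-testing correction by default; a
Benjamini-Hochberg option exists but is off, matching the single-threshold
practice of small exploratory cohorts.  Missing organ values are deleted
pairwise, so per-organ n may differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "encode_sex",
    "univariate",
    "multivariate",
    "predictor_correlation",
    "significance_screen",
    "sample_size",
    "recruit_with_dropout",
    "cohort_regressions",
]


def encode_sex(sex: Iterable) -> np.ndarray:
    """Numeric sex coding: M = 1, F = 0."""
    arr = np.asarray(list(sex))
    out = np.full(arr.shape, np.nan)
    out[arr == "M"] = 1.0
    out[arr == "F"] = 0.0
    bad = set(np.unique(arr)) - {"M", "F"}
    if bad:
        raise ValueError(f"sex values must be 'M' or 'F', got {sorted(bad)}")
    return out


@dataclass
class RegressionResult:
    """Univariate linear fit of organ conductivity against one predictor."""

    organ: str
    predictor: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    x_mean: float = field(repr=False, default=np.nan)
    sxx: float = field(repr=False, default=np.nan)
    resid_var: float = field(repr=False, default=np.nan)

    def confidence_band(self, x_grid, confidence: float = 0.95):
        """Confidence band of the mean prediction along ``x_grid``.

        Returns (fit, lower, upper) arrays for the fitted line.
        """
        x_grid = np.asarray(x_grid, dtype=float)
        fit = self.intercept + self.slope * x_grid
        se = np.sqrt(
            self.resid_var * (1.0 / self.n + (x_grid - self.x_mean) ** 2 / self.sxx)
        )
        tq = sps.t.ppf(0.5 + confidence / 2.0, self.n - 2)
        return fit, fit - tq * se, fit + tq * se


def _paired_finite(y, x):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"y and x must have equal length, got {y.shape} vs {x.shape}")
    keep = np.isfinite(y) & np.isfinite(x)
    return y[keep], x[keep]


def univariate(
    y, x, organ: str = "y", predictor: str = "x"
) -> RegressionResult:
    """OLS line fit and two-tailed Pearson test of y against x.

    Non-finite pairs are deleted pairwise; at least 3 complete pairs and
    nonzero variance in both variables are required.
    """
    y, x = _paired_finite(y, x)
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    resid = y - (intercept + slope * x)
    resid_var = float(np.sum(resid**2) / (n - 2))
    return RegressionResult(
        organ=organ,
        predictor=predictor,
        slope=float(slope),
        intercept=intercept,
        r=float(r),
        p=float(p),
        n=int(n),
        x_mean=float(x.mean()),
        sxx=sxx,
        resid_var=resid_var,
    )


def predictor_correlation(x1, x2) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between two predictors."""
    res = univariate(np.asarray(x2, dtype=float), x1, organ="x2", predictor="x1")
    return res.r, res.p


def multivariate(y, predictors: pd.DataFrame) -> pd.DataFrame:
    """Gaussian linear model of y on several predictors.

    Returns a table (term, coef, se, t, p) including the intercept.  Raises
    on a collinear design, naming the dependent columns.  Meant as the
    follow-up when two or more univariate predictors are significant.
    """
    predictors = pd.DataFrame(predictors)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(predictors.to_numpy(dtype=float)).all(axis=1)
    y = y[keep]
    X = predictors.loc[keep]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} subjects cannot fit {k} predictors plus intercept")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # walk the columns to name the dependent ones
        dependent = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(
                design[:, :j]
            ):
                dependent.append(X.columns[j - 1])
        raise ValueError(f"collinear design: columns {dependent} are linearly dependent")
    fit = sm.OLS(y, design).fit()
    terms = ["intercept", *X.columns]
    return pd.DataFrame(
        {
            "term": terms,
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)


def significance_screen(
    results: Sequence[RegressionResult],
    alpha: float = 0.05,
    method: Optional[str] = None,
) -> list[RegressionResult]:
    """Flag results with p strictly below alpha.

    ``method="bh"`` applies a Benjamini-Hochberg step-up instead; the default
    is the uncorrected per-test threshold.
    """
    results = list(results)
    if not results:
        return []
    if method is None:
        return [res for res in results if res.p < alpha]
    if method == "bh":
        p = np.array([res.p for res in results])
        order = np.argsort(p)
        m = len(p)
        passed = np.zeros(m, dtype=bool)
        max_k = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= alpha * rank / m:
                max_k = rank
        passed[order[:max_k]] = True
        return [res for res, ok in zip(results, passed) if ok]
    raise ValueError(f"unknown method {method!r}")


def sample_size(sd: float, margin: float, confidence: float = 0.95) -> int:
    """Subjects needed so the CI half-width of a mean is within ``margin``.

    n = ceil((z * sd / margin)^2) with the two-sided normal quantile z.
    With sd = 0.3 S/m, margin = 0.16 S/m and 95% confidence this gives 14.
    """
    if sd <= 0 or margin <= 0:
        raise ValueError("sd and margin must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    return int(math.ceil((z * sd / margin) ** 2))


def recruit_with_dropout(n_min: int, dropout_rate: float) -> int:
    """Recruitment target inflating ``n_min`` for an expected dropout rate."""
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout rate must lie in [0, 1)")
    if n_min < 1:
        raise ValueError("n_min must be a positive integer")
    return int(math.ceil(n_min / (1.0 - dropout_rate)))


def cohort_regressions(
    table: pd.DataFrame,
    organs: Optional[Sequence[str]] = None,
    predictors: Sequence[str] = ("age", "fvf", "bmi", "sex"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate regression sweep of organ median conductivity on predictors.

    ``table`` follows the cohort CSV layout (``age, sex, bmi`` plus
    ``<organ>_sigma`` and optional ``<organ>_fvf`` columns).  Returns one row
    per organ x predictor with slope, r, p, n and a significance flag.
    """
    if organs is None:
        organs = sorted(
            c[: -len("_sigma")] for c in table.columns if c.endswith("_sigma")
        )
    rows = []
    for organ in organs:
        y = table[f"{organ}_sigma"].to_numpy(dtype=float)
        for pred in predictors:
            if pred == "sex":
                x = encode_sex(table["sex"])
            elif pred == "fvf":
                col = f"{organ}_fvf"
                if col not in table.columns:
                    continue
                x = table[col].to_numpy(dtype=float)
            else:
                x = table[pred].to_numpy(dtype=float)
            try:
                res = univariate(y, x, organ=organ, predictor=pred)
            except ValueError:
                continue  # e.g. single-sex cohort: predictor has no variance
            rows.append(
                {
                    "organ": organ,
                    "predictor": pred,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "significant": res.p < alpha,
                }
            )
    return pd.DataFrame(rows)
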