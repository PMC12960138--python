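"""Group comparisons of module/CNFC scores.

Welch's unequal-variance t-test for two-group contrasts (e.g. noise vs
control within a GeoMx segment), ordinary least squares for covariate-
adjusted contrasts (score ~ group + age), Pearson correlation for panel and
benchmark agreement, and a signature-vs-module correlation screen to flag
potential cell-composition confounding. All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import ExpressionMatrix
from .registry import ModulePanel, map_panel
from .scoring import ModuleScoreTable, score_modules


@dataclass
class GroupTestResult:
    delta: float    # mean(b) - mean(a); caller names the roles
    t: float
    df: float
    p: float
    n_a: int
    n_b: int


@dataclass
class LinearModelResult:
    coef: pd.DataFrame      # rows: term; columns beta, se, t, p
    residual_df: int
    formula: str


def welch_test(a: np.ndarray, b: np.ndarray) -> GroupTestResult:
    """Welch's t-test of b vs a with Satterthwaite degrees of freedom.

    ``delta`` is mean(b) - mean(a). When both groups are constant the
    statistic is undefined and reported as NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    delta = float(b.mean() - a.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return GroupTestResult(delta, float("nan"), float("nan"), float("nan"),
                               a.size, b.size)
    res = stats.ttest_ind(a, b, equal_var=False)
    # scipy reports t for a - b; flip so sign matches delta = b - a
    return GroupTestResult(delta, float(-res.statistic), float(res.df),
                           float(res.pvalue), a.size, b.size)


def fit_linear_model(
    y: pd.Series,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> LinearModelResult:
    """OLS of score on a 0/1 group indicator plus numeric covariates.

    Ages enter as plain numbers (P32 -> 32). Rank deficiency raises, naming
    the collinear columns.
    """
    X = pd.DataFrame({"group": np.asarray(group, dtype=float)}, index=y.index)
    terms = ["group"]
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates[c].astype(float)
            terms.append(c)
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        seen = X.iloc[:, :1].to_numpy()
        for c in X.columns[1:]:
            cand = np.column_stack([seen, X[c].to_numpy()])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(seen):
                bad.append(c)
            else:
                seen = cand
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    if len(y) <= X.shape[1]:
        raise ValueError("need more samples than coefficients")
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    coef = pd.DataFrame({
        "beta": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    })
    formula = "score ~ " + " + ".join(terms)
    return LinearModelResult(coef=coef, residual_df=int(fit.df_resid), formula=formula)


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pearson r with the t-transform p-value (n - 2 df).

    Returns ``(nan, n, nan)`` for n < 3 or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), n, float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), n, float(res.pvalue)


def signature_module_association(
    z: ExpressionMatrix,
    signatures: ModulePanel,
    module_scores: ModuleScoreTable,
    flag_threshold: float = 0.8,
    min_mapped: int = 3,
) -> pd.DataFrame:
    """Correlate cell-type signature scores with module scores across samples.

    Signature scores are computed with the same mean-z mechanics as module
    scores. Rows where |r| exceeds ``flag_threshold`` are flagged: a module
    trajectory that tracks a composition signature that tightly could reflect
    changing cell makeup rather than per-cell state (report-only, no action
    taken).
    """
    mapped = map_panel(signatures, z, min_mapped=min_mapped)
    sig_scores = score_modules(z, mapped).scores
    rows = []
    for sig in sig_scores.columns:
        for mod in module_scores.scores.columns:
            r, n, p = correlate(sig_scores[sig].to_numpy(),
                                module_scores.scores[mod].to_numpy())
            rows.append(dict(signature=sig, module=mod, r=r, n=n, p=p,
                             flagged=bool(np.isfinite(r) and abs(r) >= flag_threshold)))
    return pd.DataFrame(rows)
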