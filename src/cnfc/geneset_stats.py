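"""Module-level summaries over a differential-expression table.

Three statistics summarise how a gene set moves as a unit: the arithmetic
mean log2 fold change over mapped genes; a directional Stouffer combination
of the signed per-gene Wald z statistics, Z = sum(z_g) / sqrt(n), whose tail
probability is computed in log space (set-level p-values of order 1e-100+
arise routinely when many genes move coherently); and Cohen's d for
score-level group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSetResult:
    name: str
    n_mapped: int
    mean_log2fc: float
    stouffer_z: float
    stouffer_p: float          # two-sided
    stouffer_log10_p: float
    stouffer_p_one_sided: float
    genes: list[str]


def module_mean_log2fc(de: pd.DataFrame, genes: "list[str] | set[str]") -> tuple[float, int]:
    """Mean log2FC over set genes present in ``de`` with non-missing estimates.

    Duplicate gene entries are collapsed first. Returns ``(nan, 0)`` when no
    gene maps.
    """
    hits = [g for g in dict.fromkeys(genes) if g in de.index]
    vals = de.loc[hits, "log2fc"].dropna()
    if vals.empty:
        return float("nan"), 0
    return float(vals.mean()), int(len(vals))


def stouffer_directional(
    de: pd.DataFrame,
    genes: "list[str] | set[str]",
    transform: str = "wald_z",
) -> tuple[float, float, float]:
    """Directional Stouffer combination of per-gene evidence.

    ``transform="wald_z"`` (default) combines the signed Wald z statistics
    directly; ``transform="p_sign"`` rebuilds z_g = Phi^-1(1 - p_g/2) *
    sign(log2fc_g) from each gene's two-sided p — identical when the p's come
    from the same normal Wald z, but usable with externally supplied tables.
    Returns (Z, two-sided p, log10 of the two-sided p).
    """
    hits = [g for g in dict.fromkeys(genes) if g in de.index]
    if transform == "wald_z":
        z = de.loc[hits, "wald_z"].dropna().to_numpy()
    elif transform == "p_sign":
        sub = de.loc[hits, ["p", "log2fc"]].dropna()
        z = stats.norm.isf(sub["p"].to_numpy() / 2.0) * np.sign(sub["log2fc"].to_numpy())
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if z.size == 0:
        return float("nan"), float("nan"), float("nan")
    Z = float(z.sum() / np.sqrt(z.size))
    log_p = np.log(2.0) + stats.norm.logsf(abs(Z))
    log_p = min(log_p, 0.0)
    return Z, float(np.exp(log_p)), float(log_p / np.log(10.0))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (b - a) / pooled SD.

    Pooled SD uses the (n_a + n_b - 2)-denominator two-sample form. Undefined
    (NaN) when the pooled SD is zero or either group has fewer than 2 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return float("nan")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((b.mean() - a.mean()) / np.sqrt(pooled_var))


def summarize_gene_sets(de: pd.DataFrame, panel) -> pd.DataFrame:
    """GeneSetResult rows for every module of a panel against one DE table."""
    rows = []
    for mod in panel:
        mean_fc, n = module_mean_log2fc(de, mod.genes)
        Z, p2, lp = stouffer_directional(de, mod.genes)
        p1 = float(np.exp(stats.norm.logsf(abs(Z)))) if np.isfinite(Z) else float("nan")
        rows.append(dict(module=mod.name, n_mapped=n, mean_log2fc=mean_fc,
                         stouffer_z=Z, stouffer_p=p2, stouffer_log10_p=lp,
                         stouffer_p_one_sided=p1))
    return pd.DataFrame(rows).set_index("module")
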