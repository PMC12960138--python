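"""Transcriptome-wide PCA benchmark for the CNFC composite.

The curated composite is validated against an unsupervised summary: PCA of
log2(CPM+1) expression after dropping low-variance genes. PC1 is treated as
the dominant transcriptional axis (a maturity axis in developmental data);
its correlation with CNFC, and the OLS weights obtained by regressing PC1 on
standardized module scores, quantify how much of that axis the curated
modules capture and whether equal module weighting is a reasonable choice.

PCA here is covariance PCA over samples: genes are mean-centered (no
unit-variance scaling, since inputs are already on a common log scale) and
components are computed across samples. The sign of a principal component is
arbitrary; :func:`align_pc_sign` pins it against a reference score so that
"CNFC correlates positively with PC1" is a stable statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_io import ExpressionMatrix
from .registry import COMPOSITE_ROLES
from .scoring import ModuleScoreTable, compute_cnfc


@dataclass
class PCAResult:
    variance_fraction: np.ndarray       # per component, sums to 1
    scores: pd.DataFrame                # samples x components ("PC1", ...)
    n_genes_used: int
    flipped: dict[str, bool] = field(default_factory=dict)


@dataclass
class ModuleWeights:
    weights: pd.Series      # per module name (includes plasticity, reported only)
    intercept: float
    r_squared: float


def run_pca(logm: ExpressionMatrix, variance_quantile: float = 0.25) -> PCAResult:
    """Covariance PCA over samples after a gene variance filter.

    Drops the lowest ``variance_quantile`` fraction of genes by variance,
    centers each gene, and computes all ``n_samples - 1`` components.
    """
    if logm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 0 <= variance_quantile < 1:
        raise ValueError("variance_quantile must be in [0, 1)")
    var = logm.values.var(axis=1, ddof=1)
    cutoff = var.quantile(variance_quantile)
    keep = var > cutoff if variance_quantile > 0 else var >= 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive the variance filter")
    X = logm.values.loc[keep].to_numpy().T      # samples x genes; PCA centers genes
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        variance_fraction=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=logm.values.columns, columns=cols),
        n_genes_used=int(keep.sum()),
    )


def align_pc_sign(
    result: PCAResult,
    reference: pd.Series,
    component: str = "PC1",
) -> PCAResult:
    """Flip a component so it correlates non-negatively with a reference score.

    The reference defaults in practice to the excitability module score.
    A zero-variance reference leaves the component untouched (flip recorded
    as False). Applying twice is a no-op.
    """
    ref = reference.reindex(result.scores.index).to_numpy(dtype=float)
    pc = result.scores[component].to_numpy()
    if np.std(ref) == 0 or np.std(pc) == 0:
        result.flipped.setdefault(component, False)
        return result
    r = np.corrcoef(ref, pc)[0, 1]
    if r < 0:
        result.scores[component] = -result.scores[component]
        result.flipped[component] = not result.flipped.get(component, False)
    else:
        result.flipped.setdefault(component, False)
    return result


def regress_module_weights(
    pc1: pd.Series,
    table: ModuleScoreTable,
    standardize: bool = True,
) -> ModuleWeights:
    """OLS weights for predicting PC1 from module scores.

    Module scores are standardized across samples first (so weights are
    comparable across modules); raw OLS coefficients are reported without
    normalization. All modules — plasticity included — enter the regression;
    only the composite roles are later used for a weighted CNFC.
    """
    S = table.scores.loc[pc1.index].copy()
    if S.isna().any().any():
        raise ValueError("module scores contain missing values")
    if len(pc1) <= S.shape[1] + 1:
        raise ValueError("need n > number of modules + 1 samples")
    if standardize:
        sd = S.std(ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant module score(s): {list(sd.index[sd == 0])}")
        S = (S - S.mean()) / sd
    X = np.column_stack([np.ones(len(S)), S.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear module scores; weight regression is unidentified")
    coef, *_ = np.linalg.lstsq(X, pc1.to_numpy(dtype=float), rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((pc1.to_numpy() - fitted) ** 2))
    ss_tot = float(np.sum((pc1.to_numpy() - pc1.mean()) ** 2))
    return ModuleWeights(
        weights=pd.Series(coef[1:], index=S.columns),
        intercept=float(coef[0]),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
    )


def weighted_cnfc(table: ModuleScoreTable, weights: ModuleWeights) -> ModuleScoreTable:
    """CNFC recomputed with data-driven per-role weight magnitudes.

    The regression coefficient for each composite role is mapped to a weight
    magnitude; the composite formula keeps its fixed signs (+E +T -I), so the
    coefficients' absolute values are used. Plasticity's coefficient is
    reported by the regression but excluded here by construction.
    """
    role_w = {}
    for name, w in weights.weights.items():
        role = table.role_of.get(name, name)
        if role in COMPOSITE_ROLES:
            role_w[role] = abs(float(w))
    return compute_cnfc(table, weights=role_w)
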