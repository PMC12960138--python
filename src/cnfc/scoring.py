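"""Module scoring and the CNFC composite.

The scoring procedure is deliberately simple and platform-agnostic:

1. normalize/log-transform as appropriate for the platform (``data_io``);
2. standardize each gene across samples within the dataset (z-score),
   optionally within metadata strata (e.g. FACS fraction or GeoMx segment);
3. a module score is the per-sample mean z over the module's genes mapped
   into the matrix;
4. the composite CNFC score is

       CNFC = w_E * excitability + w_T * trophic_metabolic - w_I * injury_inflammation

   with unit weights by default. Plasticity is reported alongside but never
   enters the composite: it can reflect either developmental consolidation or
   injury-driven regrowth, so its sign is context-dependent.

Median log2(CPM+1) module expression and stage fold-change summaries support
validation plots and descriptive tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .registry import COMPOSITE_ROLES, MappedPanel

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {"excitability": 1.0, "trophic_metabolic": 1.0, "injury_inflammation": 1.0}


@dataclass
class ModuleScoreTable:
    """Per-sample module scores and, optionally, the CNFC composite.

    ``scores`` has one row per sample and one column per module (NaN where a
    module mapped too few genes); ``cnfc`` is a per-sample Series aligned to
    the same samples, NaN wherever a required composite module is missing.
    """

    scores: pd.DataFrame
    cnfc: pd.Series | None = None
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    role_of: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        if self.cnfc is not None:
            out["cnfc"] = self.cnfc
        return out.rename_axis("sample")


def zscore_genes(
    m: ExpressionMatrix,
    group_by: str | None = None,
    ddof: int = 1,
) -> ExpressionMatrix:
    """Standardize each gene to mean 0, SD 1 across samples.

    With ``group_by``, standardization is done separately within each level of
    that metadata column (e.g. within each GeoMx segment type), so scores
    compare samples only to their own stratum. The SD uses the sample
    (n-1) denominator by default. Zero-variance genes are set to all-zero and
    counted in a log message instead of producing NaN/inf.
    """
    if m.scale == "counts":
        logger.warning("z-scoring raw counts; normalize/log-transform first for real data")
    if group_by is None:
        groups = {None: m.values.columns}
    else:
        if group_by not in m.meta.columns:
            raise KeyError(f"metadata column {group_by!r} not found")
        groups = {
            level: m.meta.index[m.meta[group_by] == level]
            for level in m.meta[group_by].unique()
        }
    out = m.values.astype(float).copy()
    n_flat = 0
    for level, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(
                f"group {level!r} has a single sample; SD is undefined"
            )
        block = m.values[samples]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=ddof)
        flat = sd == 0
        n_flat += int(flat.sum())
        sd = sd.where(~flat, 1.0)  # neutral: zero-variance rows become all-zero
        out[samples] = block.sub(mu, axis=0).div(sd, axis=0)
    if n_flat:
        logger.info("zscore_genes: %d zero-variance gene/group blocks set to 0", n_flat)
    return m.with_values(out, scale="zscore")


def score_modules(
    z: ExpressionMatrix,
    mapped: MappedPanel,
    min_mapped: int | None = None,
) -> ModuleScoreTable:
    """Per-sample mean z-score over each module's mapped genes.

    Modules with fewer than ``min_mapped`` genes in the matrix get NaN
    scores (reported missing, never silently imputed).
    """
    if z.scale != "zscore":
        raise ValueError(f"score_modules expects a z-scored matrix (got {z.scale!r})")
    threshold = mapped.min_mapped if min_mapped is None else min_mapped
    cols = {}
    role_of = {}
    for mod in mapped:
        role_of[mod.name] = mod.role
        if len(mod.genes) < threshold:
            cols[mod.name] = pd.Series(np.nan, index=z.values.columns)
        else:
            cols[mod.name] = z.values.loc[mod.genes].mean(axis=0)
    scores = pd.DataFrame(cols, index=z.values.columns)
    return ModuleScoreTable(scores=scores, role_of=role_of)


def compute_cnfc(
    table: ModuleScoreTable,
    weights: dict[str, float] | None = None,
) -> ModuleScoreTable:
    """Attach the CNFC composite: w_E*E + w_T*T - w_I*I per sample.

    Weights are magnitudes per role — the minus sign on injury/inflammation is
    carried by the formula, so negative weights are rejected. The composite is
    NaN for samples where any required module score is missing. Multiple
    modules sharing a composite role are averaged within the role first.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be non-negative; the formula carries the sign")
    role_cols: dict[str, list[str]] = {r: [] for r in COMPOSITE_ROLES}
    for name, role in table.role_of.items():
        if role in role_cols:
            role_cols[role].append(name)
    missing_roles = [r for r, cols in role_cols.items() if not cols]
    if missing_roles:
        raise ValueError(f"composite requires modules with roles {missing_roles}")
    role_score = {r: table.scores[cols].mean(axis=1, skipna=False) for r, cols in role_cols.items()}
    cnfc = (
        w["excitability"] * role_score["excitability"]
        + w["trophic_metabolic"] * role_score["trophic_metabolic"]
        - w["injury_inflammation"] * role_score["injury_inflammation"]
    )
    return ModuleScoreTable(scores=table.scores, cnfc=cnfc, weights=w, role_of=table.role_of)


def median_module_expression(logm: ExpressionMatrix, mapped: MappedPanel) -> pd.DataFrame:
    """Per-sample median expression over each module's genes.

    Intended for raw-scale validation plots on log2(CPM+1) (or log-intensity)
    values; the composite itself always uses mean-z scores.
    """
    if logm.scale not in ("log2cpm", "log_intensity"):
        raise ValueError(f"median_module_expression expects a log-scale matrix (got {logm.scale!r})")
    cols = {}
    for mod in mapped:
        if not mod.genes:
            cols[mod.name] = pd.Series(np.nan, index=logm.values.columns)
        else:
            cols[mod.name] = logm.values.loc[mod.genes].median(axis=0)
    return pd.DataFrame(cols, index=logm.values.columns)


def panel_agreement(full_cnfc: pd.Series, minimal_cnfc: pd.Series) -> tuple[float, int]:
    """Pearson correlation between full-panel and minimal-panel CNFC.

    Returns ``(r, n)`` over samples where both scores are defined; ``r`` is
    NaN when either vector is constant or fewer than 3 samples overlap.
    """
    joined = pd.concat([full_cnfc, minimal_cnfc], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3 or joined.iloc[:, 0].std() == 0 or joined.iloc[:, 1].std() == 0:
        return float("nan"), n
    r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
    return r, n


def stage_fold_change(
    m: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    group: str | None = None,
    stage_key: str = "stage",
    group_key: str = "group",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene ratio of stage-B to stage-A expression within one group.

    Values are averaged across replicates within each stage before the ratio
    is taken. Ratios are computed on unrounded values; the ``ratio_2dp``
    column carries the 2-decimal presentation. Genes with zero stage-A
    expression get an undefined (NaN) ratio and an ``undefined`` flag.
    """
    if m.scale == "zscore":
        raise ValueError("fold changes need a linear/normalized scale, not z-scores")
    meta = m.meta
    if stage_key not in meta.columns:
        raise KeyError(f"metadata column {stage_key!r} not found")
    mask = pd.Series(True, index=meta.index)
    if group is not None:
        if group_key not in meta.columns:
            raise KeyError(f"metadata column {group_key!r} not found")
        mask &= meta[group_key] == group
    samples_a = meta.index[mask & (meta[stage_key] == stage_a)]
    samples_b = meta.index[mask & (meta[stage_key] == stage_b)]
    if not len(samples_a) or not len(samples_b):
        raise ValueError(f"stage {stage_a!r} or {stage_b!r} absent in group {group!r}")
    sub = m.values.loc[genes] if genes is not None else m.values
    va = sub[samples_a].mean(axis=1)
    vb = sub[samples_b].mean(axis=1)
    ratio = vb / va.where(va > 0)
    out = pd.DataFrame({
        f"value_{stage_a}": va,
        f"value_{stage_b}": vb,
        "ratio": ratio,
        "ratio_2dp": ratio.round(2),
        "undefined": va <= 0,
    })
    return out.rename_axis("gene")
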