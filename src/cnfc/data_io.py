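"""Reading, normalizing and filtering expression matrices.

The central container is :class:`ExpressionMatrix`: a gene-by-sample numeric
table tagged with the scale its values live on (raw counts, CPM, log2 CPM,
microarray log-intensity, or per-gene z-scores) plus optional per-sample
metadata (group, developmental stage, FACS fraction, segment, age).

All downstream stages — module scoring, differential expression, PCA — accept
this container and check the scale tag, so a counts matrix cannot silently be
z-scored or a z-score matrix CPM-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised value scales, roughly in pipeline order.
SCALES = ("counts", "cpm", "log2cpm", "log_intensity", "zscore")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a scale tag and sample metadata.

    Parameters
    ----------
    values
        DataFrame with unique gene symbols (or probe ids) as the index and
        unique sample ids as columns. No missing entries are allowed.
    scale
        One of :data:`SCALES`.
    meta
        Optional per-sample attributes (group, stage, fraction, segment,
        age, ...), indexed by sample id.
    """

    values: pd.DataFrame
    scale: str
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups[:5]}")
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}; imputation is refused"
            )
        if self.scale in ("counts", "cpm") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values are not allowed on scale {self.scale!r}")
        if len(self.meta) and not self.meta.index.equals(self.values.columns):
            # allow any order but require the same sample set
            if set(self.meta.index) != set(self.values.columns):
                raise ValueError("metadata sample ids do not match matrix columns")
            self.meta = self.meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a copy holding ``values`` (and optionally a new scale tag)."""
        return ExpressionMatrix(values=values, scale=scale or self.scale, meta=self.meta)


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_in_rows",
    scale: str = "counts",
    sep: str | None = None,
    id_column: str | int = 0,
    meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample (or sample-by-gene) table.

    ``sep=None`` sniffs tab vs comma from the file extension
    (``.csv`` → comma, anything else → tab). gzip is handled transparently
    by pandas. Non-numeric cells raise with the offending row/column.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "genes_in_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if ".csv" in path.suffixes or path.suffix == ".csv" else "\t"
    # pandas silently mangles duplicate header names; inspect the raw header
    import gzip
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        cols = fh.readline().rstrip("\r\n").split(sep)
    dups = sorted({c for c in cols if cols.count(c) > 1})
    if dups:
        raise ValueError(f"duplicated sample ids in header: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=id_column)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "genes_in_cols":
        df = df.T
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise ValueError(f"non-numeric cell in sample {col!r} at gene {where!r}")
    m = ExpressionMatrix(values=df.astype(float), scale=scale,
                         meta=meta if meta is not None else pd.DataFrame())
    logger.info("read %s: %d genes x %d samples (scale=%s)", path.name, *m.shape, scale)
    return m


def write_expression_table(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the matrix genes-in-rows with the gene column named 'gene'."""
    m.values.rename_axis("gene").to_csv(path, sep=sep)


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to counts-per-million (column sums of 1e6).

    A sample with zero total counts cannot be normalized and raises,
    naming the sample.
    """
    if m.scale not in ("counts", "cpm"):
        raise ValueError(f"cpm_normalize expects counts (got scale={m.scale!r})")
    totals = m.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    return m.with_values(m.values.div(totals, axis=1) * 1e6, scale="cpm")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply log2(x + pseudocount) elementwise and retag the scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("log_transform requires non-negative values")
    new_scale = "log2cpm" if m.scale == "cpm" else "log_intensity"
    return m.with_values(np.log2(m.values + pseudocount), scale=new_scale)


def collapse_probes(m: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene symbols by the per-sample median.

    Probes absent from ``probe_map`` are dropped (count logged). Raises if no
    probe in the matrix is covered by the map.
    """
    keep = [p for p in m.values.index if p in probe_map]
    dropped = m.shape[0] - len(keep)
    if not keep:
        raise ValueError("no probe in the matrix is present in the probe map")
    if dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", dropped)
    sub = m.values.loc[keep]
    symbols = pd.Index([probe_map[p] for p in keep], name=m.values.index.name)
    collapsed = sub.groupby(symbols, sort=False).median()
    return m.with_values(collapsed)


def filter_low_expression(
    m: ExpressionMatrix,
    cpm_threshold: float = 1.0,
    min_samples: int = 2,
    cpm: ExpressionMatrix | None = None,
) -> ExpressionMatrix:
    """Keep genes with CPM strictly above ``cpm_threshold`` in >= ``min_samples`` samples.

    The filter is evaluated on a CPM companion matrix: ``cpm`` if supplied,
    ``m`` itself if already on the CPM scale, else CPM computed from ``m``.
    Strict inequality follows the "CPM > 1" convention; genes exactly at the
    threshold are dropped. Row order of survivors is preserved and values are
    returned unrescaled.
    """
    if cpm is None:
        cpm = m if m.scale == "cpm" else cpm_normalize(m)
    if not cpm.values.index.equals(m.values.index):
        raise ValueError("CPM companion matrix must share the gene index")
    keep = (cpm.values > cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "expression filter removed every gene; check the value scale and threshold"
        )
    logger.info("filter_low_expression: kept %d / %d genes", int(keep.sum()), m.shape[0])
    return m.with_values(m.values.loc[keep])
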