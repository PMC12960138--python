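"""One-shot pipeline runs driven by a config mapping (YAML on disk).

``run_pipeline`` executes the requested stages in a fixed order —
normalize -> score -> de -> geneset -> compare -> pca — writing every
intermediate table under the output directory plus a machine-readable
manifest (effective config echo, seed, per-stage output files and row
counts). Config paths are validated before any stage runs, so a typo fails
fast instead of mid-run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_io import (ExpressionMatrix, cpm_normalize, filter_low_expression,
                      log_transform, read_expression_table, write_expression_table)
from .comparisons import fit_linear_model, welch_test
from .geneset_stats import summarize_gene_sets
from .nbglm import run_de
from .pca_benchmark import align_pc_sign, regress_module_weights, run_pca, weighted_cnfc
from .registry import builtin_minimal_panel, load_panel, map_panel
from .scoring import compute_cnfc, score_modules, zscore_genes

logger = logging.getLogger(__name__)

STAGE_ORDER = ("normalize", "score", "de", "geneset", "compare", "pca")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    matrix: str
    outdir: str
    scale: str = "counts"
    meta: str | None = None
    orientation: str = "genes_in_rows"
    panel: str = "minimal"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    group_by: str | None = None          # z-score stratification key
    case_mode: str = "exact"
    cpm_threshold: float = 1.0
    min_samples: int = 2
    min_mapped: int = 3
    variance_quantile: float = 0.25
    weights: dict = field(default_factory=dict)
    seed: int = 0
    de_group_key: str = "group"
    de_treatment: str | None = None
    de_reference: str | None = None
    compare_group_key: str = "group"
    compare_covariates: list[str] = field(default_factory=list)
    compare_test: str = "welch"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        for label, p in (("matrix", self.matrix), ("meta", self.meta),
                         ("panel", None if self.panel == "minimal" else self.panel)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        if not 0 <= self.variance_quantile < 1:
            raise ValueError("variance_quantile must be in [0, 1)")
        if self.cpm_threshold < 0 or self.min_samples < 1 or self.min_mapped < 1:
            raise ValueError("thresholds out of range")


def _load_inputs(cfg: RunConfig) -> ExpressionMatrix:
    meta = None
    if cfg.meta:
        meta = pd.read_csv(cfg.meta, sep=None, engine="python", index_col=0)
        meta.index = meta.index.astype(str)
    return read_expression_table(cfg.matrix, orientation=cfg.orientation,
                                 scale=cfg.scale, meta=meta)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "stages": {},
    }
    stages = [s for s in STAGE_ORDER if s in cfg.stages]

    m = _load_inputs(cfg)
    panel = builtin_minimal_panel() if cfg.panel == "minimal" else load_panel(cfg.panel)
    logm = m
    counts = m if m.scale == "counts" else None
    scores = None

    def record(stage: str, fname: str, df: pd.DataFrame) -> None:
        path = outdir / fname
        df.to_csv(path, sep="\t")
        manifest["stages"][stage] = {"output": str(path), "rows": int(df.shape[0])}

    for stage in stages:
        try:
            if stage == "normalize":
                if m.scale == "counts":
                    logm = log_transform(cpm_normalize(m))
                elif m.scale == "cpm":
                    logm = log_transform(m)
                record(stage, "normalized.tsv", logm.values.rename_axis("gene"))
            elif stage == "score":
                z = zscore_genes(logm, group_by=cfg.group_by)
                mapped = map_panel(panel, z, case_mode=cfg.case_mode,
                                   min_mapped=cfg.min_mapped)
                scores = compute_cnfc(score_modules(z, mapped), weights=cfg.weights or None)
                record(stage, "scores.tsv", scores.to_frame())
            elif stage == "de":
                if counts is None:
                    raise ValueError("de stage requires a counts-scale input matrix")
                de = run_de(counts, cpm_threshold=cfg.cpm_threshold,
                            min_samples=cfg.min_samples, group_key=cfg.de_group_key,
                            treatment=cfg.de_treatment, reference=cfg.de_reference)
                record(stage, "de.tsv", de)
                manifest["stages"][stage]["common_alpha"] = float(de.attrs["alpha"])
            elif stage == "geneset":
                if "de" not in manifest["stages"]:
                    raise ValueError("geneset stage requires the de stage")
                de = pd.read_csv(manifest["stages"]["de"]["output"], sep="\t",
                                 index_col="gene")
                record(stage, "geneset.tsv", summarize_gene_sets(de, panel))
            elif stage == "compare":
                if scores is None or scores.cnfc is None:
                    raise ValueError("compare stage requires the score stage")
                labels = m.meta[cfg.compare_group_key]
                levels = list(pd.unique(labels))
                if len(levels) != 2:
                    raise ValueError(f"compare needs 2 groups, got {levels}")
                rows = []
                for col in list(scores.scores.columns) + ["cnfc"]:
                    y = scores.cnfc if col == "cnfc" else scores.scores[col]
                    if cfg.compare_test == "welch":
                        r = welch_test(y[labels == levels[0]].to_numpy(),
                                       y[labels == levels[1]].to_numpy())
                        rows.append(dict(score=col, delta=r.delta, stat=r.t,
                                         df=r.df, p=r.p))
                    else:
                        lm = fit_linear_model(
                            y, (labels == levels[1]).astype(float),
                            covariates=m.meta[cfg.compare_covariates]
                            if cfg.compare_covariates else None)
                        g = lm.coef.loc["group"]
                        rows.append(dict(score=col, delta=g["beta"], stat=g["t"],
                                         df=lm.residual_df, p=g["p"]))
                record(stage, "compare.tsv", pd.DataFrame(rows).set_index("score"))
            elif stage == "pca":
                if scores is None:
                    raise ValueError("pca stage requires the score stage")
                pca = run_pca(logm, variance_quantile=cfg.variance_quantile)
                exc_cols = [n for n, r in scores.role_of.items() if r == "excitability"]
                if exc_cols:
                    pca = align_pc_sign(pca, scores.scores[exc_cols[0]])
                report = pca.scores.copy()
                report.insert(0, "cnfc", scores.cnfc)
                record(stage, "pca_report.tsv", report.rename_axis("sample"))
                manifest["stages"][stage]["pc1_variance_fraction"] = float(
                    pca.variance_fraction[0])
                if scores.scores.notna().all().all() and len(report) > scores.scores.shape[1] + 1:
                    w = regress_module_weights(pca.scores["PC1"], scores)
                    manifest["stages"][stage]["module_weights"] = {
                        k: float(v) for k, v in w.weights.items()}
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed on {cfg.matrix} "
                f"({m.shape[0]} genes x {m.shape[1]} samples): {exc}"
            ) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
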