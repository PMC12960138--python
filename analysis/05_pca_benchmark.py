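#!/usr/bin/env python
"""Benchmark the curated CNFC composite against transcriptome-wide PCA.

On the simulated development series: covariance PCA of log2(CPM+1) after a
25% low-variance gene filter, sign-aligned to the excitability score; then
PC1-vs-CNFC correlation, data-driven module weights from regressing PC1 on
standardized module scores, and the weighted-vs-unweighted CNFC agreement.

Requires 01_simulate_datasets.py to have been run first.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnfc import (align_pc_sign, compute_cnfc, correlate, cpm_normalize,
                  log_transform, map_panel, read_expression_table,
                  regress_module_weights, run_pca, score_modules,
                  weighted_cnfc, zscore_genes)
from cnfc.data_io import ExpressionMatrix
from cnfc.registry import load_panel

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> None:
    m = read_expression_table(ROOT / "data" / "development_counts.tsv",
                              scale="counts")
    meta = pd.read_csv(ROOT / "data" / "development_meta.tsv", sep="\t",
                       index_col=0)
    m = ExpressionMatrix(m.values, "counts", meta)
    panel = load_panel(ROOT / "data" / "development_panel.tsv")

    logm = log_transform(cpm_normalize(m))
    z = zscore_genes(logm)
    scores = compute_cnfc(score_modules(z, map_panel(panel, z)))

    pca = run_pca(logm, variance_quantile=0.25)
    pca = align_pc_sign(pca, scores.scores["excitability"])
    print(f"PCA on {pca.n_genes_used} genes: PC1 explains "
          f"{100 * pca.variance_fraction[0]:.1f}% of variance")
    r, n, p = correlate(pca.scores["PC1"].to_numpy(), scores.cnfc.to_numpy())
    print(f"CNFC vs PC1: Pearson r = {r:.3f} (n = {n}, p = {p:.2g})")

    w = regress_module_weights(pca.scores["PC1"], scores)
    print("data-driven module weights (OLS on standardized scores):")
    for name, val in w.weights.items():
        print(f"  {name}: {val:+.2f}")
    wt = weighted_cnfc(scores, w)
    r_w, n_w, _ = correlate(wt.cnfc.to_numpy(), scores.cnfc.to_numpy())
    print(f"weighted vs unweighted CNFC: r = {r_w:.3f}")

    report = pca.scores.copy()
    report.insert(0, "cnfc", scores.cnfc)
    report.insert(1, "cnfc_weighted", wt.cnfc)
    report.rename_axis("sample").to_csv(ROOT / "pca_benchmark.tsv", sep="\t")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
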