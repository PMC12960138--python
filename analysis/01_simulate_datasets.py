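#!/usr/bin/env python
"""Generate the three synthetic study datasets used by the downstream analyses.

Emulated designs: (1) a two-group noise-trauma treatment RNA-seq experiment
(n = 3 per group, NB counts, 12 excitability genes suppressed at log2FC
-2.6); (2) a developmental stage series E16-P7 with rising excitability and
falling plasticity; (3) an inner-vs-outer hair-cell style microarray
(n = 3 vs 4) with IHC-biased trophic genes.

Writes matrices, metadata and generating truth under results/data/.
"""

import argparse
from pathlib import Path

from cnfc import (SyntheticSpec, simulate_counts, simulate_development,
                  simulate_microarray, write_expression_table)
from cnfc.registry import save_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    m, design, truth, panel = simulate_counts(SyntheticSpec(seed=seed))
    write_expression_table(m, OUT / "treatment_counts.tsv")
    m.meta.rename_axis("sample").to_csv(OUT / "treatment_meta.tsv", sep="\t")
    truth.lfc.rename_axis("gene").to_csv(OUT / "treatment_truth.tsv", sep="\t")
    save_panel(panel, OUT / "treatment_panel.tsv")
    print(f"treatment design: {m.shape[0]} genes x {m.shape[1]} samples "
          f"(true excitability log2FC -2.6 on 12 genes, alpha 0.067)")

    m, meta, truth, panel = simulate_development(SyntheticSpec(seed=seed + 1))
    write_expression_table(m, OUT / "development_counts.tsv")
    meta.rename_axis("sample").to_csv(OUT / "development_meta.tsv", sep="\t")
    truth.stage_effect.rename_axis("gene").to_csv(
        OUT / "development_truth.tsv", sep="\t")
    save_panel(panel, OUT / "development_panel.tsv")
    print(f"development design: {m.shape[0]} genes x {m.shape[1]} samples "
          f"across stages E16, P0, P4, P7")

    m, meta, truth, probe_map = simulate_microarray(SyntheticSpec(seed=seed + 2))
    write_expression_table(m, OUT / "microarray_intensities.tsv")
    meta.rename_axis("sample").to_csv(OUT / "microarray_meta.tsv", sep="\t")
    print(f"microarray design: {m.shape[0]} genes x {m.shape[1]} samples "
          f"(IHC-shifted trophic genes: Ntf3, Gdnf)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
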