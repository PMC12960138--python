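# cnfc — Cochlear Neural Functional Competence scoring

`cnfc` is a Python toolkit for summarising the *functional state* of cochlear
neural tissue from transcriptomic data. Cochlear implant outcomes correlate
only loosely with how many spiral ganglion neurons survive; what may matter
more is whether the surviving tissue retains the transcriptional programs for
fast firing, synaptic transmission, trophic/metabolic support — and how much
injury/inflammation signalling is active. `cnfc` turns that idea into a
reproducible pipeline for anyone analysing cochlear (or other neural) bulk
RNA-seq, microarray, or targeted-panel expression tables.

## The score

Gene expression is normalized per platform (CPM + log2 for RNA-seq,
log-intensity for arrays), standardized per gene within the dataset
(z-score across samples, optionally within strata such as GeoMx segment
types), and averaged over curated gene modules. Four modules are tracked —
excitability/synaptic transmission (E), cytoskeletal plasticity (P),
trophic/metabolic support (T) and injury/inflammation (I) — and composed as

```
CNFC = w_E · E + w_T · T − w_I · I        (w = 1 by default)
```

Plasticity is reported as an independent axis: it rises both in development
and after injury, so its sign is context-dependent and it never enters the
composite. A built-in minimal 24-gene panel (6 E, 5 P, 7 T, 6 I genes) ships
with the package; full module lists are user-supplied (GMT or TSV).

Around the score the package provides:

- a gene-wise **negative-binomial GLM** differential-expression engine
  (log link, library-size offset, one common method-of-moments dispersion
  `α` with `Var = μ + αμ²`, Wald tests in log space, BH FDR);
- **directional gene-set statistics** (mean log2FC, signed Stouffer
  `Z = Σz_g/√n`, Cohen's d);
- **group comparisons** (Welch's t, OLS with covariates such as age,
  Pearson correlation, composition-confounding screens);
- a **PCA benchmark** (variance explained, CNFC-vs-PC1 correlation,
  regression-derived module weights, weighted CNFC);
- **synthetic-data generators** reproducing the study designs the pipeline
  assumes (two-group NB counts at n = 3/group, monotone developmental stage
  series, Gaussian microarray contrasts), with the generating truth retained
  for recovery testing.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic data
(writes under `results/`):

```bash
python analysis/01_simulate_datasets.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_module_scoring.py
python analysis/05_pca_benchmark.py
```

which prints, among other things:

```
fitted 2000 genes; common MoM dispersion alpha = 0.0503
excitability module: mean log2FC = -2.69 over 12 genes; directional Stouffer Z = -28.4 (log10 p = -177.1)
recovery error vs generating log2FC -2.60: -0.095
CNFC stage means (full panel): E16=-1.39, P0=-0.65, P4=+0.44, P7=+1.60
monotone increase: True
full vs minimal 24-gene panel CNFC agreement: r = 0.913 (n=12)
CNFC vs PC1: Pearson r = 0.971 (n = 12, p = 1.5e-07)
weighted vs unweighted CNFC: r = 0.993
```

Reading this: the DE engine recovers the simulated suppression of the
excitability module (true log2FC −2.6, estimated −2.69 over the 12 designated
genes) with overwhelming set-level evidence; on the developmental series the
CNFC composite rises monotonically from E16 to P7; the compact 24-gene panel
tracks the full panel (r = 0.91); and the composite aligns with the dominant
unsupervised transcriptome axis (r = 0.97 with PC1), essentially unchanged
under data-driven module weights.

The same steps are available as a CLI for real expression tables:

```bash
cnfc normalize --in counts.tsv --scale counts --cpm --log2 --out norm.tsv
cnfc score --matrix norm.tsv --meta meta.tsv --panel minimal --out scores.tsv
cnfc de --matrix counts.tsv --meta meta.tsv --group group --ref control --out de.tsv
cnfc run --config run.yaml          # normalize -> score -> de -> geneset -> compare -> pca
```

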