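"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators emulate the study designs the analysis is built around,
so every stage is testable without any download:

* :func:`simulate_counts` — a two-group bulk RNA-seq experiment with n = 3
  per group: negative-binomial counts (variance mu + alpha*mu^2), log-normal
  library sizes, and group effects concentrated on designated module genes
  (default: 12 excitability genes at log2FC −2.6, with smaller plasticity and
  trophic shifts, mirroring the magnitudes a treated-vs-untreated noise-trauma
  cochlea contrast produces).
* :func:`simulate_development` — a stage series (E16, P0, P4, P7) with
  monotone per-module trajectories on the log2 scale: excitability rising,
  plasticity falling, trophic/metabolic high and stable, injury/inflammation
  low and flat — the qualitative pattern of cochlear neural maturation.
* :func:`simulate_microarray` — Gaussian log-intensities for an
  inner-vs-outer hair-cell style contrast (n = 3 vs 4), with designated
  trophic genes shifted in one group and optional probe-level emission to
  exercise probe collapsing.

Every generator returns the emitted matrix plus a :class:`SyntheticTruth`
carrying the generating parameters (true log2FCs or stage effects, library
sizes, dispersion), so recovery tests can compare estimates against truth.
One seed governs all draws; substreams are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .nbglm import Design
from .registry import GeneModule, ModulePanel, builtin_minimal_panel

DEV_STAGES = ("E16", "P0", "P4", "P7")

# per-role log2 effects per stage step (development preset)
DEV_STEP_LFC = {
    "excitability": 0.8,
    "plasticity": -0.8,
    "trophic_metabolic": 0.1,
    "injury_inflammation": 0.0,
}

# treatment-design true module log2FCs (treated vs reference)
TREATMENT_LFC = {
    "excitability": -2.6,
    "plasticity": -0.83,
    "trophic_metabolic": -0.58,
    "injury_inflammation": 0.0,
}


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the study conditions under test."""

    n_genes: int = 2000
    n_per_group: int = 3
    module_lfc: dict[str, float] = field(default_factory=lambda: dict(TREATMENT_LFC))
    module_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "excitability": 12, "plasticity": 8,
            "trophic_metabolic": 7, "injury_inflammation": 6,
        }
    )
    alpha_true: float = 0.067
    libsize_meanlog: float = 0.0      # library factors centred at 1
    libsize_sdlog: float = 0.3
    baseline_meanlog: float = np.log(100.0)
    baseline_sdlog: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be >= 0")
        if self.libsize_sdlog < 0 or self.baseline_sdlog < 0:
            raise ValueError("log-normal sd parameters must be >= 0")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ValueError("module genes exceed the gene universe")


@dataclass
class SyntheticTruth:
    """Generating parameters aligned to the emitted matrix."""

    lfc: pd.Series                  # per-gene true log2FC (or 0)
    library_factor: pd.Series       # per-sample relative library size
    alpha_true: float
    spec: SyntheticSpec
    module_of: pd.Series | None = None
    stage_effect: pd.DataFrame | None = None   # gene x stage log2 effects


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, variance mu + alpha mu^2) counts; exact Poisson when alpha=0."""
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def _assign_modules(spec: SyntheticSpec) -> tuple[list[str], pd.Series, ModulePanel]:
    """Gene universe with role-prefixed module genes first, background after."""
    genes: list[str] = []
    module_of = {}
    modules = []
    for role, size in spec.module_sizes.items():
        names = [f"{role[:4]}_{i + 1:02d}" for i in range(size)]
        modules.append(GeneModule(name=role, genes=list(names), role=role))
        for g in names:
            module_of[g] = role
        genes.extend(names)
    genes.extend(f"gene_{i + 1:05d}" for i in range(spec.n_genes - len(genes)))
    module_series = pd.Series({g: module_of.get(g, "") for g in genes}, name="module")
    return genes, module_series, ModulePanel(modules, panel_name="synthetic")


def simulate_counts(spec: SyntheticSpec) -> tuple[ExpressionMatrix, Design, SyntheticTruth, ModulePanel]:
    """Two-group NB count matrix with module-concentrated group effects."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    genes, module_of, panel = _assign_modules(spec)
    n = 2 * spec.n_per_group
    group = np.repeat([0.0, 1.0], spec.n_per_group)
    samples = [f"{'ref' if g == 0 else 'trt'}_{i % spec.n_per_group + 1}"
               for i, g in enumerate(group)]
    lfc = pd.Series([spec.module_lfc.get(module_of[g], 0.0) if module_of[g] else 0.0
                     for g in genes], index=genes, name="lfc")
    q = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=len(genes))
    L = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, size=n)
    mu = np.outer(q, L) * np.power(2.0, np.outer(lfc.to_numpy(), group))
    counts = _nb_draw(rng, mu, spec.alpha_true)
    values = pd.DataFrame(counts.astype(float), index=genes, columns=samples)
    meta = pd.DataFrame({"group": np.where(group == 1, "treated", "reference")},
                        index=samples)
    m = ExpressionMatrix(values=values, scale="counts", meta=meta)
    design = Design(group=group, offset=np.log(values.sum(axis=0).to_numpy()),
                    sample_ids=samples)
    truth = SyntheticTruth(lfc=lfc, library_factor=pd.Series(L, index=samples),
                           alpha_true=spec.alpha_true, spec=spec, module_of=module_of)
    return m, design, truth, panel


def simulate_development(
    spec: SyntheticSpec,
    stages: tuple[str, ...] = DEV_STAGES,
    step_lfc: dict[str, float] | None = None,
    use_panel_symbols: bool = True,
    n_extra_per_module: int = 12,
    require_monotone: bool = True,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth, ModulePanel]:
    """Stage series with monotone per-module log2 trajectories plus NB noise.

    When ``use_panel_symbols`` is set (the default), each module contains the
    built-in minimal-panel genes *plus* ``n_extra_per_module`` synthetic
    genes sharing the module trajectory — a "full" panel whose minimal subset
    is the built-in 24-gene panel, so full-vs-minimal agreement is testable.
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    steps = dict(DEV_STEP_LFC)
    if step_lfc:
        steps.update(step_lfc)
    if require_monotone:
        # each module trajectory must not change direction across stages
        for role, s in steps.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite stage effect for {role}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    minimal = builtin_minimal_panel()
    modules, module_of, genes = [], {}, []
    for mod in minimal:
        names = list(mod.genes) if use_panel_symbols else []
        names += [f"{mod.role[:4]}_x{i + 1:02d}" for i in range(n_extra_per_module)]
        modules.append(GeneModule(name=mod.name, genes=list(names), role=mod.role))
        for g in names:
            module_of[g] = mod.role
        genes.extend(names)
    genes.extend(f"gene_{i + 1:05d}" for i in range(max(0, spec.n_genes - len(genes))))
    panel = ModulePanel(modules, panel_name="synthetic_full")
    module_series = pd.Series({g: module_of.get(g, "") for g in genes}, name="module")

    n_stage = spec.n_per_group
    samples, stage_labels = [], []
    for s in stages:
        for i in range(n_stage):
            samples.append(f"{s}_{i + 1}")
            stage_labels.append(s)
    stage_idx = np.array([stages.index(s) for s in stage_labels], dtype=float)

    effect = pd.DataFrame(0.0, index=genes, columns=list(stages))
    for g in genes:
        role = module_of.get(g)
        if role:
            effect.loc[g] = steps[role] * np.arange(len(stages))
    q = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=len(genes))
    # injury genes start low so the "low and flat" pattern holds on raw scale
    low = module_series.to_numpy() == "injury_inflammation"
    q[low] = q[low] * 0.1
    L = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, size=len(samples))
    per_sample_lfc = effect.to_numpy()[:, stage_idx.astype(int)]
    mu = (q[:, None] * L[None, :]) * np.power(2.0, per_sample_lfc)
    counts = _nb_draw(rng, mu, spec.alpha_true)
    values = pd.DataFrame(counts.astype(float), index=genes, columns=samples)
    meta = pd.DataFrame({"stage": stage_labels}, index=samples)
    m = ExpressionMatrix(values=values, scale="counts", meta=meta)
    truth = SyntheticTruth(
        lfc=pd.Series(0.0, index=genes), library_factor=pd.Series(L, index=samples),
        alpha_true=spec.alpha_true, spec=spec, module_of=module_series,
        stage_effect=effect,
    )
    return m, meta, truth, panel


def simulate_microarray(
    spec: SyntheticSpec,
    n_a: int = 3,
    n_b: int = 4,
    group_names: tuple[str, str] = ("IHC", "OHC"),
    shifted_genes: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    probes_per_gene: int = 1,
    probe_noise_sd: float = 0.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth, dict[str, str]]:
    """Gaussian log-intensity matrix with group-shifted designated genes.

    ``shifted_genes`` maps gene -> additive shift in group A (default: the
    trophic genes Ntf3 and Gdnf shifted +2, an inner-hair-cell-biased
    pattern). With ``probes_per_gene > 1`` the matrix is emitted at probe
    level (ids ``<gene>_at1`` ...) together with the probe->gene map, so the
    probe-collapse path can be exercised; ``probe_noise_sd=0`` makes all of a
    gene's probes identical.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    if shifted_genes is None:
        shifted_genes = {"Ntf3": 2.0, "Gdnf": 2.0}
    panel_genes = builtin_minimal_panel().all_genes()
    genes = list(dict.fromkeys(list(shifted_genes) + panel_genes))
    genes += [f"gene_{i + 1:05d}" for i in range(max(0, spec.n_genes - len(genes)))]
    samples = [f"{group_names[0]}_{i + 1}" for i in range(n_a)] + \
              [f"{group_names[1]}_{i + 1}" for i in range(n_b)]
    base = rng.normal(8.0, 1.5, size=len(genes))
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    shift = np.array([shifted_genes.get(g, 0.0) for g in genes])
    vals[:, :n_a] += shift[:, None]
    meta = pd.DataFrame({"group": [group_names[0]] * n_a + [group_names[1]] * n_b},
                        index=samples)
    probe_map: dict[str, str] = {}
    if probes_per_gene > 1:
        rows, index = [], []
        for gi, g in enumerate(genes):
            for k in range(probes_per_gene):
                pid = f"{g}_at{k + 1}"
                probe_map[pid] = g
                rows.append(vals[gi] + rng.normal(0.0, probe_noise_sd, size=len(samples)))
                index.append(pid)
        values = pd.DataFrame(np.array(rows), index=index, columns=samples)
    else:
        probe_map = {g: g for g in genes}
        values = pd.DataFrame(vals, index=genes, columns=samples)
    m = ExpressionMatrix(values=values, scale="log_intensity", meta=meta)
    truth = SyntheticTruth(
        lfc=pd.Series(shift, index=genes, name="shift_groupA"),
        library_factor=pd.Series(1.0, index=samples),
        alpha_true=0.0, spec=spec,
    )
    return m, meta, truth, probe_map
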