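"""Gene-module definitions: built-in minimal panel, file loading, matrix mapping.

A *module* is a curated gene set with a composite role. Four roles enter the
Cochlear Neural Functional Competence (CNFC) composite machinery: excitability
and trophic/metabolic add, injury/inflammation subtracts, and plasticity is
tracked as an independent axis. Three extra roles mark cell-type signatures
(neuronal / supporting / immune) used to probe composition confounding.

The built-in 24-gene minimal panel ships with the package; full module lists
are study-specific and user-supplied via GMT or two/three-column TSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

ROLES = (
    "excitability",
    "plasticity",
    "trophic_metabolic",
    "injury_inflammation",
    "signature_neuronal",
    "signature_supporting",
    "signature_immune",
    "other",
)

#: Roles combined into the CNFC composite (plasticity deliberately absent).
COMPOSITE_ROLES = ("excitability", "trophic_metabolic", "injury_inflammation")

# Minimal reusable CNFC panel: 6 excitability, 5 plasticity,
# 7 trophic/metabolic, 6 injury/inflammation genes (mouse symbols).
_MINIMAL_PANEL: dict[str, tuple[str, list[str]]] = {
    "excitability": (
        "excitability",
        ["Kcnc1", "Scn8a", "Gria1", "Grin2a", "Grin2c", "Snap25"],
    ),
    "plasticity": (
        "plasticity",
        ["Cfl1", "Cfl2", "Hmga2", "Syt4", "Cdk5"],
    ),
    "trophic_metabolic": (
        "trophic_metabolic",
        ["Ntf3", "Gdnf", "Bdnf", "Spp1", "Ntrk2", "Sdhd", "Atp6v1h"],
    ),
    "injury_inflammation": (
        "injury_inflammation",
        ["S100a8", "S100a9", "Ccl3", "Ccl4", "Lcn2", "Mmp9"],
    ),
}


@dataclass
class GeneModule:
    """A named, role-labelled gene set."""

    name: str
    genes: list[str]
    role: str = "other"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.name!r} has no genes")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        seen: dict[str, None] = {}
        dropped = 0
        for g in self.genes:
            if g in seen:
                dropped += 1
            seen[g] = None
        if dropped:
            logger.warning("module %s: %d duplicate gene(s) removed", self.name, dropped)
            self.genes = list(seen)


@dataclass
class ModulePanel:
    """An ordered collection of modules with unique names."""

    modules: list[GeneModule]
    panel_name: str = "panel"

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names within a panel must be unique")

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, name: str) -> GeneModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.modules]

    def all_genes(self) -> list[str]:
        out: dict[str, None] = {}
        for m in self.modules:
            for g in m.genes:
                out[g] = None
        return list(out)


@dataclass
class MappedModule:
    """Intersection of one module with one matrix's gene universe."""

    name: str
    role: str
    genes: list[str]          # mapped genes, in matrix row order
    n_requested: int
    usable: bool


@dataclass
class MappedPanel:
    """Per-module mapped gene lists for a specific expression matrix."""

    modules: list[MappedModule]
    panel_name: str = "panel"
    min_mapped: int = 3

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, name: str) -> MappedModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.modules]


def builtin_minimal_panel() -> ModulePanel:
    """The built-in minimal 24-gene CNFC panel (mouse symbols)."""
    return ModulePanel(
        modules=[GeneModule(name, list(genes), role) for name, (role, genes) in _MINIMAL_PANEL.items()],
        panel_name="minimal24",
    )


def _infer_role(name: str) -> str:
    lowered = name.lower()
    for role in ROLES:
        if role in lowered:
            return role
    aliases = {
        "trophic": "trophic_metabolic", "metabolic": "trophic_metabolic",
        "injury": "injury_inflammation", "inflammation": "injury_inflammation",
        "neuronal": "signature_neuronal", "supporting": "signature_supporting",
        "immune": "signature_immune",
    }
    for key, role in aliases.items():
        if key in lowered:
            return role
    return "other"


def load_panel(path: str | Path, panel_name: str | None = None) -> ModulePanel:
    """Load a panel from GMT or two/three-column (module, gene[, role]) TSV.

    GMT lines are ``name<TAB>description<TAB>gene...``; roles are inferred
    from module names unless an explicit third TSV column provides them.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    modules: list[GeneModule] = []
    if path.suffix.lower() == ".gmt":
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {ln!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            modules.append(GeneModule(name, genes, _infer_role(name)))
    else:
        grouped: dict[str, tuple[list[str], str | None]] = {}
        start = 0
        first = lines[0].split("\t")
        if first[:2] == ["module", "gene"] or first[0].lower() == "module":
            start = 1
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed panel line (need module<TAB>gene): {ln!r}")
            name, gene = parts[0], parts[1]
            role = parts[2] if len(parts) > 2 and parts[2] else None
            if role is not None and role not in ROLES:
                raise ValueError(f"unknown role label {role!r} for module {name!r}")
            genes, prev_role = grouped.setdefault(name, ([], role))
            genes.append(gene)
            if role is not None:
                grouped[name] = (genes, role)
        modules = [
            GeneModule(name, genes, role if role else _infer_role(name))
            for name, (genes, role) in grouped.items()
        ]
    if not modules:
        raise ValueError(f"no modules found in {path}")
    return ModulePanel(modules=modules, panel_name=panel_name or path.stem)


def save_panel(panel: ModulePanel, path: str | Path) -> None:
    """Write a panel as three-column TSV (module, gene, role)."""
    with open(path, "w") as fh:
        fh.write("module\tgene\trole\n")
        for mod in panel:
            for g in mod.genes:
                fh.write(f"{mod.name}\t{g}\t{mod.role}\n")


def _transform_symbol(symbol: str, case_mode: str) -> str:
    if case_mode == "exact":
        return symbol
    if case_mode == "title_case":
        return symbol[:1].upper() + symbol[1:].lower()
    if case_mode == "upper":
        return symbol.upper()
    raise ValueError(f"unknown case_mode {case_mode!r}")


def map_panel(
    panel: ModulePanel,
    m: ExpressionMatrix,
    case_mode: str = "exact",
    min_mapped: int = 3,
) -> MappedPanel:
    """Intersect each module with the matrix genes, in matrix row order.

    ``case_mode`` bridges symbol conventions across species by case
    transformation only (mouse Title case vs upper-case human/rat style);
    no ortholog lookup is attempted. Modules mapping fewer than
    ``min_mapped`` genes are flagged unusable rather than erroring.
    """
    matrix_genes = {_transform_symbol(g, case_mode): g for g in reversed(m.gene_ids)}
    order = {g: i for i, g in enumerate(m.gene_ids)}
    mapped_modules = []
    for mod in panel:
        hits = []
        for g in mod.genes:
            target = matrix_genes.get(_transform_symbol(g, case_mode))
            if target is not None:
                hits.append(target)
        hits = sorted(set(hits), key=order.get)
        usable = len(hits) >= min_mapped
        if not usable:
            logger.warning(
                "module %s maps %d/%d genes (< %d): flagged unusable",
                mod.name, len(hits), len(mod.genes), min_mapped,
            )
        mapped_modules.append(MappedModule(mod.name, mod.role, hits, len(mod.genes), usable))
    return MappedPanel(mapped_modules, panel_name=panel.panel_name, min_mapped=min_mapped)
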