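"""Synthetic class-structured cohorts and toy pathways with known ground truth.

The generator emulates a multi-class expression cohort in which disjoint gene
modules are co-overexpressed in specific sample classes on the log10 scale,
with additive Gaussian noise.  Every downstream stage (map training, spot
detection, differential statistics, spot networks, signal flow) is testable
against the planted structure without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .psf import PathwayGraph

__all__ = [
    "ModuleSpec",
    "CohortDesign",
    "GroundTruth",
    "generate_cohort",
    "generate_toy_pathway",
    "default_design",
    "lymphoma_like_design",
    "TCA_COMPOUNDS",
]

#: Compound order of the packaged toy TCA-like cycle.
TCA_COMPOUNDS = (
    "Oxaloacetate",
    "Citrate",
    "Isocitrate",
    "2-Oxoglutarate",
    "Succinyl-CoA",
    "Succinate",
    "Fumarate",
    "Malate",
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    Parameters
    ----------
    module_id : str
        Identifier recorded in the ground truth.
    n_genes : int
        Number of member genes.
    up_classes : tuple of str
        Classes in which the module is overexpressed.
    effect : float
        Additive overexpression, log10 units (1.0 = ten-fold).
    """

    module_id: str
    n_genes: int
    up_classes: tuple[str, ...]
    effect: float = 1.0


@dataclass
class CohortDesign:
    """Design of a synthetic cohort: classes, planted modules, noise level."""

    n_genes: int
    classes: list[tuple[str, int]]
    modules: list[ModuleSpec] = field(default_factory=list)
    noise_sd: float = 0.3
    baseline: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        labels = [c for c, _ in self.classes]
        if len(labels) != len(set(labels)):
            raise ValueError("class labels must be unique")
        if any(n < 1 for _, n in self.classes):
            raise ValueError("every class needs at least one sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        ids = [m.module_id for m in self.modules]
        if len(ids) != len(set(ids)):
            raise ValueError("module ids must be unique")
        total = sum(m.n_genes for m in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"modules claim {total} genes but the cohort has only {self.n_genes}"
            )
        known = set(labels)
        for m in self.modules:
            if m.effect < 0:
                raise ValueError(f"module {m.module_id}: effect must be >= 0")
            unknown = set(m.up_classes) - known
            if unknown:
                raise ValueError(
                    f"module {m.module_id}: unknown class labels {sorted(unknown)}"
                )

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.classes)


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    module_of_gene: pd.Series  # gene -> module_id or None
    class_of_sample: pd.Series  # sample -> class label

    def module_genes(self, module_id: str) -> list[str]:
        mask = self.module_of_gene == module_id
        if not mask.any():
            raise KeyError(f"unknown module: {module_id!r}")
        return list(self.module_of_gene.index[mask])


def generate_cohort(design: CohortDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a cohort matrix and its ground truth from a design.

    Entry (g, s) = baseline + effect * [g in module m and class(s) in
    up_classes(m)] + Normal(0, noise_sd).  Bit-reproducible given the design
    seed (one pseudorandom stream; sub-streams derived deterministically).
    """
    rng = np.random.default_rng(design.seed)
    gene_ids = [f"g{i + 1:05d}" for i in range(design.n_genes)]
    sample_ids: list[str] = []
    class_of_sample: list[str] = []
    for label, n in design.classes:
        for j in range(n):
            sample_ids.append(f"{label}_{j + 1:02d}")
            class_of_sample.append(label)
    classes = pd.Series(class_of_sample, index=sample_ids, name="class")

    values = np.full((design.n_genes, len(sample_ids)), design.baseline, dtype=float)
    module_of_gene = pd.Series([None] * design.n_genes, index=gene_ids, dtype=object)
    cursor = 0
    for m in design.modules:
        rows = slice(cursor, cursor + m.n_genes)
        cols = np.array([c in m.up_classes for c in class_of_sample])
        values[rows, cols] += m.effect
        module_of_gene.iloc[rows] = m.module_id
        cursor += m.n_genes
    if design.noise_sd > 0:
        values += rng.normal(0.0, design.noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), classes
    )
    return matrix, GroundTruth(module_of_gene, classes)


def default_design(seed: int = 0) -> CohortDesign:
    """Desk-scale reference design: 2000 genes, 5 classes x 12 samples, four
    50-gene modules each overexpressed (1.0 log10 units) in one class, noise
    0.3 log10 units.  The fifth class carries no module and acts as control."""
    classes = [(f"C{i + 1}", 12) for i in range(5)]
    modules = [
        ModuleSpec(f"M{i + 1}", 50, (f"C{i + 1}",), effect=1.0) for i in range(4)
    ]
    return CohortDesign(
        n_genes=2000, classes=classes, modules=modules, noise_sd=0.3, seed=seed
    )


def lymphoma_like_design(seed: int = 0) -> CohortDesign:
    """Nine-class design mirroring a lymphoma-style cohort layout: five tumor
    subtypes plus four control classes, with tumor-specific and pan-tumor
    modules.  Reduced sample counts for desk-scale runs."""
    tumor = ["BL", "DLBCL", "IntL", "FL", "MM"]
    control = ["Bcell", "GCB", "cellline", "tonsil"]
    classes = [(c, 8) for c in tumor] + [(c, 6) for c in control]
    modules = [
        ModuleSpec("BL_up", 40, ("BL",), 1.0),
        ModuleSpec("DLBCL_FL_up", 40, ("DLBCL", "FL"), 1.0),
        ModuleSpec("MM_up", 40, ("MM",), 1.0),
        ModuleSpec("lymphoma_up", 40, tuple(tumor), 0.8),
        ModuleSpec("Bcell_up", 40, ("Bcell", "GCB"), 1.0),
    ]
    return CohortDesign(
        n_genes=2500, classes=classes, modules=modules, noise_sd=0.3, seed=seed
    )


def generate_toy_pathway(
    n_enzymes: int,
    split_label: str = "Oxaloacetate",
    weights: list[float] | None = None,
) -> tuple[PathwayGraph, ExpressionMatrix]:
    """Build a cyclic compound/enzyme pathway and a matching expression matrix.

    The cycle alternates compound and enzyme nodes (compound -> enzyme ->
    compound ... closing the cycle); all edges are activations and one compound
    is named `split_label` so the cycle can later be cut there.  The companion
    matrix encodes each enzyme's fold-change `weight`: reference samples at
    log10 expression 0, target samples at log10(weight).

    With 8 enzymes and the packaged compound names this reproduces the toy
    TCA-like cycle shipped as ``tca_toy.tsv``.
    """
    if n_enzymes < 2:
        raise ValueError("n_enzymes must be >= 2")
    if weights is None:
        weights = [1.0] * n_enzymes
    if len(weights) != n_enzymes:
        raise ValueError("weights length must equal n_enzymes")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive (linear-scale fold changes)")

    if n_enzymes == len(TCA_COMPOUNDS) and split_label in TCA_COMPOUNDS:
        offset = TCA_COMPOUNDS.index(split_label)
        compounds = [TCA_COMPOUNDS[(offset + i) % n_enzymes] for i in range(n_enzymes)]
    else:
        compounds = [split_label] + [f"Cpd{i}" for i in range(1, n_enzymes)]
    enzymes = [f"ENZ{i + 1}" for i in range(n_enzymes)]

    graph = PathwayGraph()
    for c in compounds:
        graph.add_node(c, kind="compound")
    for e in enzymes:
        graph.add_node(e, kind="gene", genes=[f"{e}_gene"])
    for i in range(n_enzymes):
        graph.add_edge(compounds[i], enzymes[i], "activation")
        graph.add_edge(enzymes[i], compounds[(i + 1) % n_enzymes], "activation")

    genes = [f"{e}_gene" for e in enzymes]
    log_w = np.log10(np.asarray(weights, dtype=float))
    values = np.column_stack(
        [np.zeros(n_enzymes), np.zeros(n_enzymes), log_w, log_w]
    )
    samples = ["ref_1", "ref_2", "tgt_1", "tgt_2"]
    classes = pd.Series(
        ["reference", "reference", "target", "target"], index=samples, name="class"
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), classes
    )
    return graph, matrix
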