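"""End-to-end orchestration: simulate/load -> center -> map -> spots ->
differential statistics -> spot network -> pathway signal flow.

One config (YAML or :class:`PipelineConfig`) drives all stages; a single
seed drives every source of randomness, so a run is byte-reproducible for a
fixed config + seed.  Outputs are plain TSV per stage plus a machine-readable
``report.json`` and a ``provenance.yaml`` recording all parameters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import CohortDesign, ModuleSpec, default_design, generate_cohort
from .io import (
    ExpressionMatrix,
    center_genes,
    read_annotation_tsv,
    read_classes_tsv,
    read_expression_tsv,
    write_expression_tsv,
)
from .network import build_wto_network
from .psf import linearize_cycle, node_weights, propagate_psf, read_pathway_tsv
from .som import mean_total_expression, sample_portrait, train_som
from .spots import (
    SpotDetector,
    associate_spot_classes,
    count_by_region,
    fisher_enrichment,
    invariant_units,
    segment_map,
    spot_genes,
    variance_map,
)
from .stats import shrinkage_t, spot_t

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "packaged_data_path"]

logger = logging.getLogger("epicart")


def packaged_data_path(name: str) -> Path:
    """Path of a packaged data fixture (e.g. ``tca_toy.tsv``)."""
    return Path(resources.files("epicart").joinpath("data", name))


@dataclass
class PipelineConfig:
    """All parameters of one end-to-end run."""

    # input: either file paths ...
    matrix_path: str | None = None
    classes_path: str | None = None
    annotation_path: str | None = None
    pathway_path: str | None = None
    # ... or a simulation design
    design: CohortDesign | None = None

    # stage parameters
    n_rows: int = 20
    n_cols: int = 20
    epochs: int = 20
    quantile: float = 0.98
    min_spot_size: int = 4
    central_fraction: float = 1 / 3
    invariant_quantile: float = 0.25
    s0_rule: str | float = "median"
    tau: float = 0.3
    split_node: str = "Oxaloacetate"
    reference_class: str | None = None
    map_pathway_to_module: str | None = "M1"

    seed: int = 0
    out_dir: str = "epicart_out"

    def validate(self) -> None:
        if self.matrix_path is None and self.design is None:
            raise ValueError("config needs either a matrix path or a simulation design")
        if self.matrix_path is not None and not Path(self.matrix_path).exists():
            raise FileNotFoundError(self.matrix_path)
        for p in (self.classes_path, self.annotation_path, self.pathway_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if not 0 < self.central_fraction < 1:
            raise ValueError("central_fraction must lie in (0, 1)")
        if self.min_spot_size < 1 or self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid/spot parameters out of range")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; a `design:` block mirrors CohortDesign."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    design = None
    if "design" in raw and raw["design"] is not None:
        d = raw.pop("design")
        modules = [
            ModuleSpec(
                m["module_id"],
                int(m["n_genes"]),
                tuple(m["up_classes"]),
                float(m.get("effect", 1.0)),
            )
            for m in d.get("modules", [])
        ]
        design = CohortDesign(
            n_genes=int(d["n_genes"]),
            classes=[(c["label"], int(c["n_samples"])) for c in d["classes"]],
            modules=modules,
            noise_sd=float(d.get("noise_sd", 0.3)),
            baseline=float(d.get("baseline", 2.0)),
            seed=int(d.get("seed", raw.get("seed", 0))),
        )
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(design=design, **raw)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    return obj


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write per-stage TSVs, report.json, provenance.yaml.

    Returns the report dict.  Any stage error aborts with the stage name in
    the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "setup"
    try:
        # ---- input ----------------------------------------------------------
        stage = "input"
        t0 = _stage(stage)
        truth = None
        if config.design is not None:
            matrix, truth = generate_cohort(config.design)
            write_expression_tsv(matrix, out / "expr.tsv")
            matrix.classes.to_csv(out / "classes.tsv", sep="\t", header=False)
            truth.module_of_gene.fillna("").to_csv(
                out / "truth.tsv", sep="\t", header=False
            )
        else:
            matrix = read_expression_tsv(config.matrix_path)
            if config.classes_path:
                matrix = ExpressionMatrix(
                    matrix.data, read_classes_tsv(config.classes_path)
                )
        report["n_genes"] = matrix.n_genes
        report["n_samples"] = matrix.n_samples

        # ---- center + train -------------------------------------------------
        stage = "train"
        _stage(stage)
        centered = center_genes(matrix)
        som = train_som(
            centered,
            n_rows=config.n_rows,
            n_cols=config.n_cols,
            epochs=config.epochs,
            random_state=config.seed,
        )
        som.gene_to_unit_.to_csv(out / "gene_to_unit.tsv", sep="\t", header=False)
        pd.DataFrame(som.metagenes_, columns=som.sample_ids_).to_csv(
            out / "metagenes.tsv", sep="\t", index_label="unit"
        )
        report["quantization_error"] = som.quantization_error_

        # ---- spots ----------------------------------------------------------
        stage = "spots"
        _stage(stage)
        portraits = [sample_portrait(som, s) for s in matrix.sample_ids]
        detector = SpotDetector(q=config.quantile, min_size=config.min_spot_size)
        labels_per_sample = (
            [matrix.classes[s] for s in matrix.sample_ids]
            if matrix.classes is not None
            else None
        )
        detector.fit(portraits, labels_per_sample)
        spot_map = detector.spot_map_
        if matrix.classes is not None:
            spot_map = associate_spot_classes(spot_map, som, centered)
        seg = segment_map(config.n_rows, config.n_cols, config.central_fraction)
        inv = invariant_units(variance_map(som), config.invariant_quantile)

        if config.annotation_path:
            annotation = read_annotation_tsv(config.annotation_path)
            annotated = set(annotation.symbols)
        elif truth is not None:
            annotated = set(truth.module_of_gene.dropna().index)
        else:
            annotated = set()
        region_counts = count_by_region(som.gene_to_unit_, seg, annotated, invariant=inv)
        region_counts.to_csv(out / "region_counts.tsv", sep="\t")
        spot_rows = []
        all_spot_units: set[int] = set()
        for spot in spot_map.spots:
            genes = spot_genes(spot, som.gene_to_unit_)
            all_spot_units |= spot.units
            spot_rows.append(
                {
                    "label": spot.label,
                    "size": spot.size,
                    "peak": spot.peak,
                    "n_genes": len(genes),
                    "classes": ",".join(spot.classes),
                }
            )
        pd.DataFrame(spot_rows).to_csv(out / "spots.tsv", sep="\t", index=False)
        report["spot_count"] = len(spot_map)
        report["spots"] = spot_rows
        report["region_counts"] = {
            r: {"total": int(row["total"]), "annotated": int(row["annotated"])}
            for r, row in region_counts.iterrows()
        }

        genes_in_spots = [
            g for g in som.gene_to_unit_.index if som.gene_to_unit_[g] in all_spot_units
        ]
        if annotated:
            known_annot = annotated & set(som.gene_to_unit_.index)
            overlap = len(known_annot & set(genes_in_spots))
            enr = fisher_enrichment(
                overlap, len(genes_in_spots), len(known_annot), matrix.n_genes
            )
            report["enrichment"] = {
                "annotated_in_spots": overlap,
                "genes_in_spots": len(genes_in_spots),
                "annotated": len(known_annot),
                "universe": matrix.n_genes,
                "odds_ratio": enr.odds_ratio,
                "p_value": enr.p_value,
            }

        # ---- differential statistics ---------------------------------------
        stage = "dex"
        _stage(stage)
        module_recovery = {}
        if matrix.classes is not None:
            labels = matrix.class_labels()
            mte = mean_total_expression(portraits)
            report["mean_total_expression_by_class"] = {
                lab: float(mte[matrix.samples_of_class(lab)].mean()) for lab in labels
            }
            spot_p: dict[str, dict[str, float]] = {}
            for lab in labels:
                rest = [l for l in labels if l != lab]
                gene_res = shrinkage_t(centered, lab, rest, s0_rule=config.s0_rule)
                gene_res.table.to_csv(out / f"dex_{lab}_vs_rest.tsv", sep="\t")
                if len(spot_map):
                    sres = spot_t(
                        centered, spot_map, som.gene_to_unit_, lab, rest,
                        s0_rule=config.s0_rule,
                    )
                    for s_label, row in sres.table.iterrows():
                        spot_p.setdefault(s_label, {})[lab] = float(row["p"])
            report["spot_p_by_class"] = spot_p

            if truth is not None and config.design is not None:
                for m in config.design.modules:
                    planted = set(truth.module_genes(m.module_id))
                    best = {"spot": None, "jaccard": 0.0, "p_value": None}
                    for spot in spot_map.spots:
                        sg = set(spot_genes(spot, som.gene_to_unit_))
                        if not sg:
                            continue
                        jac = len(sg & planted) / len(sg | planted)
                        if jac > best["jaccard"]:
                            up = m.up_classes[0]
                            best = {
                                "spot": spot.label,
                                "jaccard": jac,
                                "p_value": spot_p.get(spot.label, {}).get(up),
                            }
                    module_recovery[m.module_id] = best
                report["module_recovery"] = module_recovery

        # ---- network --------------------------------------------------------
        stage = "network"
        _stage(stage)
        if len(spot_map) >= 2:
            net = build_wto_network(
                centered, spot_map, som.gene_to_unit_, tau=config.tau
            )
            net.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False)
            report["network"] = {
                "nodes": net.nodes,
                "n_positive_edges": len(net.positive_edges),
                "n_negative_edges": len(net.negative_edges),
                "edges": [
                    {"source": u, "target": v, "w": w, "sign": sign}
                    for u, v, w, sign in net.edges
                ],
            }

        # ---- pathway signal flow --------------------------------------------
        stage = "psf"
        _stage(stage)
        pathway_path = config.pathway_path or packaged_data_path("tca_toy.tsv")
        pathway = read_pathway_tsv(pathway_path)
        if (
            config.design is not None
            and truth is not None
            and config.map_pathway_to_module is not None
        ):
            # couple the toy pathway to the cohort: enzyme members become the
            # first genes of the designated planted module
            planted = truth.module_genes(config.map_pathway_to_module)
            enzyme_nodes = [n for n in pathway.nodes if pathway.kind(n) == "gene"]
            if len(planted) >= len(enzyme_nodes):
                for node, gene in zip(enzyme_nodes, planted):
                    pathway.graph.nodes[node]["genes"] = [gene]
        linear = linearize_cycle(pathway, config.split_node)
        if matrix.classes is not None:
            labels = matrix.class_labels()
            reference = config.reference_class or labels[-1]
            ref_samples = matrix.samples_of_class(reference)
            psf_by_class = {}
            psf_tables = []
            for lab in labels:
                if lab == reference:
                    continue
                weights = node_weights(
                    linear, centered, ref_samples, matrix.samples_of_class(lab)
                )
                result = propagate_psf(linear, weights)
                output_node = f"{config.split_node}__out"
                psf_by_class[lab] = result.log10_signal(output_node)
                t = result.table.copy()
                t.insert(0, "class", lab)
                psf_tables.append(t)
            pd.concat(psf_tables).to_csv(out / "psf.tsv", sep="\t", index_label="node")
            report["psf"] = {
                "reference_class": reference,
                "output_log10_signal_by_class": psf_by_class,
            }
        logger.info("pipeline done in %.1f s", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- bundle -------------------------------------------------------------
    report_path = out / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(_json_ready(report), fh, sort_keys=True, indent=2)
        fh.write("\n")
    provenance = {
        "package": "epicart",
        "version": __version__,
        "seed": config.seed,
        "parameters": _json_ready(
            {
                k: v
                for k, v in asdict(config).items()
                if k != "design"
            }
        ),
        "design": _json_ready(asdict(config.design)) if config.design else None,
    }
    with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return report
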