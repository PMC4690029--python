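"""Pathway Signal Flow: propagate expression-derived node weights through a
directed activation/inhibition pathway graph.

A pathway is a directed graph whose nodes are genes (enzymes), compounds
(metabolites) or explicit input/output terminals.  Gene nodes carry member
gene IDs; their weight is the linear-scale fold change of the member genes
between a target and a reference sample group.  Compounds are pass-through
(weight 1): they have no transcript, so their activity is inferred purely
from the propagated signal.

Cyclic pathways (like the TCA cycle) are first linearized by splitting one
designated node into an input and an output copy; the signal then flows once
around the former cycle, so the activity of the input compound passes through
every intermediate.  Signals are reported in linear and log10 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PathwayGraph",
    "PSFResult",
    "read_pathway_tsv",
    "write_pathway_tsv",
    "reactions_to_relations",
    "linearize_cycle",
    "node_weights",
    "propagate_psf",
]

NODE_KINDS = frozenset({"gene", "compound", "input", "output"})
EDGE_TYPES = frozenset({"activation", "inhibition"})


@dataclass
class Reaction:
    substrate: str
    enzyme: str
    product: str
    reversible: bool = False


class PathwayGraph:
    """Directed pathway graph over gene/compound/input/output nodes.

    Thin wrapper over a :class:`networkx.DiGraph` that enforces the node and
    edge vocabularies and optionally carries raw reaction records prior to
    their conversion into one-directional relations.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self.reactions: list[Reaction] = []

    # -- construction ----------------------------------------------------------
    def add_node(self, node_id: str, kind: str, genes: list[str] | None = None) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r} for node {node_id!r}")
        self.graph.add_node(node_id, kind=kind, genes=list(genes or []))

    def add_edge(self, source: str, target: str, edge_type: str = "activation") -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        for endpoint in (source, target):
            if endpoint not in self.graph:
                raise ValueError(f"edge endpoint {endpoint!r} is not a declared node")
        self.graph.add_edge(source, target, type=edge_type)

    def add_reaction(self, substrate: str, enzyme: str, product: str,
                     reversible: bool = False) -> None:
        for endpoint in (substrate, enzyme, product):
            if endpoint not in self.graph:
                raise ValueError(f"reaction endpoint {endpoint!r} is not a declared node")
        self.reactions.append(Reaction(substrate, enzyme, product, reversible))

    # -- queries ---------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, d["type"]) for u, v, d in self.graph.edges(data=True)]

    def kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def member_genes(self, node_id: str) -> list[str]:
        return list(self.graph.nodes[node_id]["genes"])

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def copy(self) -> "PathwayGraph":
        clone = PathwayGraph()
        clone.graph = self.graph.copy()
        clone.reactions = list(self.reactions)
        return clone

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def read_pathway_tsv(path) -> PathwayGraph:
    """Parse the pathway TSV dialect.

    Lines are ``node <id> <kind> [gene,gene,...]``, ``edge <src> <dst>
    <activation|inhibition>`` or ``reaction <substrate> <enzyme> <product>
    <fwd|rev>``, tab-separated.  Edge endpoints must be declared nodes.
    """
    graph = PathwayGraph()
    n_records = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            record = parts[0]
            try:
                if record == "node":
                    genes = parts[3].split(",") if len(parts) > 3 and parts[3] else []
                    graph.add_node(parts[1], kind=parts[2], genes=genes)
                elif record == "edge":
                    graph.add_edge(parts[1], parts[2], parts[3])
                elif record == "reaction":
                    graph.add_reaction(
                        parts[1], parts[2], parts[3], reversible=parts[4] == "rev"
                    )
                else:
                    raise ValueError(f"unknown record type {record!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            n_records += 1
    if n_records == 0:
        raise ValueError(f"{path}: empty pathway file")
    return graph


def write_pathway_tsv(graph: PathwayGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in graph.nodes:
            genes = ",".join(graph.member_genes(node))
            fh.write(f"node\t{node}\t{graph.kind(node)}\t{genes}\n")
        for u, v, t in graph.edges:
            fh.write(f"edge\t{u}\t{v}\t{t}\n")
        for r in graph.reactions:
            flag = "rev" if r.reversible else "fwd"
            fh.write(f"reaction\t{r.substrate}\t{r.enzyme}\t{r.product}\t{flag}\n")


def reactions_to_relations(graph: PathwayGraph) -> PathwayGraph:
    """Convert substrate-enzyme-product reactions into one-directional
    relations: each reaction (S, E, P) becomes activation edges S->E and E->P.

    Reversible reactions carry no declared orientation in this dialect and
    therefore raise; orient them (``fwd``) along the intended cycle direction
    before conversion.
    """
    if not graph.reactions:
        raise ValueError("graph contains no reaction records to convert")
    out = graph.copy()
    for r in out.reactions:
        if r.reversible:
            raise ValueError(
                f"reversible reaction {r.substrate}->{r.enzyme}->{r.product} has no "
                "declared orientation; mark it 'fwd' along the cycle direction"
            )
        out.add_edge(r.substrate, r.enzyme, "activation")
        out.add_edge(r.enzyme, r.product, "activation")
    out.reactions = []
    return out


def linearize_cycle(graph: PathwayGraph, split_label: str) -> PathwayGraph:
    """Cut a cyclic pathway at one node so the signal can flow acyclically.

    The node is duplicated into ``<label>__in`` (kind input, keeps the
    outgoing edges) and ``<label>__out`` (kind output, keeps the incoming
    edges).  The result must be acyclic; a residual cycle raises with the
    offending nodes.  Node count grows by exactly one.
    """
    if split_label not in graph.graph:
        raise ValueError(f"split node {split_label!r} not in pathway")
    if graph.reactions:
        raise ValueError("convert reactions to relations before linearizing")
    out = PathwayGraph()
    in_id, out_id = f"{split_label}__in", f"{split_label}__out"
    for node in graph.nodes:
        if node == split_label:
            continue
        out.add_node(node, kind=graph.kind(node), genes=graph.member_genes(node))
    out.add_node(in_id, kind="input", genes=graph.member_genes(split_label))
    out.add_node(out_id, kind="output", genes=graph.member_genes(split_label))
    for u, v, t in graph.edges:
        if u == split_label and v == split_label:  # self-loop: in -> out directly
            out.add_edge(in_id, out_id, t)
            continue
        u2 = in_id if u == split_label else u
        v2 = out_id if v == split_label else v
        out.add_edge(u2, v2, t)
    if not out.is_acyclic():
        cycle = nx.find_cycle(out.graph)
        raise ValueError(f"graph still cyclic after split: residual cycle {cycle}")
    return out


def node_weights(
    graph: PathwayGraph,
    matrix,
    reference_samples: list[str],
    target_samples: list[str],
) -> dict[str, float]:
    """Expression-derived node weights, linear scale.

    A gene node's weight is ``10 ** (mean_target - mean_reference)`` of the
    node's member-gene mean log10 expression (so a mean log10 difference of 1
    is a ten-fold change).  Compound, input and output nodes weigh 1.
    Member genes missing from the matrix are dropped with a warning; a gene
    node with no member present weighs 1 with a warning.
    """
    if not reference_samples or not target_samples:
        raise ValueError("reference and target sample sets must be non-empty")
    data = matrix.data
    for s in list(reference_samples) + list(target_samples):
        if s not in data.columns:
            raise KeyError(f"unknown sample: {s!r}")
    weights: dict[str, float] = {}
    for node in graph.nodes:
        if graph.kind(node) != "gene":
            weights[node] = 1.0
            continue
        members = graph.member_genes(node)
        present = [g for g in members if g in data.index]
        missing = sorted(set(members) - set(present))
        if missing:
            warnings.warn(
                f"node {node!r}: member genes absent from matrix: {missing}",
                stacklevel=2,
            )
        if not present:
            weights[node] = 1.0
            continue
        sub = data.loc[present]
        diff = float(
            sub[list(target_samples)].to_numpy().mean()
            - sub[list(reference_samples)].to_numpy().mean()
        )
        weights[node] = float(10.0 ** diff)
    return weights


@dataclass
class PSFResult:
    """Per-node propagated signals (linear and log10) with node roles."""

    table: pd.DataFrame  # index node; columns kind, role, weight, signal, log10_signal

    def signal(self, node: str) -> float:
        return float(self.table.loc[node, "signal"])

    def log10_signal(self, node: str) -> float:
        return float(self.table.loc[node, "log10_signal"])

    @property
    def outputs(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "output"]


_AGGREGATORS = {
    "mean": np.mean,
    "min": np.min,
    "product": np.prod,
}


def propagate_psf(
    graph: PathwayGraph,
    weights: dict[str, float],
    aggregate: str = "mean",
) -> PSFResult:
    """Propagate signals from the pathway inputs to every downstream node.

    Nodes are processed in topological order.  An input node's signal equals
    its own weight.  Every other node aggregates one contribution per incoming
    edge — the upstream signal for an activation, its reciprocal for an
    inhibition — by the arithmetic mean (``min`` and ``product`` selectable),
    then multiplies by its own weight.
    """
    if not graph.is_acyclic():
        raise ValueError("propagation requires an acyclic pathway; linearize first")
    if aggregate not in _AGGREGATORS:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    agg = _AGGREGATORS[aggregate]
    g = graph.graph
    for node in g.nodes:
        w = weights.get(node)
        if w is None:
            raise ValueError(f"no weight for node {node!r}")
        if not (w > 0 and np.isfinite(w)):
            raise ValueError(f"node {node!r}: weight must be positive and finite")
    inputs = [n for n in g.nodes if g.in_degree(n) == 0]
    if not inputs:
        raise ValueError("pathway has no input node")

    signal: dict[str, float] = {}
    for node in nx.topological_sort(g):
        if g.in_degree(node) == 0:
            signal[node] = float(weights[node])
            continue
        contributions = []
        for u, _, d in g.in_edges(node, data=True):
            s = signal[u]
            contributions.append(s if d["type"] == "activation" else 1.0 / s)
        signal[node] = float(agg(contributions) * weights[node])

    rows = []
    for node in graph.nodes:
        if g.in_degree(node) == 0:
            role = "input"
        elif g.out_degree(node) == 0:
            role = "output"
        else:
            role = "intermediate"
        s = signal[node]
        rows.append(
            {
                "node": node,
                "kind": graph.kind(node),
                "role": role,
                "weight": float(weights[node]),
                "signal": s,
                "log10_signal": float(np.log10(s)),
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return PSFResult(table)
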