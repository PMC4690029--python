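"""Tabular input/output and expression preprocessing.

The pipeline's universal input is a gene x sample matrix of log10
expression values.  On this scale a difference of 1 between two values
corresponds to a ten-fold change in linear scale.  All readers are plain
tab-separated text: an expression TSV (first row sample IDs, first column
gene IDs), a two-column sample->class table, standard GMT gene-set files
and a four-column chromatin-modifier annotation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ModifierAnnotation",
    "read_expression_tsv",
    "write_expression_tsv",
    "center_genes",
    "log10_transform",
    "read_gmt",
    "read_classes_tsv",
    "read_annotation_tsv",
]

MARK_VOCABULARY = frozenset({"H3K4", "H3K9", "H3K27", "H3K36", "H3K79", "DNA"})
ROLE_VOCABULARY = frozenset({"writer", "eraser", "reader"})
TXN_VOCABULARY = frozenset({"act", "rep", "unknown"})


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log10 expression with optional class labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes on rows, samples on columns, finite floats (log10 units).
    classes : pandas.Series, optional
        Sample -> class label association, indexed by sample ID.
    """

    data: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.data = self.data.astype(float)
        if self.classes is not None:
            self.classes = pd.Series(self.classes)
            missing = [s for s in self.data.columns if s not in self.classes.index]
            if missing:
                raise ValueError(f"samples without class assignment: {missing}")
            self.classes = self.classes.reindex(self.data.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def class_labels(self) -> list[str]:
        if self.classes is None:
            raise ValueError("matrix carries no class assignment")
        seen: dict[str, None] = {}
        for label in self.classes:
            seen.setdefault(label, None)
        return list(seen)

    def samples_of_class(self, label: str) -> list[str]:
        if self.classes is None:
            raise ValueError("matrix carries no class assignment")
        hits = [s for s in self.sample_ids if self.classes[s] == label]
        if not hits:
            raise KeyError(f"unknown class label: {label!r}")
        return hits

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.classes)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("gene set names must be unique")
        for s in self.sets:
            if not s.genes:
                raise ValueError(f"gene set {s.name!r} is empty")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class ModifierAnnotation:
    """Chromatin-modifier annotation: which mark an enzyme targets, whether it
    writes/erases/reads it, and the expected effect on transcription."""

    table: pd.DataFrame  # columns: symbol, mark, role, txn_effect

    def __post_init__(self) -> None:
        required = ["symbol", "mark", "role", "txn_effect"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns: {missing}")
        bad_marks = set(self.table["mark"]) - MARK_VOCABULARY
        if bad_marks:
            raise ValueError(f"unknown marks: {sorted(bad_marks)}")
        bad_roles = set(self.table["role"]) - ROLE_VOCABULARY
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        bad_txn = set(self.table["txn_effect"]) - TXN_VOCABULARY
        if bad_txn:
            raise ValueError(f"unknown transcription effects: {sorted(bad_txn)}")

    @property
    def symbols(self) -> list[str]:
        return list(dict.fromkeys(self.table["symbol"]))

    def subset(self, *, mark: str | None = None, role: str | None = None) -> list[str]:
        t = self.table
        if mark is not None:
            t = t[t["mark"] == mark]
        if role is not None:
            t = t[t["role"] == role]
        return list(dict.fromkeys(t["symbol"]))


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First row holds sample IDs (first header cell ignored), first column gene
    IDs, body numeric.  Duplicate gene IDs and ragged/non-numeric rows raise.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        samples = header.split("\t")[1:]
        n_cols = len(samples)
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols + 1} columns, got {len(parts)}"
                )
            genes.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    frame = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(frame)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix back as TSV with 12 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        values = matrix.values
        for gene, row in zip(matrix.gene_ids, values):
            cells = "\t".join(format(v, ".12g") for v in row)
            fh.write(f"{gene}\t{cells}\n")


def center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (the differential-expression
    preprocessing: portraits then show deviation from the cohort mean).

    Idempotent; preserves all within-gene differences exactly.
    """
    values = matrix.values
    centered = values - values.mean(axis=1, keepdims=True)
    frame = pd.DataFrame(centered, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, matrix.classes)


def log10_transform(matrix: ExpressionMatrix, epsilon: float = 1.0) -> ExpressionMatrix:
    """Apply log10(x + epsilon) to a linear-scale matrix.

    For matrices already on log10 scale this must NOT be applied; it exists for
    linear-scale input only.  epsilon defaults to one linear unit.
    """
    values = matrix.values
    if np.any(values + epsilon <= 0):
        raise ValueError("log10 transform requires x + epsilon > 0 everywhere")
    frame = pd.DataFrame(
        np.log10(values + epsilon), index=matrix.data.index, columns=matrix.data.columns
    )
    return ExpressionMatrix(frame, matrix.classes)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then gene IDs, tab-separated."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                name = parts[0] if parts else f"line {lineno}"
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return GeneSetCollection(sets)


def read_classes_tsv(path) -> pd.Series:
    """Read a two-column sample -> class TSV (header optional)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (sample, class)")
    first = frame.iloc[0]
    if first[0].lower() in {"sample", "sample_id"}:
        frame = frame.iloc[1:]
    return pd.Series(frame[1].to_numpy(), index=frame[0].to_numpy(), name="class")


_ROLE_CODES = {"W": "writer", "E": "eraser", "R": "reader"}


def read_annotation_tsv(path) -> ModifierAnnotation:
    """Read the four-column modifier annotation TSV (symbol, mark, role, txn)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    rename = {"txn": "txn_effect", "effect": "txn_effect"}
    frame = frame.rename(columns=rename)
    frame["role"] = frame["role"].map(lambda r: _ROLE_CODES.get(r, r))
    frame["txn_effect"] = frame["txn_effect"].fillna("unknown")
    return ModifierAnnotation(frame[["symbol", "mark", "role", "txn_effect"]])


def warn_if_uncentered(matrix: ExpressionMatrix, tol: float = 1e-6) -> None:
    means = matrix.values.mean(axis=1)
    if means.size and np.max(np.abs(means)) > tol:
        warnings.warn(
            "matrix does not look gene-centered; portraits will mix absolute and "
            "differential expression (apply center_genes first)",
            stacklevel=3,
        )
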