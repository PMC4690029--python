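"""Shrinkage t-test differential expression, map overlays and gene-set
summary profiles.

The shrinkage t statistic stabilizes small-variance genes by adding a
cohort-wide fudge constant s0 to every gene's pooled standard error:
t = d / (s + s0) with d the class-mean difference (log10 units) and s the
pooled two-sample standard error.  The default s0 is the median of the
gene-wise standard errors (the canonical additive-shrinkage rule); s0 = 0
recovers the ordinary pooled two-sample t exactly.  p-values come from the
Student reference with n_a + n_b - 2 degrees of freedom and are therefore
conservative whenever s0 > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix
from .som import ExpressionSOM
from .spots import SpotMap, spot_genes

__all__ = [
    "ShrinkageTResult",
    "MapOverlay",
    "shrinkage_t",
    "spot_t",
    "overlay_maps",
    "set_mean_profile",
    "set_mean_class_profile",
]


@dataclass
class ShrinkageTResult:
    """Per-gene (or per-spot) shrinkage t-test results.

    `table` columns: d (mean difference, log10 units), s (pooled standard
    error), t, p (two-sided), fdr (Benjamini-Hochberg).  `s0` is the fudge
    constant shared by all rows of the call; `df` the Student degrees of
    freedom; `zero_variance` flags rows with s + s0 == 0 (infinite statistic).
    """

    table: pd.DataFrame
    s0: float
    df: int
    class_a: str
    class_b: str

    @property
    def zero_variance(self) -> pd.Series:
        return ~np.isfinite(self.table["t"])


def _resolve_classes(matrix: ExpressionMatrix, label) -> list[str]:
    if isinstance(label, str):
        return matrix.samples_of_class(label)
    samples: list[str] = []
    for lab in label:
        samples.extend(matrix.samples_of_class(lab))
    return samples


def _resolve_s0(rule, s: np.ndarray) -> float:
    if rule is None:
        rule = "median"
    if isinstance(rule, str):
        if rule == "median":
            return float(np.median(s))
        if rule == "q90":
            return float(np.quantile(s, 0.9))
        raise ValueError(f"unknown s0 rule {rule!r}")
    s0 = float(rule)
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    return s0


def shrinkage_t(
    matrix: ExpressionMatrix,
    class_a,
    class_b,
    s0_rule="median",
) -> ShrinkageTResult:
    """Shrinkage t-test of class_a versus class_b per gene.

    Each class needs >= 2 samples.  d = mean(a) - mean(b); s is the pooled
    (equal-variance) standard error; s0 follows `s0_rule` ("median", "q90",
    or a nonnegative number); t = d / (s + s0); two-sided p from Student's t
    with n_a + n_b - 2 degrees of freedom plus a Benjamini-Hochberg FDR
    column.  Genes with s + s0 == 0 get an infinite statistic and p = 0.
    """
    samples_a = _resolve_classes(matrix, class_a)
    samples_b = _resolve_classes(matrix, class_b)
    na, nb = len(samples_a), len(samples_b)
    if na < 2 or nb < 2:
        raise ValueError(f"each class needs >= 2 samples (got {na} and {nb})")
    A = matrix.data[samples_a].to_numpy()
    B = matrix.data[samples_b].to_numpy()
    d = A.mean(axis=1) - B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    s = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    s0 = _resolve_s0(s0_rule, s)

    denom = s + s0
    with np.errstate(divide="ignore"):
        t = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), np.sign(d) * np.inf)
    t = np.where((denom == 0) & (d == 0), 0.0, t)
    p = np.where(np.isfinite(t), 2.0 * sps.t.sf(np.abs(t), df), 0.0)
    if np.any(~np.isfinite(t)):
        warnings.warn(
            "genes with zero variance and s0 = 0: statistic infinite, p = 0",
            stacklevel=2,
        )
    fdr = sps.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")
    table = pd.DataFrame(
        {"d": d, "s": s, "t": t, "p": p, "fdr": fdr}, index=matrix.data.index
    )
    label_a = class_a if isinstance(class_a, str) else "+".join(class_a)
    label_b = class_b if isinstance(class_b, str) else "+".join(class_b)
    return ShrinkageTResult(table, s0, df, label_a, label_b)


def spot_profiles(
    matrix: ExpressionMatrix,
    spot_map: SpotMap,
    gene_to_unit: pd.Series,
) -> pd.DataFrame:
    """Per spot, the mean expression across its genes, per sample.

    Spots whose unit set captures no gene are omitted with a warning.
    """
    rows = {}
    for spot in spot_map.spots:
        genes = spot_genes(spot, gene_to_unit)
        if not genes:
            warnings.warn(f"spot {spot.label}: no genes mapped; omitted", stacklevel=2)
            continue
        rows[spot.label] = matrix.data.loc[genes].mean(axis=0)
    if not rows:
        raise ValueError("no spot has any mapped genes")
    return pd.DataFrame(rows).T


def spot_t(
    matrix: ExpressionMatrix,
    spot_map: SpotMap,
    gene_to_unit: pd.Series,
    class_a,
    class_b,
    s0_rule="median",
) -> ShrinkageTResult:
    """Shrinkage t-test applied to each spot's mean-gene profile."""
    profiles = spot_profiles(matrix, spot_map, gene_to_unit)
    spot_matrix = ExpressionMatrix(profiles, matrix.classes)
    return shrinkage_t(spot_matrix, class_a, class_b, s0_rule=s0_rule)


@dataclass
class MapOverlay:
    """Differential expression and significance maps over the grid.

    `mean_d`: per unit, mean difference of its genes; `neg_log10_p`: per
    unit, -log10 of the Fisher-combined p of its genes.  Units without genes
    carry NaN.
    """

    mean_d: np.ndarray
    neg_log10_p: np.ndarray
    combined_p: np.ndarray


def overlay_maps(
    result: ShrinkageTResult,
    gene_to_unit: pd.Series,
    som: ExpressionSOM,
) -> MapOverlay:
    """Aggregate per-gene d and p onto the grid.

    Significance is combined per unit by Fisher's method: X = -2 * sum(ln p)
    is referred to a chi-square with 2k degrees of freedom.
    """
    missing = [g for g in som.gene_to_unit_.index if g not in result.table.index]
    if missing:
        raise ValueError(f"result lacks {len(missing)} of the map's genes")
    n_units = som.n_rows * som.n_cols
    mean_d = np.full(n_units, np.nan)
    comb_p = np.full(n_units, np.nan)
    units = gene_to_unit.to_numpy()
    d = result.table["d"].reindex(gene_to_unit.index).to_numpy()
    p = result.table["p"].reindex(gene_to_unit.index).to_numpy()
    for u in np.unique(units):
        mask = units == u
        mean_d[u] = d[mask].mean()
        pk = np.clip(p[mask], 1e-300, 1.0)
        x = -2.0 * np.log(pk).sum()
        comb_p[u] = float(sps.chi2.sf(x, 2 * int(mask.sum())))
    with np.errstate(divide="ignore"):
        neg_log = -np.log10(comb_p)
    shape = (som.n_rows, som.n_cols)
    return MapOverlay(mean_d.reshape(shape), neg_log.reshape(shape), comb_p.reshape(shape))


def set_mean_profile(matrix: ExpressionMatrix, gene_set, name: str = "set") -> tuple[pd.Series, int]:
    """Mean expression over the set's genes present in the matrix, per sample.

    Returns (profile, number of genes used); raises when no set gene is
    present.
    """
    present = [g for g in gene_set if g in matrix.data.index]
    if not present:
        raise ValueError(f"no gene of set {name!r} present in the matrix")
    profile = matrix.data.loc[present].mean(axis=0)
    profile.name = name
    return profile, len(present)


def set_mean_class_profile(
    matrix: ExpressionMatrix, gene_set, name: str = "set"
) -> tuple[pd.Series, int]:
    """Class-wise mean of the set-mean profile (classes in cohort order)."""
    profile, n_used = set_mean_profile(matrix, gene_set, name)
    labels = matrix.class_labels()
    by_class = pd.Series(
        {lab: float(profile[matrix.samples_of_class(lab)].mean()) for lab in labels},
        name=name,
    )
    return by_class, n_used
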