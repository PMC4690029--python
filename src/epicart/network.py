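"""Spot correlation networks with the signed weighted topological overlap.

Spot mean-expression profiles are correlated across samples (signed Pearson
adjacency); the weighted topological overlap (wTO) then augments each direct
correlation with the correlation the two spots share through all other
spots:

    w_ij = (sum_k a_ik * a_kj + a_ij) / (min(k_i, k_j) + 1 - |a_ij|),
    k_i  = sum_{k != i} |a_ik|

The numerator keeps signs so positive and negative overlap stay
distinguishable; the node strengths in the denominator use magnitudes.
Edges with |w| above a threshold (default 0.3) form the module graph,
split into positive and negative edge sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .spots import SpotMap
from .stats import spot_profiles

__all__ = [
    "WTONetwork",
    "spot_profiles",
    "spot_adjacency",
    "wto",
    "threshold_edges",
    "build_wto_network",
]


def spot_adjacency(profiles: pd.DataFrame, beta: float = 1.0) -> pd.DataFrame:
    """Signed Pearson correlation between spot profiles, zero diagonal.

    `beta` is an optional soft-threshold exponent applied to the magnitude
    while keeping the sign (default 1: plain correlation).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two spot profiles")
    corr = np.corrcoef(profiles.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    if beta != 1.0:
        corr = np.sign(corr) * np.abs(corr) ** beta
    np.fill_diagonal(corr, 0.0)
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


def wto(adjacency) -> pd.DataFrame | np.ndarray:
    """Signed weighted topological overlap of a symmetric adjacency.

    Requires a symmetric matrix with zero diagonal and entries in [-1, 1];
    w_ii = 1 by convention.
    """
    if isinstance(adjacency, pd.DataFrame):
        labels = adjacency.index
        a = adjacency.to_numpy(dtype=float)
    else:
        labels = None
        a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max(initial=0.0) > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if np.abs(a).max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError("adjacency entries must lie in [-1, 1]")

    k = np.abs(a).sum(axis=1)
    numerator = a @ a + a
    denominator = np.minimum.outer(k, k) + 1.0 - np.abs(a)
    w = numerator / denominator
    np.fill_diagonal(w, 1.0)
    if labels is not None:
        return pd.DataFrame(w, index=labels, columns=labels)
    return w


def threshold_edges(
    w, tau: float = 0.3
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]]]:
    """Edges with |w_ij| > tau, split into (positive, negative) lists.

    Each edge is (node_i, node_j, w_ij) with i < j; the diagonal is excluded.
    """
    if isinstance(w, pd.DataFrame):
        labels = list(w.index)
        mat = w.to_numpy(dtype=float)
    else:
        mat = np.asarray(w, dtype=float)
        labels = list(range(mat.shape[0]))
    positive, negative = [], []
    n = mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            wij = float(mat[i, j])
            if abs(wij) > tau:
                edge = (labels[i], labels[j], wij)
                (positive if wij > 0 else negative).append(edge)
    return positive, negative


@dataclass
class WTONetwork:
    """Spot network: profiles, signed adjacency, wTO matrix, thresholded edges."""

    profiles: pd.DataFrame
    adjacency: pd.DataFrame
    w: pd.DataFrame
    positive_edges: list[tuple[str, str, float]]
    negative_edges: list[tuple[str, str, float]]
    tau: float

    @property
    def nodes(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def edges(self) -> list[tuple[str, str, float, str]]:
        out = [(u, v, w, "positive") for u, v, w in self.positive_edges]
        out += [(u, v, w, "negative") for u, v, w in self.negative_edges]
        return out

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["source", "target", "w", "sign"]
        )


def build_wto_network(
    matrix: ExpressionMatrix,
    spot_map: SpotMap,
    gene_to_unit: pd.Series,
    tau: float = 0.3,
    beta: float = 1.0,
) -> WTONetwork:
    """Full route: spot mean profiles -> signed correlation -> wTO ->
    thresholded positive/negative edge sets."""
    profiles = spot_profiles(matrix, spot_map, gene_to_unit)
    adjacency = spot_adjacency(profiles, beta=beta)
    w = wto(adjacency)
    positive, negative = threshold_edges(w, tau)
    return WTONetwork(profiles, adjacency, w, positive, negative, tau)
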