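"""Self-organizing-map expression portraits.

Gene expression profiles (one profile = one gene's values across all samples)
are clustered onto a rectangular lattice of prototype profiles ("metagenes")
by classic online Kohonen training.  Co-expressed genes end up in nearby
units, so each sample's metagene values arranged on the grid form a 2-D
"portrait" of its transcriptome, and localized clusters of co-overexpressed
genes appear as spots on those portraits.

Unit indexing is row-major, 0-based, with row 0 at top; every module of the
package shares this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, warn_if_uncentered

__all__ = [
    "ExpressionSOM",
    "Portrait",
    "train_som",
    "best_matching_unit",
    "sample_portrait",
    "class_portrait",
    "mean_total_expression",
    "quantization_error",
]

MAX_UNITS = 10**6


@dataclass
class Portrait:
    """A sample's (or class-mean's) metagene values arranged on the grid."""

    sample_id: str
    values: np.ndarray  # (n_rows, n_cols)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


class ExpressionSOM(BaseEstimator):
    """Kohonen self-organizing map over gene expression profiles.

    Observations are genes, features are samples.  Training presents each
    gene profile in turn (reshuffled every epoch), finds its best-matching
    unit (BMU) by Euclidean distance and pulls all units toward the profile
    with a Gaussian neighborhood kernel centered on the BMU.  Learning rate
    and neighborhood radius decay exponentially over the run.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions (default 20 x 20).
    epochs : int
        Full passes over the genes (default 20).
    learning_rate : (float, float)
        Initial and final learning rate (default 0.5 -> 0.01).
    radius : (float or None, float)
        Initial and final neighborhood radius in grid units; initial None
        means max(n_rows, n_cols) / 2.
    random_state : int
        Seed for initialization and presentation order; training is
        bit-reproducible given (data, params, seed).

    Attributes
    ----------
    metagenes_ : ndarray of shape (n_units, n_samples)
        Prototype profiles, row-major unit order.
    gene_to_unit_ : pandas.Series
        Gene -> unit index under the final metagenes (BMU assignment).
    quantization_error_ : float
        Mean distance of each gene profile to its BMU.
    """

    def __init__(
        self,
        n_rows: int = 20,
        n_cols: int = 20,
        epochs: int = 20,
        learning_rate: tuple[float, float] = (0.5, 0.01),
        radius: tuple[float | None, float] = (None, 0.5),
        random_state: int = 0,
    ) -> None:
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.radius = radius
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def _grid_coords(self) -> np.ndarray:
        rows, cols = np.divmod(np.arange(self.n_units), self.n_cols)
        return np.column_stack([rows, cols]).astype(float)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, ExpressionMatrix):
            return X.data
        return pd.DataFrame(X)

    # -- estimator API ---------------------------------------------------------
    def fit(self, X, y=None) -> "ExpressionSOM":
        frame = self._as_frame(X)
        data = frame.to_numpy(dtype=float)
        n_genes, n_samples = data.shape
        if n_genes < 1:
            raise ValueError("need at least one gene profile")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_units > MAX_UNITS:
            raise ValueError(f"grid of {self.n_units} units exceeds {MAX_UNITS}")
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite values in input")
        if isinstance(X, ExpressionMatrix):
            warn_if_uncentered(X)

        rng = np.random.default_rng(self.random_state)
        lr0, lr1 = self.learning_rate
        r0, r1 = self.radius
        if r0 is None:
            r0 = max(self.n_rows, self.n_cols) / 2.0
        r0 = max(float(r0), 1e-9)
        r1 = max(float(r1), 1e-9)

        # init: uniform random sample of gene profiles
        init_idx = rng.choice(n_genes, size=self.n_units, replace=n_genes < self.n_units)
        metagenes = data[init_idx].astype(float).copy()

        coords = self._grid_coords()
        # pairwise squared grid distances, computed once
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

        total_steps = max(self.epochs * n_genes - 1, 1)
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n_genes)
            for g in order:
                frac = step / total_steps
                lr = lr0 * (lr1 / lr0) ** frac
                rad = r0 * (r1 / r0) ** frac
                x = data[g]
                d2 = ((metagenes - x) ** 2).sum(axis=1)
                bmu = int(np.argmin(d2))
                h = lr * np.exp(-grid_d2[bmu] / (2.0 * rad * rad))
                active = h > 1e-9
                metagenes[active] += h[active, None] * (x - metagenes[active])
                step += 1

        self.metagenes_ = metagenes
        self.n_features_in_ = n_samples
        self.sample_ids_ = list(frame.columns)
        bmus = self._bmu_batch(data)
        self.gene_to_unit_ = pd.Series(bmus, index=frame.index, name="unit")
        self.quantization_error_ = float(
            np.sqrt(((data - metagenes[bmus]) ** 2).sum(axis=1)).mean()
        )
        return self

    def _bmu_batch(self, data: np.ndarray) -> np.ndarray:
        # argmin of Euclidean distance; np.argmin breaks ties toward the
        # lowest row-major index
        d2 = (
            (data**2).sum(axis=1, keepdims=True)
            - 2.0 * data @ self.metagenes_.T
            + (self.metagenes_**2).sum(axis=1)[None, :]
        )
        return d2.argmin(axis=1)

    def predict(self, X) -> np.ndarray:
        """Best-matching unit index for each profile in X."""
        check_is_fitted(self, "metagenes_")
        data = self._as_frame(X).to_numpy(dtype=float)
        if data.shape[1] != self.n_features_in_:
            raise ValueError(
                f"profile length {data.shape[1]} != {self.n_features_in_} samples"
            )
        return self._bmu_batch(data)

    def transform(self, X) -> np.ndarray:
        """Map profiles to their BMU grid coordinates (row, col)."""
        units = self.predict(X)
        return np.column_stack(np.divmod(units, self.n_cols))

    def unit_coords(self, units) -> np.ndarray:
        return np.column_stack(np.divmod(np.asarray(units), self.n_cols))


def train_som(
    matrix: ExpressionMatrix,
    n_rows: int = 20,
    n_cols: int = 20,
    **params,
) -> ExpressionSOM:
    """Train an :class:`ExpressionSOM` on a (centered) expression matrix."""
    som = ExpressionSOM(n_rows=n_rows, n_cols=n_cols, **params)
    return som.fit(matrix)


def best_matching_unit(profile, som: ExpressionSOM) -> int:
    """Unit index minimizing Euclidean distance to `profile`; ties break to
    the lowest row-major index."""
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.shape[0] != som.n_features_in_:
        raise ValueError(
            f"profile length {profile.shape} does not match {som.n_features_in_} samples"
        )
    d2 = ((som.metagenes_ - profile) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def sample_portrait(som: ExpressionSOM, sample_id: str) -> Portrait:
    """Portrait of one sample: its metagene values arranged on the grid."""
    check_is_fitted(som, "metagenes_")
    try:
        j = som.sample_ids_.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample: {sample_id!r}") from None
    grid = som.metagenes_[:, j].reshape(som.n_rows, som.n_cols)
    return Portrait(sample_id, grid.copy())


def class_portrait(som: ExpressionSOM, matrix: ExpressionMatrix, label: str) -> Portrait:
    """Mean portrait over all samples of one class."""
    samples = matrix.samples_of_class(label)
    stack = np.stack([sample_portrait(som, s).values for s in samples])
    return Portrait(label, stack.mean(axis=0))


def mean_total_expression(portraits: list[Portrait]) -> pd.Series:
    """Per portrait, the arithmetic mean over all grid units.

    Computed on the sample portraits of a non-centered map this summarizes a
    sample's overall transcriptional activity.
    """
    if not portraits:
        raise ValueError("no portraits given")
    shape = portraits[0].values.shape
    for p in portraits:
        if p.values.shape != shape:
            raise ValueError("portraits do not share one grid")
    return pd.Series(
        {p.sample_id: float(p.values.mean()) for p in portraits}, name="mean_total"
    )


def quantization_error(som: ExpressionSOM, matrix: ExpressionMatrix) -> float:
    """Mean Euclidean distance of each gene profile to its BMU."""
    data = matrix.values
    bmus = som.predict(matrix)
    return float(np.sqrt(((data - som.metagenes_[bmus]) ** 2).sum(axis=1)).mean())
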