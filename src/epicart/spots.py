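"""Overexpression spot detection, map segmentation and gene-group enrichment.

A "spot" is an 8-connected cluster of adjacently located map units that are
co-overexpressed: per sample portrait, units at or above a high quantile of
that portrait's values are marked, and connected components of the union of
marks across the cohort become spots, labeled 'A', 'B', ... in order of
decreasing peak support.  The map is additionally segmented into four corner
quadrants (Q1 top-left, Q2 top-right, Q3 bottom-right, Q4 bottom-left) and a
central zone Z of near-invariant genes, and annotated gene groups can be
counted and tested for enrichment (one-sided Fisher exact) per region or
within the spots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix
from .som import ExpressionSOM, Portrait, class_portrait

__all__ = [
    "Spot",
    "SpotMap",
    "Segmentation",
    "EnrichmentResult",
    "SpotDetector",
    "overexpression_summary_map",
    "detect_spots",
    "segment_map",
    "count_by_region",
    "fisher_enrichment",
    "variance_map",
    "invariant_units",
    "spot_genes",
    "associate_spot_classes",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def _spot_label(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', ... (spreadsheet-style)."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


@dataclass
class Spot:
    label: str
    units: frozenset[int]  # row-major unit indices
    peak: float  # peak summary value over the spot's units
    classes: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.units)


@dataclass
class SpotMap:
    """Labeled disjoint spots on a grid."""

    n_rows: int
    n_cols: int
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for spot in self.spots:
            if seen & spot.units:
                raise ValueError("spot unit sets must be disjoint")
            seen |= spot.units

    @property
    def labels(self) -> dict[int, str]:
        return {u: s.label for s in self.spots for u in s.units}

    def label_grid(self) -> np.ndarray:
        grid = np.full((self.n_rows, self.n_cols), "", dtype=object)
        for spot in self.spots:
            for u in spot.units:
                grid[divmod(u, self.n_cols)] = spot.label
        return grid

    def __getitem__(self, label: str) -> Spot:
        for spot in self.spots:
            if spot.label == label:
                return spot
        raise KeyError(label)

    def __len__(self) -> int:
        return len(self.spots)


def portrait_marks(portraits: list[Portrait], q: float = 0.98) -> np.ndarray:
    """Per portrait, mark the units at or above that portrait's q-quantile.

    Quantile rule is the lower empirical quantile (type 1, inverse CDF); ties
    at the cut are included.  Returns a boolean (n_portraits, rows, cols)
    stack.
    """
    if not portraits:
        raise ValueError("need at least one portrait")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    shape = portraits[0].values.shape
    marks = np.zeros((len(portraits),) + shape, dtype=bool)
    for i, p in enumerate(portraits):
        if p.values.shape != shape:
            raise ValueError("portraits do not share one grid")
        cut = np.quantile(p.values, q, method="inverted_cdf")
        marks[i] = p.values >= cut
    return marks


def overexpression_summary_map(
    portraits: list[Portrait], q: float = 0.98
) -> tuple[np.ndarray, np.ndarray]:
    """Overexpression support across the cohort.

    Returns (summary, binary): the fraction of portraits marking each unit
    and the union of marks (see :func:`portrait_marks` for the marking rule).
    """
    marks = portrait_marks(portraits, q)
    return marks.mean(axis=0), marks.any(axis=0)


def detect_spots(
    binary: np.ndarray,
    min_size: int = 4,
    summary: np.ndarray | None = None,
) -> SpotMap:
    """8-connected components of marked units with >= min_size units.

    Spots are labeled 'A', 'B', ... in order of decreasing peak summary value
    (component size, then lowest unit index, break ties); smaller components
    are discarded.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ValueError("binary grid must be 2-D")
    if min_size < 1:
        raise ValueError("min_size must be positive")
    if summary is None:
        summary = binary.astype(float)
    summary = np.asarray(summary, dtype=float)
    if summary.shape != binary.shape:
        raise ValueError("summary and binary grids differ in shape")

    labeled, n_comp = ndimage.label(binary, structure=EIGHT_CONNECTED)
    n_rows, n_cols = binary.shape
    candidates = []
    for comp in range(1, n_comp + 1):
        mask = labeled == comp
        if int(mask.sum()) < min_size:
            continue
        units = frozenset(int(u) for u in np.flatnonzero(mask.ravel()))
        peak = float(summary[mask].max())
        candidates.append((units, peak))
    candidates.sort(key=lambda c: (-c[1], -len(c[0]), min(c[0])))
    spots = [
        Spot(label=_spot_label(i), units=units, peak=peak)
        for i, (units, peak) in enumerate(candidates)
    ]
    return SpotMap(n_rows, n_cols, spots)


class SpotDetector(BaseEstimator):
    """Estimator: fit on a list of portraits, expose the spot map.

    A spot is a cluster of units co-overexpressed in a certain sample class,
    so detection filters the raw union of per-portrait marks by support
    before extracting connected components:

    * with class labels (``fit(portraits, y=labels)``): a unit is kept when
      at least ``class_majority`` of some class's portraits mark it — units
      marked only sporadically, or by scattered samples of many classes
      (bridges between adjacent spots), are dropped;
    * without labels: a unit is kept when at least ``min_support`` of all
      portraits mark it (single-sample marks are almost always noise).

    Set ``min_support=0`` and ``y=None`` to segment the raw union.

    Fitted attributes: ``summary_map_`` (fraction of portraits marking each
    unit), ``binary_map_`` (union of marks), ``detection_map_`` (the
    support-filtered binary actually segmented) and ``spot_map_``.
    """

    def __init__(self, q: float = 0.98, min_size: int = 4,
                 min_support: float = 0.05, class_majority: float = 0.5) -> None:
        self.q = q
        self.min_size = min_size
        self.min_support = min_support
        self.class_majority = class_majority

    def fit(self, X: list[Portrait], y=None) -> "SpotDetector":
        marks = portrait_marks(X, self.q)
        self.summary_map_ = marks.mean(axis=0)
        self.binary_map_ = marks.any(axis=0)
        if y is not None:
            y = np.asarray(y)
            if len(y) != len(X):
                raise ValueError("y must give one class label per portrait")
            keep = np.zeros_like(self.binary_map_)
            for label in np.unique(y):
                class_support = marks[y == label].mean(axis=0)
                keep |= class_support >= self.class_majority
            self.detection_map_ = self.binary_map_ & keep
        elif self.min_support > 0:
            self.detection_map_ = self.binary_map_ & (
                self.summary_map_ >= self.min_support
            )
        else:
            self.detection_map_ = self.binary_map_
        self.spot_map_ = detect_spots(
            self.detection_map_, self.min_size, self.summary_map_
        )
        return self


@dataclass
class Segmentation:
    """Partition of the grid into quadrants Q1-Q4 and central zone Z."""

    n_rows: int
    n_cols: int
    central_fraction: float
    region_of_unit: np.ndarray  # (n_rows, n_cols) of {'Q1','Q2','Q3','Q4','Z'}

    def units_of(self, region: str) -> frozenset[int]:
        mask = self.region_of_unit == region
        return frozenset(int(u) for u in np.flatnonzero(mask.ravel()))

    @property
    def regions(self) -> tuple[str, ...]:
        return ("Q1", "Q2", "Q3", "Q4", "Z")


def segment_map(n_rows: int, n_cols: int, central_fraction: float = 1 / 3) -> Segmentation:
    """Segment the grid: Z is the centered rectangle of side
    ceil(central_fraction * dim) per dimension; the remainder splits into the
    four corner quadrants (Q1 top-left, Q2 top-right, Q3 bottom-right, Q4
    bottom-left)."""
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    if not 0.0 < central_fraction < 1.0:
        raise ValueError("central_fraction must lie in (0, 1)")
    z_r = math.ceil(central_fraction * n_rows)
    z_c = math.ceil(central_fraction * n_cols)
    r0 = (n_rows - z_r) // 2
    c0 = (n_cols - z_c) // 2
    region = np.empty((n_rows, n_cols), dtype=object)
    for r in range(n_rows):
        top = r < n_rows / 2
        for c in range(n_cols):
            left = c < n_cols / 2
            if top:
                region[r, c] = "Q1" if left else "Q2"
            else:
                region[r, c] = "Q4" if left else "Q3"
    region[r0 : r0 + z_r, c0 : c0 + z_c] = "Z"
    return Segmentation(n_rows, n_cols, central_fraction, region)


def spot_genes(spot: Spot, gene_to_unit: pd.Series) -> list[str]:
    """Genes whose BMU lies within the spot's units."""
    return list(gene_to_unit.index[gene_to_unit.isin(spot.units)])


def count_by_region(
    gene_to_unit: pd.Series,
    regions,
    annotated,
    invariant: frozenset[int] | None = None,
) -> pd.DataFrame:
    """Count total and annotated genes per region (or per spot).

    `regions` is a Segmentation, a SpotMap, or a mapping region -> unit set.
    Annotated genes absent from the assignment are dropped with a warning.
    When an invariant unit set is supplied, genes in those units are counted
    under an extra 'Inv' class instead of their region.
    """
    if isinstance(regions, Segmentation):
        region_units = {r: regions.units_of(r) for r in regions.regions}
    elif isinstance(regions, SpotMap):
        region_units = {s.label: s.units for s in regions.spots}
        region_units["none"] = frozenset(
            set(range(regions.n_rows * regions.n_cols))
            - set().union(*[s.units for s in regions.spots], set())
        )
    else:
        region_units = {k: frozenset(v) for k, v in dict(regions).items()}

    annotated = set(annotated)
    unknown = annotated - set(gene_to_unit.index)
    if unknown:
        warnings.warn(
            f"{len(unknown)} annotated genes absent from the matrix were dropped",
            stacklevel=2,
        )
        annotated -= unknown

    rows = {}
    for region, units in region_units.items():
        in_region = gene_to_unit.index[gene_to_unit.isin(units)]
        if invariant is not None and region != "Inv":
            in_region = in_region[~gene_to_unit.loc[in_region].isin(invariant)]
        rows[region] = {
            "total": len(in_region),
            "annotated": len(annotated & set(in_region)),
        }
    if invariant is not None:
        in_inv = gene_to_unit.index[gene_to_unit.isin(invariant)]
        rows["Inv"] = {"total": len(in_inv), "annotated": len(annotated & set(in_inv))}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class EnrichmentResult:
    """One-sided (greater) Fisher exact enrichment of an annotated group."""

    contingency: np.ndarray  # 2x2: [[overlap, region-only], [annot-only, rest]]
    odds_ratio: float
    p_value: float

    direction: str = "greater"


def fisher_enrichment(
    n_in_region_annot: int, n_in_region: int, n_annot: int, n_universe: int
) -> EnrichmentResult:
    """One-sided Fisher exact test for overrepresentation.

    The p-value is the upper hypergeometric tail P(X >= overlap) with X ~
    Hypergeom(universe, annotated, region); the odds ratio comes from the 2x2
    table.  Inconsistent margins raise.
    """
    k, n, K, N = n_in_region_annot, n_in_region, n_annot, n_universe
    table = np.array([[k, n - k], [K - k, N - n - K + k]], dtype=int)
    if (table < 0).any() or min(k, n, K, N) < 0 or max(n, K) > N:
        raise ValueError(
            f"inconsistent margins: overlap={k}, region={n}, annotated={K}, universe={N}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = table.ravel()
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = a * d / (b * c)
    return EnrichmentResult(table, float(odds), min(p, 1.0))


def variance_map(som: ExpressionSOM) -> np.ndarray:
    """Per unit, the (population) variance of its metagene profile across
    samples; near-zero-variance units hold genes of invariant expression."""
    var = som.metagenes_.var(axis=1)
    return var.reshape(som.n_rows, som.n_cols)


def invariant_units(variance_grid: np.ndarray, q: float = 0.25) -> frozenset[int]:
    """Units whose metagene variance lies at or below the q-quantile of unit
    variances (lower empirical quantile; ties included)."""
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    flat = np.asarray(variance_grid, dtype=float).ravel()
    cut = np.quantile(flat, q, method="inverted_cdf")
    return frozenset(int(u) for u in np.flatnonzero(flat <= cut))


def associate_spot_classes(
    spot_map: SpotMap,
    som: ExpressionSOM,
    matrix: ExpressionMatrix,
    within: float = 0.9,
) -> SpotMap:
    """Associate each spot with the sample classes overexpressing it.

    A class is associated when its class-portrait mean over the spot's units
    is positive and within `within` of the maximal class mean.  Returns a new
    SpotMap with the `classes` fields filled.
    """
    labels = matrix.class_labels()
    class_means = {
        lab: class_portrait(som, matrix, lab).values.ravel() for lab in labels
    }
    spots = []
    for spot in spot_map.spots:
        idx = np.array(sorted(spot.units))
        means = {lab: float(class_means[lab][idx].mean()) for lab in labels}
        top = max(means.values())
        assoc = tuple(
            lab for lab in labels if means[lab] > 0 and means[lab] >= within * top
        )
        spots.append(Spot(spot.label, spot.units, spot.peak, assoc))
    return SpotMap(spot_map.n_rows, spot_map.n_cols, spots)
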