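"""Spot detection, segmentation, region counts, Fisher enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import epicart as ec
from epicart.som import ExpressionSOM


def _portrait(values, name="p"):
    return ec.Portrait(name, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# overexpression marking


class TestSummaryMap:
    def test_distinct_values_q98_marks_three_of_hundred(self):
        vals = np.arange(1, 101).reshape(10, 10)
        summary, binary = ec.overexpression_summary_map([_portrait(vals)], q=0.98)
        assert binary.sum() == 3  # lower empirical quantile cut at 98
        assert summary[binary].tolist() == [1.0, 1.0, 1.0]

    def test_small_q_marks_all(self):
        vals = np.arange(9).reshape(3, 3)
        _, binary = ec.overexpression_summary_map([_portrait(vals)], q=1e-9)
        assert binary.all()

    def test_constant_portrait_marks_all(self):
        _, binary = ec.overexpression_summary_map([_portrait(np.ones((4, 4)))], q=0.98)
        assert binary.all()

    def test_q_bounds(self):
        with pytest.raises(ValueError):
            ec.overexpression_summary_map([_portrait(np.ones((2, 2)))], q=1.0)


# ---------------------------------------------------------------------------
# connected components


def _flood_fill_components(binary):
    """Independent 8-connectivity oracle: breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    rows, cols = binary.shape
    for r in range(rows):
        for c in range(cols):
            if binary[r, c] and not seen[r, c]:
                queue, comp = [(r, c)], set()
                seen[r, c] = True
                while queue:
                    rr, cc = queue.pop()
                    comp.add(rr * cols + cc)
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (
                                0 <= nr < rows and 0 <= nc < cols
                                and binary[nr, nc] and not seen[nr, nc]
                            ):
                                seen[nr, nc] = True
                                queue.append((nr, nc))
                comps.append(frozenset(comp))
    return comps


class TestDetectSpots:
    def test_two_blocks(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[0:3, 0:3] = grid[6:9, 6:9] = True
        spot_map = ec.detect_spots(grid, min_size=4)
        assert len(spot_map) == 2
        assert sorted(s.size for s in spot_map.spots) == [9, 9]
        assert [s.label for s in spot_map.spots] == ["A", "B"]

    def test_min_size_filters_singleton(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        assert len(ec.detect_spots(grid, min_size=4)) == 0

    def test_diagonal_chain_is_one_spot(self):
        grid = np.eye(6, dtype=bool)
        spot_map = ec.detect_spots(grid, min_size=4)
        assert len(spot_map) == 1
        assert spot_map.spots[0].units == _flood_fill_components(grid)[0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((12, 12)) < 0.3
        expected = {c for c in _flood_fill_components(grid) if len(c) >= 3}
        spot_map = ec.detect_spots(grid, min_size=3)
        assert {s.units for s in spot_map.spots} == expected

    def test_labels_ordered_by_peak(self):
        grid = np.zeros((8, 8), dtype=bool)
        grid[0:2, 0:2] = grid[5:7, 5:7] = True
        summary = np.zeros((8, 8))
        summary[5, 5] = 0.9  # second block has the higher peak
        summary[0, 0] = 0.4
        spot_map = ec.detect_spots(grid, min_size=2, summary=summary)
        assert spot_map["A"].peak == 0.9
        assert (5 * 8 + 5) in spot_map["A"].units

    def test_spot_sets_disjoint_and_connected(self, spot_map):
        all_units = [u for s in spot_map.spots for u in s.units]
        assert len(all_units) == len(set(all_units))
        grid = np.zeros((spot_map.n_rows, spot_map.n_cols), dtype=bool)
        for s in spot_map.spots:
            grid[:] = False
            for u in s.units:
                grid[divmod(u, spot_map.n_cols)] = True
            assert len(_flood_fill_components(grid)) == 1


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentation:
    def test_6x6_one_third(self):
        seg = ec.segment_map(6, 6, central_fraction=1 / 3)
        assert len(seg.units_of("Z")) == 4
        for q in ("Q1", "Q2", "Q3", "Q4"):
            assert len(seg.units_of(q)) == 8

    def test_quadrant_orientation(self):
        seg = ec.segment_map(6, 6, central_fraction=1 / 3)
        assert seg.region_of_unit[0, 0] == "Q1"
        assert seg.region_of_unit[0, 5] == "Q2"
        assert seg.region_of_unit[5, 5] == "Q3"
        assert seg.region_of_unit[5, 0] == "Q4"

    @pytest.mark.parametrize("n_rows,n_cols,frac", [
        (6, 6, 1e-9), (7, 5, 0.33), (20, 20, 1 / 3), (4, 9, 0.5),
    ])
    def test_regions_partition_grid(self, n_rows, n_cols, frac):
        seg = ec.segment_map(n_rows, n_cols, frac)
        total = sum(len(seg.units_of(r)) for r in seg.regions)
        assert total == n_rows * n_cols
        import math
        assert len(seg.units_of("Z")) == math.ceil(frac * n_rows) * math.ceil(
            frac * n_cols
        )

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            ec.segment_map(1, 5, 0.3)


# ---------------------------------------------------------------------------
# region counts


class TestCountByRegion:
    def test_all_genes_in_one_unit(self):
        seg = ec.segment_map(6, 6, 1 / 3)
        g2u = pd.Series(0, index=[f"g{i}" for i in range(10)])  # unit 0 is Q1
        counts = ec.count_by_region(g2u, seg, annotated=set())
        assert counts.loc["Q1", "total"] == 10
        assert counts.drop(index="Q1")["total"].eq(0).all()
        assert counts["annotated"].eq(0).all()

    def test_random_assignment_matches_brute_tally(self, rng):
        seg = ec.segment_map(6, 6, 1 / 3)
        genes = [f"g{i}" for i in range(100)]
        units = rng.integers(0, 36, size=100)
        g2u = pd.Series(units, index=genes)
        annotated = set(rng.choice(genes, size=30, replace=False))
        counts = ec.count_by_region(g2u, seg, annotated)
        region_lookup = seg.region_of_unit.ravel()
        for region in seg.regions:
            expect_total = sum(region_lookup[u] == region for u in units)
            expect_annot = sum(
                region_lookup[u] == region
                for g, u in zip(genes, units)
                if g in annotated
            )
            assert counts.loc[region, "total"] == expect_total
            assert counts.loc[region, "annotated"] == expect_annot
        assert counts["total"].sum() == 100

    def test_unknown_annotated_genes_warn(self):
        seg = ec.segment_map(4, 4, 0.5)
        g2u = pd.Series({"g1": 0})
        with pytest.warns(UserWarning, match="absent"):
            counts = ec.count_by_region(g2u, seg, {"g1", "ghost"})
        assert counts["annotated"].sum() == 1

    def test_invariant_units_counted_separately(self):
        seg = ec.segment_map(4, 4, 0.5)
        g2u = pd.Series({"g1": 0, "g2": 0, "g3": 15})
        counts = ec.count_by_region(g2u, seg, {"g3"}, invariant=frozenset({0}))
        assert counts.loc["Inv", "total"] == 2
        assert counts.loc["Q1", "total"] == 0
        assert counts.loc["Q3", "total"] == 1
        assert counts["total"].sum() == 3


# ---------------------------------------------------------------------------
# Fisher enrichment


def _enumeration_p(k, n, K, N):
    """Exact upper-tail hypergeometric by integer enumeration (oracle)."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return float(acc)


class TestFisherEnrichment:
    def test_fully_overlapping_region(self):
        res = ec.fisher_enrichment(4, 4, 4, 8)
        assert res.p_value == pytest.approx(1 / 70, abs=1e-15)

    def test_overlap_at_expectation(self):
        res = ec.fisher_enrichment(1, 2, 2, 4)
        assert res.p_value == pytest.approx(5 / 6, abs=1e-15)

    def test_annotated_equals_universe(self):
        assert ec.fisher_enrichment(3, 3, 10, 10).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [(5, 4, 4, 8), (1, 2, 9, 8), (2, 9, 4, 8)])
    def test_inconsistent_margins(self, bad):
        with pytest.raises(ValueError, match="margins"):
            ec.fisher_enrichment(*bad)

    def test_matches_enumeration_all_small_tables(self):
        """Exact-fraction enumeration oracle over every table, universe <= 25."""
        worst = 0.0
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        p = ec.fisher_enrichment(k, n, K, N).p_value
                        worst = max(worst, abs(p - _enumeration_p(k, n, K, N)))
        assert worst < 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_fisher_exact(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 200))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
        res = ec.fisher_enrichment(k, n, K, N)
        table = [[k, n - k], [K - k, N - n - K + k]]
        _, p = sps.fisher_exact(table, alternative="greater")
        assert res.p_value == pytest.approx(p, abs=1e-10)


# ---------------------------------------------------------------------------
# variance map


class TestVarianceMap:
    def _som(self, metagenes, n_rows, n_cols):
        som = ExpressionSOM(n_rows=n_rows, n_cols=n_cols)
        som.metagenes_ = np.asarray(metagenes, dtype=float)
        som.n_features_in_ = som.metagenes_.shape[1]
        som.sample_ids_ = [f"s{j}" for j in range(som.n_features_in_)]
        return som

    def test_constant_metagenes_zero_variance(self):
        som = self._som(np.ones((4, 5)), 2, 2)
        assert not ec.variance_map(som).any()

    def test_two_unit_toy(self):
        som = self._som([[0.0, 0.0], [-1.0, 1.0]], 1, 2)
        var = ec.variance_map(som)
        np.testing.assert_allclose(var, [[0.0, 1.0]])  # population variance
        assert ec.invariant_units(var, q=0.5) == frozenset({0})

    def test_q_one_marks_all(self):
        som = self._som([[0.0, 1.0], [0.0, 2.0]], 1, 2)
        assert ec.invariant_units(ec.variance_map(som), q=1.0) == frozenset({0, 1})


# ---------------------------------------------------------------------------
# planted-structure recovery and class association


def test_detected_spots_recover_planted_modules(design, cohort, som, spot_map):
    matrix, truth = cohort
    assert len(spot_map) >= 4
    for module in design.modules:
        planted = set(truth.module_genes(module.module_id))
        best = max(
            len(set(ec.spot_genes(s, som.gene_to_unit_)) & planted)
            / len(set(ec.spot_genes(s, som.gene_to_unit_)) | planted)
            for s in spot_map.spots
        )
        assert best >= 0.5, f"{module.module_id}: best Jaccard {best:.2f}"


def test_spots_associate_with_their_up_class(design, cohort, som, spot_map, centered):
    matrix, truth = cohort
    associated = ec.associate_spot_classes(spot_map, som, centered)
    for module in design.modules:
        planted = set(truth.module_genes(module.module_id))
        spot = max(
            associated.spots,
            key=lambda s: len(set(ec.spot_genes(s, som.gene_to_unit_)) & planted),
        )
        assert module.up_classes[0] in spot.classes
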