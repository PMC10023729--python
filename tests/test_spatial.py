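"""Coverage density, linear-dipole g(r), contacts, association tests."""

import numpy as np
import pandas as pd
import pytest

from seerfish import cellmap as cm
from seerfish import spatial as sp


def _map_from_rows(rows, shape=(200, 200), pixel_size=0.25, mask=None):
    cells = pd.DataFrame(rows, columns=cm.CELL_COLUMNS)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return cm.CellMap(cells, mask, pixel_size)


class TestCoverageDensity:
    def test_no_cells_zero(self):
        cmap = _map_from_rows([])
        assert sp.coverage_density(cmap) == 0.0

    def test_single_cell_fraction(self):
        # 50x50 µm mask; ellipse area pi*5*2.5 ≈ 39.3 µm² ≈ 1.6% of 2500
        cmap = _map_from_rows([("c0", 25.0, 25.0, 5.0, 2.5, 0.0, "A")])
        expected = np.pi * 5.0 * 2.5 / 2500.0
        assert sp.coverage_density(cmap, "A") == pytest.approx(expected, rel=0.05)

    def test_additivity_for_disjoint_taxa(self):
        rows = [("c0", 12.0, 12.0, 3.0, 1.5, 0.0, "A"),
                ("c1", 38.0, 38.0, 3.0, 1.5, 0.5, "B")]
        cmap = _map_from_rows(rows)
        total = sp.coverage_density(cmap)
        assert total == pytest.approx(sp.coverage_density(cmap, "A")
                                      + sp.coverage_density(cmap, "B"), rel=1e-9)

    def test_empty_mask_rejected(self):
        cmap = _map_from_rows([], mask=np.zeros((10, 10), dtype=bool))
        with pytest.raises(ValueError):
            sp.coverage_density(cmap)


@pytest.fixture(scope="module")
def csr_map():
    return cm.random_cellmap(1000, ["A"], shape=(400, 400),
                             pixel_size=0.25, seed=7)


class TestPairCorrelation:
    def test_csr_auto_correlation_near_one(self, csr_map):
        curve = sp.pair_correlation(csr_map, "A", "A", [3, 5, 8, 12],
                                    n_dipoles=100_000, seed=3)
        assert np.all(np.abs(curve.g - 1.0) <= 0.05)

    def test_csr_cross_correlation_near_one(self):
        cmap = cm.random_cellmap(1600, ["A", "B"], shape=(400, 400),
                                 pixel_size=0.25, seed=9)
        curve = sp.pair_correlation(cmap, "A", "B", [4, 8], n_dipoles=200_000,
                                    seed=4)
        assert np.all(np.abs(curve.g - 1.0) <= 0.08)

    def test_clustered_exceeds_threshold_at_cluster_scale(self):
        cmap = cm.clustered_cellmap(60, 20, 3.0, ["A"], shape=(400, 400),
                                    pixel_size=0.25, seed=8)
        curve = sp.pair_correlation(cmap, "A", "A", [3.0], n_dipoles=50_000,
                                    seed=3)
        assert curve.g[0] > 1.2

    def test_symmetric_in_taxa(self):
        cmap = cm.random_cellmap(800, ["A", "B"], shape=(300, 300),
                                 pixel_size=0.25, seed=11)
        ab = sp.pair_correlation(cmap, "A", "B", [5.0], n_dipoles=20_000, seed=6)
        ba = sp.pair_correlation(cmap, "B", "A", [5.0], n_dipoles=20_000, seed=6)
        assert ab.g[0] == ba.g[0]

    def test_missing_taxon_rejected(self, csr_map):
        with pytest.raises(ValueError):
            sp.pair_correlation(csr_map, "A", "Z", [5.0], n_dipoles=1000)

    def test_confidence_band_covers_estimate(self, csr_map):
        curve = sp.pair_correlation(csr_map, "A", "A", [5.0], n_dipoles=20_000,
                                    seed=3, ci=True, n_boot=100)
        assert curve.ci_low[0] <= curve.g[0] <= curve.ci_high[0]


class TestContactAnalysis:
    def test_two_distant_cells_zero_events(self):
        rows = [("c0", 5.0, 5.0, 1.0, 0.4, 0.0, "A"),
                ("c1", 45.0, 45.0, 1.0, 0.4, 0.0, "B")]
        cmap = _map_from_rows(rows)
        results = sp.contact_analysis(cmap, n_sims=10, seed=0)
        ab = [r for r in results if (r.taxon_a, r.taxon_b) == ("A", "B")][0]
        assert ab.events == 0
        assert ab.frequency == 0.0

    def test_touching_cells_counted(self):
        rows = [("c0", 20.0, 20.0, 1.0, 0.4, 0.0, "A"),
                ("c1", 21.8, 20.0, 1.0, 0.4, 0.0, "B")]
        cmap = _map_from_rows(rows)
        results = sp.contact_analysis(cmap, n_sims=10, seed=0)
        ab = [r for r in results if (r.taxon_a, r.taxon_b) == ("A", "B")][0]
        assert ab.events == 1

    def test_shared_microcolonies_significant(self):
        cmap = cm.clustered_cellmap(25, 8, 1.5, ["A", "B"], shape=(400, 400),
                                    pixel_size=0.25, taxa_mixing="paired",
                                    seed=42)
        results = sp.contact_analysis(cmap, n_sims=60, seed=1)
        ab = [r for r in results if (r.taxon_a, r.taxon_b) == ("A", "B")][0]
        assert ab.fold > 1
        assert ab.significant

    def test_random_layout_rarely_significant(self):
        # null calibration: a CSR layout should essentially never reject
        cmap = cm.random_cellmap(150, ["A", "B"], shape=(300, 300),
                                 pixel_size=0.25, seed=13)
        results = sp.contact_analysis(cmap, n_sims=60, seed=2)
        assert not any(r.significant for r in results)


@pytest.fixture(scope="module")
def csr_roots():
    return [cm.random_cellmap(300, ["A", "B", "C"], shape=(400, 400),
                              pixel_size=0.25, seed=100 + i)
            for i in range(10)]


class TestAssociationAnalysis:
    def test_null_fold_near_one(self, csr_roots):
        results = sp.association_analysis(csr_roots, range_um=10, n_perm=100,
                                          seed=5)
        for r in results:
            assert not r.dropped
            assert abs(r.fold - 1.0) <= 0.1
            assert not r.significant

    def test_abundances_conserved_under_permutation(self):
        # permuting labels must leave cell count and per-taxon abundance intact
        rng = np.random.default_rng(0)
        labels = np.array([0] * 30 + [1] * 50 + [2] * 20)
        perm = rng.permutation(labels)
        assert len(perm) == len(labels)
        assert np.array_equal(np.bincount(perm), np.bincount(labels))

    def test_single_taxon_map_tests_no_pairs(self):
        maps = [cm.random_cellmap(100, ["A"], shape=(200, 200),
                                  pixel_size=0.25, seed=1)]
        results = sp.association_analysis(maps, seed=0)
        assert results == []

    def test_planted_pairs_fold_above_one(self):
        maps = [cm.clustered_cellmap(30, 10, 2.0, ["A", "B", "C", "D"],
                                     shape=(400, 400), pixel_size=0.25,
                                     taxa_mixing="paired", seed=200 + i)
                for i in range(5)]
        results = sp.association_analysis(maps, range_um=10, n_perm=100, seed=6)
        by_pair = {(r.taxon_a, r.taxon_b): r for r in results}
        assert by_pair[("A", "B")].fold > 1.2
        assert by_pair[("C", "D")].fold > 1.2
        assert by_pair[("A", "C")].fold < 1.0

    def test_low_event_pairs_dropped(self):
        rows = [("c0", 10.0, 10.0, 1.0, 0.4, 0.0, "A"),
                ("c1", 12.0, 10.0, 1.0, 0.4, 0.0, "B"),
                ("c2", 40.0, 40.0, 1.0, 0.4, 0.0, "A"),
                ("c3", 42.0, 40.0, 1.0, 0.4, 0.0, "B")]
        maps = [_map_from_rows(rows)]
        results = sp.association_analysis(maps, range_um=10, min_events=5, seed=0)
        ab = [r for r in results if (r.taxon_a, r.taxon_b) == ("A", "B")][0]
        assert ab.dropped
        assert "min_events" in ab.drop_reason

    def test_fold_scale_invariance(self):
        base = cm.clustered_cellmap(20, 8, 2.0, ["A", "B"], shape=(400, 400),
                                    pixel_size=0.25, taxa_mixing="paired",
                                    seed=77)
        scaled_cells = base.cells.copy()
        for col in ("x_um", "y_um", "a_um", "b_um"):
            scaled_cells[col] *= 2
        scaled = cm.CellMap(scaled_cells, np.ones((800, 800), bool), 0.25)
        r1 = sp.association_analysis([base], range_um=10, n_perm=20, seed=3)
        r2 = sp.association_analysis([scaled], range_um=20, n_perm=20, seed=3)
        obs1 = {(r.taxon_a, r.taxon_b): r.observed for r in r1}
        obs2 = {(r.taxon_a, r.taxon_b): r.observed for r in r2}
        assert obs1 == obs2

    def test_monotone_power_in_planted_strength(self):
        folds = []
        for fidelity in (0.0, 0.5, 1.0):
            maps = [cm.clustered_cellmap(30, 10, 2.0, ["A", "B", "C", "D"],
                                         shape=(400, 400), pixel_size=0.25,
                                         taxa_mixing="paired",
                                         pair_fidelity=fidelity, seed=300 + i)
                    for i in range(3)]
            res = sp.association_analysis(maps, range_um=10, n_perm=50, seed=7)
            ab = [r for r in res if (r.taxon_a, r.taxon_b) == ("A", "B")][0]
            folds.append(ab.fold)
        assert folds[0] < folds[1] < folds[2]


class TestDifferentialAssociation:
    def _clustered_group(self, fidelity, seed0, n_roots=6):
        return [cm.clustered_cellmap(30, 10, 2.0, ["A", "B", "C", "D"],
                                     shape=(400, 400), pixel_size=0.25,
                                     taxa_mixing="paired",
                                     pair_fidelity=fidelity, seed=seed0 + i)
                for i in range(n_roots)]

    def test_identical_groups_zero_fold_no_hits(self):
        maps = self._clustered_group(0.5, 400)
        res = sp.association_analysis(maps, n_perm=50, seed=1)
        diff = sp.differential_association(res, res)
        for d in diff:
            if d.applicable:
                assert d.log2_fold_change == 0.0
                assert not d.significant

    def test_log2_identity_on_doubled_folds(self):
        res = sp.association_analysis(self._clustered_group(0.5, 400),
                                      n_perm=50, seed=1)
        doubled = []
        for r in res:
            d = sp.AssociationResult(
                taxon_a=r.taxon_a, taxon_b=r.taxon_b, observed=r.observed * 2,
                null_mean=r.null_mean, fold=r.fold * 2,
                per_root_folds=[f * 2 for f in r.per_root_folds],
                p_value=r.p_value, dropped=r.dropped)
            doubled.append(d)
        diff = sp.differential_association(doubled, res)
        for d in diff:
            if d.applicable:
                assert d.log2_fold_change == pytest.approx(1.0)

    def test_missing_pair_flagged_not_applicable(self):
        res = sp.association_analysis(self._clustered_group(0.5, 400),
                                      n_perm=50, seed=1)
        partial = [r for r in res if (r.taxon_a, r.taxon_b) != ("A", "B")]
        diff = sp.differential_association(partial, res)
        ab = [d for d in diff if (d.taxon_a, d.taxon_b) == ("A", "B")][0]
        assert not ab.applicable

    def test_planted_shift_detected(self):
        rc = sp.association_analysis(self._clustered_group(0.3, 400),
                                     n_perm=50, seed=1)
        rt = sp.association_analysis(self._clustered_group(0.9, 500),
                                     n_perm=50, seed=2)
        diff = sp.differential_association(rt, rc)
        ab = [d for d in diff if (d.taxon_a, d.taxon_b) == ("A", "B")][0]
        assert ab.applicable
        assert ab.log2_fold_change > 0
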