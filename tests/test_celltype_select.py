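import math

import numpy as np
import pytest
from scipy import sparse

from deltabind.celltype_select import (
    CellTypeMotifSet,
    DeviationResult,
    MotifEnrichment,
    call_marker_peaks,
    enrich_motifs,
    expression_filter,
    marker_region_ids,
    motif_deviation,
    select_motifs,
    upper_tail_hypergeom,
)
from deltabind.io_formats import CountMatrix


def make_matrix(counts, cell_types, donors, feature_prefix="p"):
    counts = np.asarray(counts)
    n_cells, n_feat = counts.shape
    return CountMatrix(
        sparse.csr_matrix(counts),
        [f"c{i}" for i in range(n_cells)],
        [f"{feature_prefix}{j}" for j in range(n_feat)],
        list(cell_types),
        list(donors),
    )


def simulate_atac(rng, n_donors=10, cells_per=20, n_peaks=100, n_marker=10, fold=8.0):
    """Two cell types; peaks [0, n_marker) elevated in type A, the next
    n_marker peaks elevated in type B (so background matching has peaks of
    comparable mean accessibility that are not elevated in A)."""
    cell_types, donors = [], []
    for ct in ("A", "B"):
        for d in range(n_donors):
            for _ in range(cells_per):
                cell_types.append(ct)
                donors.append(f"d{d}")
    n_cells = len(cell_types)
    mean = np.full((n_cells, n_peaks), 0.3)
    rows_a = np.asarray(cell_types) == "A"
    mean[np.ix_(rows_a, np.arange(n_marker))] *= fold
    mean[np.ix_(~rows_a, np.arange(n_marker, 2 * n_marker))] *= fold
    counts = rng.poisson(mean)
    return make_matrix(counts, cell_types, donors), [f"p{j}" for j in range(n_marker)]


class TestMarkerPeaks:
    def test_planted_markers_recovered(self, rng):
        atac, truth = simulate_atac(rng)
        results = call_marker_peaks(atac, "A")
        found = marker_region_ids(results)
        assert len(found & set(truth)) >= 9
        # and nothing called in the flat background
        assert len(found - set(truth)) == 0

    def test_identical_distributions_not_marker(self, rng):
        counts = rng.poisson(1.0, size=(80, 20))
        cts = ["A"] * 40 + ["B"] * 40
        donors = [f"d{i % 8}" for i in range(80)]
        atac = make_matrix(counts, cts, donors)
        results = call_marker_peaks(atac, "A")
        assert marker_region_ids(results) == set()
        assert all(r.pvalue > 0.001 for r in results)

    def test_absent_cell_type_is_error(self, rng):
        atac, _ = simulate_atac(rng)
        with pytest.raises(KeyError):
            call_marker_peaks(atac, "Z")


class TestEnrichment:
    def test_closed_form_example(self):
        # universe 10, 5 markers, motif in 4 peaks all of them markers:
        # P(X >= 4) = C(5,4)C(5,0)/C(10,4) ... computed from the closed form
        annotations = {f"r{i}": ({"m"} if i < 4 else set()) for i in range(10)}
        markers = {f"r{i}" for i in range(5)}
        (res,) = enrich_motifs(annotations, markers)
        expected = (math.comb(5, 4) * math.comb(5, 0)) / math.comb(10, 4)
        assert res.pvalue_hypergeom == pytest.approx(expected)
        assert expected == pytest.approx(5 / 210)

    def test_motif_absent_from_markers_has_p_one(self):
        annotations = {"r0": {"m"}, "r1": set(), "r2": set()}
        (res,) = enrich_motifs(annotations, {"r1", "r2"})
        assert res.pvalue_hypergeom == 1.0

    def test_boundary_pvalue_not_enriched(self):
        res = MotifEnrichment("A", "m", 100, 10, 10, 10, 1e-10)
        assert not res.is_enriched
        assert MotifEnrichment("A", "m", 100, 10, 10, 10, 0.99e-10).is_enriched

    def test_no_markers_is_error(self):
        with pytest.raises(ValueError, match="marker"):
            enrich_motifs({"r0": {"m"}}, set())

    def test_matches_combinatorial_oracle_small_universe(self):
        for M in (5, 12):
            for K in range(M + 1):
                for n in range(1, M + 1):
                    for k in range(min(K, n) + 1):
                        expected = sum(
                            math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
                            for x in range(k, min(K, n) + 1)
                        )
                        assert upper_tail_hypergeom(k, M, K, n) == pytest.approx(
                            expected, abs=1e-12
                        )


class TestDeviation:
    def test_random_motif_peaks_near_zero(self, rng):
        atac, _ = simulate_atac(rng, n_donors=5, cells_per=20, n_peaks=120)
        gc = {f"p{j}": float(rng.uniform(0.3, 0.7)) for j in range(120)}
        zs = []
        for seed in range(10):
            peaks = set(
                f"p{j}" for j in np.random.default_rng(seed).choice(120, 15, replace=False)
            )
            (res,) = motif_deviation(atac, {"m": peaks}, gc, "A", seed=seed)
            zs.append(res.deviation_z)
        assert abs(np.mean(zs)) < 0.5

    def test_planted_accessibility_gives_positive_z(self, rng):
        atac, markers = simulate_atac(rng, n_peaks=120, n_marker=15)
        gc = {f"p{j}": float(rng.uniform(0.3, 0.7)) for j in range(120)}
        (res,) = motif_deviation(atac, {"m": set(markers)}, gc, "A", seed=0)
        assert res.deviation_z > 1.0
        (res_b,) = motif_deviation(atac, {"m": set(markers)}, gc, "B", seed=0)
        assert res_b.deviation_z < res.deviation_z

    def test_too_few_background_sets_is_error(self, rng):
        atac, _ = simulate_atac(rng, n_donors=3, cells_per=5, n_peaks=30)
        with pytest.raises(ValueError, match="insufficient background"):
            motif_deviation(atac, {"m": {"p0"}}, {}, "A", n_background=1)

    def test_motif_without_peaks_is_error(self, rng):
        atac, _ = simulate_atac(rng, n_donors=3, cells_per=5, n_peaks=30)
        with pytest.raises(ValueError, match="0 peaks"):
            motif_deviation(atac, {"m": set()}, {}, "A")

    def test_seed_reproducible(self, rng):
        atac, markers = simulate_atac(rng, n_donors=4, cells_per=10, n_peaks=60, n_marker=8)
        gc = {f"p{j}": 0.5 for j in range(60)}
        a = motif_deviation(atac, {"m": set(markers)}, gc, "A", seed=3)
        b = motif_deviation(atac, {"m": set(markers)}, gc, "A", seed=3)
        assert a == b


class TestExpressionFilter:
    def _rna(self, frac_by_gene, n_cells=100):
        genes = list(frac_by_gene)
        counts = np.zeros((n_cells, len(genes)), dtype=int)
        for j, g in enumerate(genes):
            n_on = int(round(frac_by_gene[g] * n_cells))
            counts[:n_on, j] = 1
        return CountMatrix(
            sparse.csr_matrix(counts),
            [f"c{i}" for i in range(n_cells)], genes,
            ["A"] * n_cells, ["d0"] * n_cells,
        )

    def test_five_percent_inclusive(self):
        rna = self._rna({"TF1": 0.05})
        ok, fr = expression_filter(rna, "A", "TF1")
        assert ok and fr["TF1"] == pytest.approx(0.05)

    def test_below_threshold_fails(self):
        rna = self._rna({"TF1": 0.04})
        ok, _ = expression_filter(rna, "A", "TF1")
        assert not ok

    def test_dimer_requires_all_components(self):
        rna = self._rna({"FOSL2": 0.10, "JUN": 0.03})
        ok, fr = expression_filter(rna, "A", "FOSL2::JUN")
        assert not ok
        assert fr == {"FOSL2": pytest.approx(0.10), "JUN": pytest.approx(0.03)}

    def test_absent_gene_counts_as_zero(self):
        rna = self._rna({"TF1": 0.5})
        ok, fr = expression_filter(rna, "A", "GHOST")
        assert not ok and fr["GHOST"] == 0.0


class TestSelectMotifs:
    def _inputs(self):
        enr = [
            MotifEnrichment("A", "m1", 100, 10, 10, 10, 1e-15),
            MotifEnrichment("A", "m2", 100, 10, 10, 10, 1e-12),
            MotifEnrichment("A", "m3", 100, 10, 10, 10, 0.5),
        ]
        dev = [
            DeviationResult("A", "m1", 2.0),
            DeviationResult("A", "m2", 0.5),
            DeviationResult("A", "m3", 3.0),
        ]
        expr = {"m1": (True, {"g": 0.2}), "m2": (True, {"g": 0.2}), "m3": (True, {"g": 0.2})}
        return enr, dev, expr

    def test_all_three_filters_required(self):
        enr, dev, expr = self._inputs()
        sel = select_motifs("A", enr, dev, expr)
        assert sel.motifs == ["m1"]  # m2 fails deviation, m3 fails enrichment

    def test_expression_failure_excludes(self):
        enr, dev, expr = self._inputs()
        expr["m1"] = (False, {"g": 0.01})
        assert select_motifs("A", enr, dev, expr).motifs == []

    def test_lowering_zmin_never_shrinks(self, rng):
        enr, dev, expr = self._inputs()
        prev: set = set()
        for z_min in (3.0, 2.0, 1.0, 0.0, -1.0):
            cur = set(select_motifs("A", enr, dev, expr, z_min=z_min).motifs)
            assert prev <= cur
            prev = cur

    def test_selected_is_subset_of_enriched(self):
        enr, dev, expr = self._inputs()
        sel = select_motifs("A", enr, dev, expr, z_min=-10)
        enriched = {e.motif_id for e in enr if e.is_enriched}
        assert set(sel.motifs) <= enriched
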