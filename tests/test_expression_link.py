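import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from deltabind.expression_link import (
    GeneModel,
    apply_fdr,
    carrier_split,
    de_test_gene,
    filter_testable,
    map_snps_to_genes,
    pseudobulk,
)
from deltabind.io_formats import CountMatrix, Region
from deltabind.variants import SnpRecord


def snp(rsid="rs1", pos0=10_000):
    return SnpRecord(rsid, "chr1", pos0, "A", "G", 0.1, 1e-9)


def gene(gene_id="g1", tss=15_000):
    return GeneModel(gene_id, gene_id, "chr1", tss, "+")


class TestMapping:
    def test_promoter_window_link(self):
        links = map_snps_to_genes([snp(pos0=10_000)], [gene(tss=15_000)], window_bp=10_000)
        assert [(l.gene_id, l.evidence) for l in links] == [("g1", "promoter-window")]

    def test_interaction_pair_link(self):
        pair = (Region("chr1", 9_000, 11_000, "a"), Region("chr1", 99_000, 101_000, "b"))
        links = map_snps_to_genes(
            [snp(pos0=10_000)], [gene(tss=100_000)], window_bp=10_000,
            interaction_pairs=[pair],
        )
        assert [(l.gene_id, l.evidence) for l in links] == [("g1", "interaction-pair")]

    def test_distant_snp_unlinked(self):
        assert map_snps_to_genes([snp(pos0=10_000)], [gene(tss=60_000)]) == []

    def test_deduplicated_with_promoter_priority(self):
        pair = (Region("chr1", 9_000, 11_000, "a"), Region("chr1", 14_000, 16_000, "b"))
        links = map_snps_to_genes(
            [snp(pos0=10_000)], [gene(tss=15_000)], interaction_pairs=[pair]
        )
        assert len(links) == 1 and links[0].evidence == "promoter-window"


class TestCarrierSplit:
    def test_partition_and_na_exclusion(self):
        geno = pd.DataFrame(
            [[0.0, 1.0, 2.0, np.nan]],
            index=["rs1"], columns=["d1", "d2", "d3", "d4"],
        )
        carriers, noncarriers, n_na = carrier_split(geno, "rs1")
        assert carriers == ["d2", "d3"]
        assert noncarriers == ["d1"]
        assert n_na == 1

    def test_missing_rsid_is_error(self):
        geno = pd.DataFrame([[0.0]], index=["rs1"], columns=["d1"])
        with pytest.raises(KeyError):
            carrier_split(geno, "rs9")

    def test_partitions_all_non_na_donors(self, rng):
        dosages = rng.choice([0.0, 1.0, 2.0, np.nan], size=20)
        geno = pd.DataFrame([dosages], index=["rs1"],
                            columns=[f"d{i}" for i in range(20)])
        carriers, noncarriers, n_na = carrier_split(geno, "rs1")
        assert len(carriers) + len(noncarriers) + n_na == 20
        assert not set(carriers) & set(noncarriers)


class TestPseudobulk:
    def _rna(self):
        counts = np.array([[3, 1], [4, 0], [2, 5], [1, 1]])
        return CountMatrix(
            sparse.csr_matrix(counts),
            ["c1", "c2", "c3", "c4"], ["g1", "g2"],
            ["A", "A", "A", "B"], ["d1", "d1", "d2", "d2"],
        )

    def test_sums_per_donor(self):
        pb = pseudobulk(self._rna(), "A")
        assert pb.loc["d1", "g1"] == 7
        assert pb.loc["d2", "g1"] == 2

    def test_donor_without_cells_omitted(self):
        pb = pseudobulk(self._rna(), "B")
        assert list(pb.index) == ["d2"]

    def test_column_sums_conserved(self, rng):
        n_cells, n_genes = 200, 15
        counts = rng.poisson(2.0, size=(n_cells, n_genes))
        donors = [f"d{i % 12}" for i in range(n_cells)]
        cts = ["A" if i % 2 else "B" for i in range(n_cells)]
        rna = CountMatrix(
            sparse.csr_matrix(counts), [f"c{i}" for i in range(n_cells)],
            [f"g{j}" for j in range(n_genes)], cts, donors,
        )
        pb = pseudobulk(rna, "A")
        mask = np.asarray(cts) == "A"
        np.testing.assert_array_equal(pb.sum(axis=0).to_numpy(), counts[mask].sum(axis=0))


class TestFilterTestable:
    def _pb(self, counts):
        return pd.DataFrame({"g1": counts}, index=[f"d{i}" for i in range(len(counts))])

    def test_exact_75_percent_passes(self):
        assert filter_testable(self._pb([10, 10, 10, 10, 10, 10, 0, 0]), "g1")

    def test_below_75_percent_fails(self):
        assert not filter_testable(self._pb([10, 10, 10, 10, 10, 0, 0, 0]), "g1")

    def test_count_of_exactly_ten_passes(self):
        assert filter_testable(self._pb([10, 10, 10, 10]), "g1")
        assert not filter_testable(self._pb([9, 9, 9, 9]), "g1")


def _covariates(donors, rng):
    return pd.DataFrame(
        {
            "diagnosis": rng.choice(["case", "control"], len(donors)),
            "sex": rng.choice(["F", "M"], len(donors)),
            "age": rng.normal(55, 13, len(donors)),
            "pH": rng.normal(6.6, 0.2, len(donors)),
            "RIN": rng.normal(7.2, 1.2, len(donors)),
            "PMI": rng.normal(33, 14, len(donors)),
        },
        index=donors,
    )


def _simulate_pseudobulk(rng, donors, carriers, log2fc, base_mean=40.0, alpha=0.2,
                         n_null_genes=5):
    libs = rng.uniform(0.7, 1.3, len(donors))
    cols = {}
    mult = np.array([2.0 ** log2fc if d in carriers else 1.0 for d in donors])
    cols["target"] = rng.poisson(rng.gamma(1 / alpha, scale=base_mean * libs * mult * alpha))
    for j in range(n_null_genes):
        cols[f"null{j}"] = rng.poisson(rng.gamma(1 / alpha, scale=base_mean * libs * alpha))
    return pd.DataFrame(cols, index=donors)


class TestDeTest:
    def test_effect_size_recovered(self, rng):
        donors = [f"d{i}" for i in range(30)]
        cov = _covariates(donors, rng)
        hits = 0
        for rep in range(10):
            carriers = set(rng.choice(donors, 15, replace=False))
            pb = _simulate_pseudobulk(rng, donors, carriers, log2fc=1.0)
            res = de_test_gene(pb, "target", sorted(carriers),
                               sorted(set(donors) - carriers), cov)
            assert res.testable
            if abs(res.log2_fc - 1.0) <= 0.3:
                hits += 1
        assert hits >= 8

    def test_upregulation_in_carriers_gives_positive_log2fc(self, rng):
        donors = [f"d{i}" for i in range(30)]
        cov = _covariates(donors, rng)
        carriers = set(donors[:15])
        pb = _simulate_pseudobulk(rng, donors, carriers, log2fc=2.0)
        res = de_test_gene(pb, "target", sorted(carriers), donors[15:], cov)
        assert res.log2_fc > 0

    def test_too_few_carriers_untestable(self, rng):
        donors = [f"d{i}" for i in range(20)]
        cov = _covariates(donors, rng)
        pb = _simulate_pseudobulk(rng, donors, set(donors[:2]), log2fc=0.0)
        res = de_test_gene(pb, "target", donors[:2], donors[2:], cov)
        assert not res.testable

    def test_fdr_family_and_significance(self, rng):
        donors = [f"d{i}" for i in range(30)]
        cov = _covariates(donors, rng)
        carriers = set(donors[:15])
        pb = _simulate_pseudobulk(rng, donors, carriers, log2fc=2.0, n_null_genes=8)
        results = [
            de_test_gene(pb, g, sorted(carriers), donors[15:], cov, rsid="rs1")
            for g in pb.columns
        ]
        results = apply_fdr(results)
        by_gene = {r.gene_id: r for r in results}
        assert by_gene["target"].significant
        assert all(np.isfinite(r.fdr) for r in results if r.testable)
        assert all(r.fdr >= r.pvalue - 1e-12 for r in results if r.testable)
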