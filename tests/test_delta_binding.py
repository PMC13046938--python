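import numpy as np
import pytest
from scipy import sparse

from deltabind.delta_binding import (
    DELTA_CUTOFF,
    DeltaBindingResult,
    classify_delta,
    define_sccres,
    delta_over_snp_windows,
    delta_score,
    motif_consistency,
    peak_binding_score,
)
from deltabind.io_formats import CountMatrix, GenomeSource, Region
from deltabind.motif_engine import MotifHit, scan_region
from deltabind.variants import AlleleSequencePair, SnpRecord, build_allele_pair


def hit(p, offset=0, strand="+"):
    return MotifHit("r", "m", offset, strand, 1.0, p)


class TestBindingScore:
    def test_no_hits_scores_zero(self):
        assert peak_binding_score([]) == 0.0

    def test_sum_of_neglog10(self):
        assert peak_binding_score([hit(0.1), hit(0.01, 1)]) == pytest.approx(3.0)

    def test_order_invariant(self, rng):
        ps = rng.uniform(1e-6, 1, size=20)
        hits = [hit(p, i) for i, p in enumerate(ps)]
        shuffled = [hits[i] for i in rng.permutation(20)]
        assert peak_binding_score(hits) == pytest.approx(peak_binding_score(shuffled))

    def test_nonpositive_pvalue_is_error(self):
        with pytest.raises(ValueError):
            peak_binding_score([hit(0.0)])


class TestClassification:
    @pytest.mark.parametrize(
        "delta,call",
        [(3.0, "unchanged"), (3.0001, "gained"), (-3.0, "unchanged"),
         (-3.0001, "lost"), (0.0, "unchanged")],
    )
    def test_strict_cutoff(self, delta, call):
        assert classify_delta(delta) == call


class TestDeltaScore:
    def test_identical_alleles_give_zero(self, toy_models, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        pair = AlleleSequencePair("r1", seq, seq, ())
        res = delta_score(pair, toy_models[0])
        assert res.delta == 0.0 and res.call == "unchanged"

    def test_delta_is_score_difference(self, toy_models, rng):
        m = toy_models[0]
        seq = "".join(rng.choice(list("ACGT"), 150))
        other = seq[:70] + "T" + seq[71:]
        pair = AlleleSequencePair("r1", seq, other, ("rs1",))
        res = delta_score(pair, m)
        assert res.delta == pytest.approx(res.score_risk - res.score_nonrisk)

    def test_sign_flag_restores_literal_definition(self, toy_models, rng):
        m = toy_models[0]
        seq = "".join(rng.choice(list("ACGT"), 150))
        other = seq[:70] + ("A" if seq[70] != "A" else "C") + seq[71:]
        pair = AlleleSequencePair("r1", seq, other, ("rs1",))
        a = delta_score(pair, m, sign="risk-minus-nonrisk")
        b = delta_score(pair, m, sign="ref-minus-alt")
        assert a.delta == pytest.approx(-b.delta)

    def test_antisymmetry_under_allele_swap(self, toy_models, rng):
        m = toy_models[3]
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 120))
            other = seq[:60] + ("G" if seq[60] != "G" else "T") + seq[61:]
            pair = AlleleSequencePair("r1", seq, other, ("rs1",))
            swapped = AlleleSequencePair("r1", other, seq, ("rs1",))
            a, b = delta_score(pair, m), delta_score(swapped, m)
            assert a.delta == -b.delta
            swap = {"gained": "lost", "lost": "gained", "unchanged": "unchanged"}
            assert b.call == swap[a.call]

    def test_locality_delta_determined_by_snp_windows(self, toy_models, rng):
        m = toy_models[5]
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 200))
            pos = sorted(rng.choice(200, size=2, replace=False))
            other = list(seq)
            for p in pos:
                other[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
            pair = AlleleSequencePair("r1", seq, "".join(other), ("rs1", "rs2"))
            full = delta_score(pair, m).delta
            local = delta_over_snp_windows(pair, m, [int(p) for p in pos])
            assert full == pytest.approx(local, abs=1e-9)


class TestConsistency:
    def _results(self, n_gained, n_lost, n_unchanged=0):
        out = []
        for i in range(n_gained):
            out.append(DeltaBindingResult("A", "m", f"g{i}", 0, 5, 5, "gained"))
        for i in range(n_lost):
            out.append(DeltaBindingResult("A", "m", f"l{i}", 5, 0, -5, "lost"))
        for i in range(n_unchanged):
            out.append(DeltaBindingResult("A", "m", f"u{i}", 1, 1, 0, "unchanged"))
        return out

    @pytest.mark.parametrize(
        "g,l,verdict",
        [(10, 2, "enhanced"), (4, 0, "none"), (0, 5, "disrupted"), (7, 2, "enhanced"),
         (3, 3, "none"), (0, 4, "none")],
    )
    def test_verdict_rule(self, g, l, verdict):
        res = motif_consistency(self._results(g, l))
        assert (res.n_gained, res.n_lost, res.verdict) == (g, l, verdict)

    def test_conservation_of_counts(self, rng):
        g, l, u = 6, 2, 9
        res = motif_consistency(self._results(g, l, u))
        assert res.n_gained + res.n_lost == g + l
        assert g + l + u == len(self._results(g, l, u))

    def test_mixed_groups_rejected(self):
        rows = self._results(1, 0) + [DeltaBindingResult("B", "m", "x", 0, 0, 0, "unchanged")]
        with pytest.raises(ValueError, match="single"):
            motif_consistency(rows)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            motif_consistency([])


class TestScCREs:
    def _atac(self):
        # 100 cells of type A: p0 accessible in 1%, p1 in 6%, p2 in 4%
        counts = np.zeros((100, 3), dtype=int)
        counts[:1, 0] = 1
        counts[:6, 1] = 1
        counts[:4, 2] = 1
        return CountMatrix(
            sparse.csr_matrix(counts),
            [f"c{i}" for i in range(100)], ["p0", "p1", "p2"],
            ["A"] * 100, ["d0"] * 100,
        )

    regions = {f"p{j}": Region("chr1", j * 100, j * 100 + 50, f"p{j}") for j in range(3)}

    def test_called_peak_included_despite_low_accessibility(self):
        sccres = define_sccres(self._atac(), {"A": {"p0"}}, "A", self.regions)
        by_id = {s.region.region_id: s for s in sccres}
        assert by_id["p0"].source == "called-in-celltype"

    def test_accessible_fraction_alone_qualifies(self):
        sccres = define_sccres(self._atac(), {"A": {"p0"}}, "A", self.regions)
        by_id = {s.region.region_id: s for s in sccres}
        assert by_id["p1"].source == "accessible-fraction"

    def test_neither_criterion_excluded(self):
        sccres = define_sccres(self._atac(), {"A": {"p0"}}, "A", self.regions)
        assert "p2" not in {s.region.region_id for s in sccres}

    def test_both_criteria_recorded(self):
        sccres = define_sccres(self._atac(), {"A": {"p1"}}, "A", self.regions)
        by_id = {s.region.region_id: s for s in sccres}
        assert by_id["p1"].source == "both"

    def test_snps_attached(self):
        s = SnpRecord("rs1", "chr1", 110, "A", "G", 0.1, 1e-9)
        sccres = define_sccres(
            self._atac(), {"A": {"p1"}}, "A", self.regions, {"p1": [s]}
        )
        by_id = {x.region.region_id: x for x in sccres}
        assert by_id["p1"].snps == (s,)
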