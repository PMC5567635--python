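"""SNP calling, filtering, partition algebra, chi-square, and panel matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from homeopipe import subassign, synthsim, variation
from homeopipe.core import AnnotatedTranscriptome
from homeopipe.variation import (
    SnpRecord,
    SnpSet,
    call_snps,
    filter_snps,
    match_accessions,
    partition_pairwise,
    partition_with_panel,
    snp_deg_enrichment,
)


def _snp(t="AT_g1", pos=1, ref="A", alt="C", qual=40.0, indel=False):
    return SnpRecord(t, pos, ref, alt, qual, indel)


def _set(label, keys, qual=40.0):
    s = SnpSet(label)
    for t, pos, alt in keys:
        s.add(SnpRecord(t, pos, "A", alt, qual))
    return s


class TestSnpRecords:
    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            _snp(ref="A", alt="A")
        with pytest.raises(ValueError):
            _snp(pos=0)
        with pytest.raises(ValueError):
            SnpRecord("t", 1, "AC", "A", 10.0, is_indel=False)

    def test_duplicate_keys_rejected(self):
        s = SnpSet("x", [_snp()])
        with pytest.raises(ValueError, match="duplicate"):
            s.add(_snp(qual=10.0))


class TestCallSnps:
    def test_unanimous_alt_called(self):
        ref = AnnotatedTranscriptome("AT", {"AT_g1": "A" * 50})
        pile = np.zeros((50, 4), dtype=np.int32)
        pile[9, 1] = 10  # ten reads say C at position 10
        called = call_snps({"AT_g1": pile}, ref)
        assert ("AT_g1", 10, "C") in called
        rec = called.get(("AT_g1", 10, "C"))
        assert rec.qual > 30

    def test_below_min_depth_not_called(self):
        ref = AnnotatedTranscriptome("AT", {"AT_g1": "A" * 50})
        pile = np.zeros((50, 4), dtype=np.int32)
        pile[9, 1] = 2
        assert len(call_snps({"AT_g1": pile}, ref, min_depth=4)) == 0

    def test_mixed_site_below_alt_fraction_not_called(self):
        ref = AnnotatedTranscriptome("AT", {"AT_g1": "A" * 50})
        pile = np.zeros((50, 4), dtype=np.int32)
        pile[9, 1] = 6
        pile[9, 0] = 4  # 60% alt < 90%
        assert len(call_snps({"AT_g1": pile}, ref)) == 0

    def test_missing_reference_errors_with_name(self):
        ref = AnnotatedTranscriptome("AT", {"AT_g1": "A" * 50})
        with pytest.raises(KeyError, match="AT_gX"):
            call_snps({"AT_gX": np.zeros((10, 4), dtype=np.int32)}, ref)

    def test_error_free_simulation_recovers_planted_snps_exactly(self):
        """On error-free reads, called SNPs = planted SNPs at every site with
        depth >= min_depth, with zero false calls."""
        cfg = synthsim.SimulationConfig.desk_scale(
            seed=21, n_pairs=30, n_unpaired_per_subgenome=0,
            transcript_len_range=(300, 500), reads_per_sample=6000,
            seq_error_rate=0.0, accession_snp_rate=0.01,
        )
        truth = synthsim.simulate_study(cfg)
        idx_at = subassign.build_index(truth.at, 21)
        idx_aa = subassign.build_index(truth.aa, 21)
        frags, _ = synthsim.simulate_reads(truth, "acc1", 1)
        assignments = subassign.assign_sample(frags, idx_at, idx_aa)
        at_assign = [a for a in assignments if a.subgenome == "AT"]
        piles = variation.build_pileups(
            frags, at_assign, {"AT": idx_at, "AA": idx_aa},
            {"AT": truth.at, "AA": truth.aa},
        )
        called = call_snps(piles, truth.at, min_depth=4)
        planted = truth.accession_snps["acc1"]
        covered_planted = {
            rec.key for rec in planted
            if rec.transcript in piles and piles[rec.transcript][rec.pos - 1].sum() >= 4
        }
        assert called.keys == covered_planted
        # coverage-limited recall reported for transparency
        assert len(covered_planted) / len(planted) > 0.5


class TestFilterSnps:
    def test_quality_boundary_strict(self):
        s = SnpSet("x", [_snp(pos=1, qual=30.0), _snp(pos=2, qual=30.01)])
        kept = filter_snps(s, min_quality=30.0)
        assert kept.keys == {("AT_g1", 2, "C")}

    def test_empty_in_empty_out(self):
        assert len(filter_snps(SnpSet("x"))) == 0

    def test_indels_dropped_when_flagged(self):
        recs = [_snp(pos=i + 1, qual=50.0) for i in range(100)]
        recs += [
            SnpRecord("AT_g1", 200 + i, "A", "AC", 50.0, is_indel=True) for i in range(20)
        ]
        s = SnpSet("x", recs)
        assert len(filter_snps(s, remove_indels=True, min_quality=0)) == 100
        assert len(filter_snps(s, remove_indels=False, min_quality=0)) == 120


class TestPartitions:
    def test_pairwise_hand_example(self):
        a = _set("a", [("t", 1, "C"), ("t", 2, "C"), ("t", 3, "C")])
        b = _set("b", [("t", 2, "C"), ("t", 3, "C"), ("t", 4, "C")])
        part = partition_pairwise(a, b)
        assert (part.shared, part.a_only, part.b_only) == (2, 1, 1)

    def test_identical_sets(self):
        a = _set("a", [("t", 1, "C")])
        part = partition_pairwise(a, a)
        assert part.a_only == part.b_only == 0

    def test_study_scale_pairwise_arithmetic(self):
        """Shared 46,223 + A-only 17,580 recovers the 63,803 A total."""
        part = variation.PairwisePartition(shared=46223, a_only=17580, b_only=11797)
        assert part.a_total == 63803
        assert part.b_total == 58020

    def test_study_scale_panel_arithmetic(self):
        """Private 8,447 / 5,943 plus shared-not-panel 11,648 give the
        20,095 / 17,591 not-in-panel totals."""
        part = variation.PanelPartition(
            shared_in_panel=34575, shared_not_panel=11648,
            a_only_in_panel=9133, a_only_not_panel=8447,
            b_only_in_panel=5854, b_only_not_panel=5943,
        )
        assert part.a_not_in_panel == 20095
        assert part.b_not_in_panel == 17591
        assert part.a_total == 63803
        assert part.b_total == 58020

    def test_toy_panel_enumeration(self):
        a = _set("a", [("t", 1, "C"), ("t", 2, "C"), ("t", 3, "C")])
        b = _set("b", [("t", 2, "C"), ("t", 3, "C"), ("t", 4, "C")])
        panel = _set("p", [("t", 3, "C"), ("t", 4, "C"), ("t", 5, "C")])
        part = partition_with_panel(a, b, panel)
        assert part.shared_not_panel == 1  # {2}
        assert part.shared_in_panel == 1  # {3}
        assert part.a_only_not_panel == 1  # {1}
        assert part.b_only_in_panel == 1  # {4}
        assert part.a_only_in_panel == 0 and part.b_only_not_panel == 0

    def test_all_empty(self):
        e = SnpSet("e")
        part = partition_with_panel(e, e, e)
        assert all(v == 0 for v in part.as_dict().values())

    @given(
        a_keys=st.sets(st.integers(1, 40), max_size=25),
        b_keys=st.sets(st.integers(1, 40), max_size=25),
        p_keys=st.sets(st.integers(1, 40), max_size=25),
    )
    @settings(max_examples=60, deadline=None)
    def test_cells_disjoint_and_marginalize(self, a_keys, b_keys, p_keys):
        a = _set("a", [("t", k, "C") for k in a_keys])
        b = _set("b", [("t", k, "C") for k in b_keys])
        p = _set("p", [("t", k, "C") for k in p_keys])
        cells = partition_with_panel(a, b, p)
        pair = partition_pairwise(a, b)
        assert cells.a_total == len(a) == pair.a_total
        assert cells.b_total == len(b) == pair.b_total
        assert cells.shared_in_panel + cells.shared_not_panel == pair.shared
        assert cells.a_only_in_panel + cells.a_only_not_panel == pair.a_only
        assert cells.b_only_in_panel + cells.b_only_not_panel == pair.b_only


class TestChiSquare:
    def test_observed_equals_expected(self):
        chi2, df, p = snp_deg_enrichment(100, 10, 100, 1000)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        chi2, df, p = snp_deg_enrichment(100, 20, 100, 1000)
        assert chi2 == pytest.approx((20 - 10) ** 2 / 10 + (80 - 90) ** 2 / 90)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))
        assert p == pytest.approx(0.00086, abs=5e-5)

    def test_agrees_with_independent_oracle(self, rng):
        """scipy.stats.chisquare as the independent two-cell oracle."""
        for _ in range(100):
            total_bp = int(rng.integers(10_000, 1_000_000))
            deg_bp = int(rng.integers(100, total_bp // 2))
            total_snps = int(rng.integers(10, 5000))
            in_deg = int(rng.integers(0, total_snps + 1))
            chi2, df, p = snp_deg_enrichment(total_snps, in_deg, deg_bp, total_bp)
            frac = deg_bp / total_bp
            oracle = stats.chisquare(
                [in_deg, total_snps - in_deg],
                [total_snps * frac, total_snps * (1 - frac)],
            )
            assert chi2 == pytest.approx(oracle.statistic, abs=1e-9, rel=1e-9)
            assert p == pytest.approx(oracle.pvalue, abs=1e-9, rel=1e-9)

    def test_contingency_variant(self):
        chi2, df, p = snp_deg_enrichment(100, 20, 10_000, 100_000, method="contingency")
        assert df == 1 and 0 <= p <= 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            snp_deg_enrichment(10, 20, 100, 1000)
        with pytest.raises(ValueError):
            snp_deg_enrichment(10, 1, 2000, 1000)
        with pytest.raises(ValueError, match="zero expected"):
            snp_deg_enrichment(10, 0, 0, 1000)


class TestMatchAccessions:
    def test_identical_member_ranks_first_with_score_one(self):
        q = _set("q", [("t", i, "C") for i in range(1, 11)])
        ident = _set("m1", [("t", i, "C") for i in range(1, 11)])
        other = _set("m2", [("t", i, "C") for i in range(100, 105)])
        df = match_accessions(q, [other, ident])
        assert df.iloc[0]["member"] == "m1"
        assert df.iloc[0]["score"] == 1.0
        assert df.iloc[1]["score"] == 0.0

    def test_planted_half_overlap_member_found(self, rng):
        q = _set("q", [("t", i, "C") for i in range(1, 41)])
        planted = _set("hit", [("t", i, "C") for i in range(1, 21)]
                       + [("t", i, "C") for i in range(200, 220)])
        decoys = [
            _set(f"d{j}", [("t", int(i), "C") for i in rng.choice(range(300, 1000), 40, replace=False)]
                 + [("t", j + 1, "C")])
            for j in range(5)
        ]
        df = match_accessions(q, decoys + [planted])
        assert df.iloc[0]["member"] == "hit"

    def test_ties_flagged_and_lexicographic(self):
        q = _set("q", [("t", 1, "C"), ("t", 2, "C")])
        m1 = _set("mb", [("t", 1, "C")])
        m2 = _set("ma", [("t", 2, "C")])
        df = match_accessions(q, [m1, m2])
        assert list(df["member"]) == ["ma", "mb"]
        assert df["tied"].all()


def test_vcf_roundtrip(tmp_path):
    s = SnpSet("acc1", [_snp(pos=i, qual=30 + i) for i in range(1, 6)])
    path = tmp_path / "x.vcf"
    s.to_vcf(path)
    back = SnpSet.from_vcf(path, "acc1")
    assert back.keys == s.keys
    assert back.get(("AT_g1", 3, "C")).qual == pytest.approx(33.0, abs=0.05)
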