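"""Generator truth: divergence, variants, expression, and reads."""

import numpy as np
import pandas as pd
import pytest

from homeopipe import subassign, synthsim, variation
from homeopipe.synthsim import SimulationConfig


def _pair_identity(truth, n=None):
    vals = []
    rows = truth.homoeolog_map.rows[:n] if n else truth.homoeolog_map.rows
    for _, g1, g2 in rows:
        s1, s2 = truth.at.records[g1], truth.aa.records[g2]
        vals.append(sum(a == b for a, b in zip(s1, s2)) / len(s1))
    return np.array(vals)


class TestSubgenomes:
    def test_zero_divergence_gives_identical_homoeologs(self):
        cfg = SimulationConfig.desk_scale(seed=1, n_pairs=10, subgenome_divergence=0.0)
        at, aa, hmap = synthsim.generate_subgenomes(cfg)
        for _, g1, g2 in hmap:
            assert at.records[g1] == aa.records[g2]

    def test_observed_identity_matches_one_minus_divergence(self):
        # closed-form: per-site difference prob is exactly d; binomial error
        cfg = SimulationConfig.desk_scale(
            seed=2, n_pairs=200, transcript_len_range=(1000, 1000)
        )
        truth = synthsim.simulate_study(cfg)
        ident = _pair_identity(truth)
        n_sites = 200 * 1000
        se = np.sqrt(0.17 * 0.83 / n_sites)
        assert abs(ident.mean() - 0.83) < 3 * se
        assert 0.81 <= ident.mean() <= 0.85

    def test_map_row_count_and_prefixes(self, small_truth, small_config):
        hmap = small_truth.homoeolog_map
        assert len(hmap) == small_config.n_pairs
        for _, at_gene, aa_gene in hmap:
            assert at_gene.startswith("AT_") and aa_gene.startswith("AA_")

    def test_short_transcripts_rejected_below_kmer_size(self):
        cfg = SimulationConfig.desk_scale(seed=1, transcript_len_range=(10, 50))
        with pytest.raises(ValueError, match="k-mer"):
            synthsim.generate_subgenomes(cfg, min_transcript_len=21)

    def test_same_seed_bit_identical_different_seed_not(self):
        cfg = SimulationConfig.desk_scale(seed=5, n_pairs=20)
        a1, _, _ = synthsim.generate_subgenomes(cfg)
        a2, _, _ = synthsim.generate_subgenomes(cfg)
        assert a1.records == a2.records
        cfg2 = SimulationConfig.desk_scale(seed=6, n_pairs=20)
        a3, _, _ = synthsim.generate_subgenomes(cfg2)
        assert a1.records != a3.records
        assert sorted(a1.records) == sorted(a3.records)  # config-derived IDs


class TestAccessionVariants:
    def test_zero_rate_gives_empty_sets(self, small_truth):
        cfg = SimulationConfig.desk_scale(seed=3, n_pairs=20, accession_snp_rate=0.0)
        truth = synthsim.simulate_study(cfg)
        assert all(len(s) == 0 for s in truth.accession_snps.values())
        part = variation.partition_with_panel(
            truth.accession_snps["acc1"],
            truth.accession_snps["acc2"],
            variation.SnpSet("panel"),
        )
        assert all(v == 0 for v in part.as_dict().values())

    def test_planted_cells_recovered_exactly(self, rng):
        cfg = SimulationConfig.desk_scale(seed=4, n_pairs=40)
        at, _, _ = synthsim.generate_subgenomes(cfg)
        cells = {
            "shared_not_panel": 10,
            "a_only_not_panel": 5,
            "b_only_not_panel": 3,
            "shared_in_panel": 2,
            "a_only_in_panel": 2,
            "b_only_in_panel": 2,
        }
        a, b, panel = synthsim.plant_snp_partition(at, cells, panel_size=3, rng=rng)
        union = variation.SnpSet("panel")
        for m in panel:
            union = union.union(m)
        part = variation.partition_with_panel(a, b, union)
        for k, v in cells.items():
            assert getattr(part, k) == v

    def test_shared_fraction_reproduces_panel_regime(self):
        """At the realistic shared fraction, the pairwise partition has the
        shared-majority structure of the two-accession comparison."""
        cfg = SimulationConfig.desk_scale(
            seed=5, n_pairs=150, accession_snp_rate=0.01, shared_snp_fraction=0.724
        )
        truth = synthsim.simulate_study(cfg)
        part = variation.partition_pairwise(
            truth.accession_snps["acc1"], truth.accession_snps["acc2"]
        )
        assert part.a_total == len(truth.accession_snps["acc1"])
        frac = part.shared / part.a_total
        assert abs(frac - 0.724) < 0.02
        assert part.a_only > 0 and part.b_only > 0

    def test_snp_positions_within_transcripts(self, small_truth):
        small_truth.validate()


class TestExpressionTruth:
    def test_zero_fc_means_no_de(self):
        cfg = SimulationConfig.desk_scale(seed=6, n_pairs=30, de_log2fc=0.0)
        truth = synthsim.simulate_study(cfg)
        assert not truth.expression["is_de"].any()

    def test_coordinated_pairs_fully_concordant(self, small_truth, small_config):
        expr = small_truth.expression
        coord = expr[expr["coordinated"]]
        assert len(coord) == 2 * small_config.n_coordinated_pairs
        for pid, grp in coord.groupby("pair_id"):
            assert len(grp) == 2
            assert grp["direction"].nunique() == 1  # same direction both members

    def test_de_count_matches_config(self, small_truth, small_config):
        assert int(small_truth.expression["is_de"].sum()) == small_config.n_de_genes

    def test_dominance_offset_in_truth(self):
        cfg = SimulationConfig.desk_scale(seed=7, n_pairs=500, n_de_genes=0,
                                          n_coordinated_pairs=0, dominance_log2=1.0)
        at, aa, hmap = synthsim.generate_subgenomes(cfg)
        expr = synthsim.generate_expression_truth(hmap, at, aa, cfg)
        lr = []
        for _, g1, g2 in hmap:
            lr.append(np.log2(expr.loc[g1, "expr_acc1"] / expr.loc[g2, "expr_acc1"]))
        # baselines are iid log-normal; dominance shifts the mean by 1
        se = np.std(lr, ddof=1) / np.sqrt(len(lr))
        assert abs(np.mean(lr) - 1.0) < 4 * se

    def test_too_many_de_genes_rejected(self):
        cfg = SimulationConfig.desk_scale(seed=1, n_pairs=5, n_unpaired_per_subgenome=0,
                                          n_de_genes=100, n_coordinated_pairs=5)
        at, aa, hmap = synthsim.generate_subgenomes(cfg)
        with pytest.raises(ValueError, match="exceeds gene count"):
            synthsim.generate_expression_truth(hmap, at, aa, cfg)


class TestReads:
    def test_zero_reads_give_empty_valid_fastq(self, tmp_path):
        cfg = SimulationConfig.desk_scale(seed=8, n_pairs=10, reads_per_sample=0)
        truth = synthsim.simulate_study(cfg)
        frags, origin = synthsim.simulate_reads(truth, "acc1", 1)
        assert frags == [] and origin.empty
        synthsim.write_fastq(frags, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert (tmp_path / "r1.fastq").read_text() == ""

    def test_six_samples_for_two_accessions_three_replicates(self, small_config):
        samples = list(synthsim.iter_samples(small_config))
        assert len(samples) == 6
        assert {acc for acc, _, _ in samples} == {"acc1", "acc2"}

    def test_error_free_reads_assign_uniquely_to_true_gene(self):
        cfg = SimulationConfig.desk_scale(
            seed=9, n_pairs=50, n_unpaired_per_subgenome=5,
            reads_per_sample=2000, seq_error_rate=0.0,
        )
        truth = synthsim.simulate_study(cfg)
        idx_at = subassign.build_index(truth.at, 21)
        idx_aa = subassign.build_index(truth.aa, 21)
        frags, origin = synthsim.simulate_reads(truth, "acc2", 2)
        assignments = subassign.assign_sample(frags, idx_at, idx_aa)
        true_gene = dict(zip(origin["read_id"], origin["gene"]))
        mis = sum(
            1 for a in assignments
            if a.subgenome in ("AT", "AA") and a.gene != true_gene[a.read_id]
        )
        assert mis == 0
        n_amb = sum(1 for a in assignments if a.subgenome == "ambiguous")
        assert n_amb / len(assignments) < 0.01

    def test_fragment_counts_multinomial_expression_times_length(self, rng):
        # chi-square goodness of fit vs expression*length probabilities
        cfg = SimulationConfig.desk_scale(seed=10, n_pairs=50, n_de_genes=0,
                                          n_coordinated_pairs=0)
        at, aa, hmap = synthsim.generate_subgenomes(cfg)
        expr = synthsim.generate_expression_truth(hmap, at, aa, cfg)
        n = 200_000
        counts = synthsim.simulate_fragment_counts(expr, "acc1", n, rng)
        w = expr["expr_acc1"] * expr["length"]
        p = (w / w.sum()).to_numpy()
        exp = n * p
        keep = exp >= 5
        from scipy import stats
        chi2 = ((counts.to_numpy()[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.001

    def test_reads_deterministic_per_seed(self, small_truth):
        f1, o1 = synthsim.simulate_reads(small_truth, "acc1", 2)
        f2, o2 = synthsim.simulate_reads(small_truth, "acc1", 2)
        assert f1 == f2
        pd.testing.assert_frame_equal(o1, o2)


def test_config_invariant_validation():
    with pytest.raises(ValueError):
        SimulationConfig(subgenome_divergence=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_de_genes=10, n_coordinated_pairs=6).validate()
    with pytest.raises(ValueError):
        SimulationConfig(reads_per_sample=-1).validate()


def test_write_study_roundtrip(tmp_path):
    from homeopipe.core import AnnotatedTranscriptome, HomoeologMap

    cfg = SimulationConfig.desk_scale(seed=12, n_pairs=10, n_unpaired_per_subgenome=2,
                                      reads_per_sample=200, n_de_genes=6,
                                      n_coordinated_pairs=2)
    truth = synthsim.simulate_study(cfg)
    synthsim.write_study(truth, tmp_path)
    at = AnnotatedTranscriptome.from_fasta(tmp_path / "subgenome_AT.fasta", "AT")
    assert at.records == truth.at.records
    hmap = HomoeologMap.from_tsv(tmp_path / "homoeolog_map.tsv")
    assert hmap.rows == truth.homoeolog_map.rows
    vcf = variation.SnpSet.from_vcf(tmp_path / "snps_acc1.vcf", "acc1")
    assert vcf.keys == truth.accession_snps["acc1"].keys
    fq = (tmp_path / "acc1_r1_1.fastq").read_text().splitlines()
    assert len(fq) % 4 == 0 and fq[0].startswith("@")
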