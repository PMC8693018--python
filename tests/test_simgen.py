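"""Synthetic-data generator: determinism, divergence, depth and read models."""

import numpy as np
import pytest

from sexlinkscan import _seq, simgen
from sexlinkscan.simgen import ConfigurationError, SimConfig


def _tiny_cfg(**kw):
    base = dict(seed=5, scaffold_lengths=(20_000, 30_000),
                msr_scaffold="scaffold_1", msr_start=4_000,
                msr_length=12_000, paralog_scaffold="scaffold_2",
                paralog_length=10_000, paralog_identity=0.92,
                cassette_deletion=0, coverage=30.0, read_length=100,
                error_rate=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_msr_overflow_rejected(self):
        with pytest.raises(ConfigurationError):
            _tiny_cfg(msr_start=15_000)

    def test_bad_identity_rejected(self):
        with pytest.raises(ConfigurationError):
            _tiny_cfg(paralog_identity=0.0)

    def test_bad_coverage_rejected(self):
        with pytest.raises(ConfigurationError):
            _tiny_cfg(coverage=0)


class TestMakeGenomes:
    def test_deterministic_byte_identical(self, tmp_path):
        cfg = _tiny_cfg()
        f1, m1, _ = simgen.make_genomes(cfg)
        f2, m2, _ = simgen.make_genomes(cfg)
        _seq.write_fasta(m1, tmp_path / "a.fasta")
        _seq.write_fasta(m2, tmp_path / "b.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == \
            (tmp_path / "b.fasta").read_bytes()
        assert all(np.array_equal(f1[k], f2[k]) for k in f1)

    def test_identity_one_gives_exact_copy(self):
        female, male, truth = simgen.make_genomes(
            _tiny_cfg(paralog_identity=1.0))
        sc, a, b = truth.cassette_interval
        psc, pa, pb = truth.paralog_interval
        assert np.array_equal(male[sc][a:b], female[psc][pa:pb])

    def test_cassette_divergence_matches_identity(self):
        # 10 kb cassette at 92% identity: mismatch fraction within 3 SD of
        # the binomial expectation 0.08
        female, male, truth = simgen.make_genomes(_tiny_cfg())
        sc, a, b = truth.cassette_interval
        psc, pa, pb = truth.paralog_interval
        cass, par = male[sc][a:b], female[psc][pa:pb]
        frac = float((cass != par).mean())
        sd = np.sqrt(0.08 * 0.92 / cass.size)
        assert abs(frac - 0.08) < 3 * sd

    def test_male_is_female_plus_insertion(self):
        cfg = _tiny_cfg()
        female, male, truth = simgen.make_genomes(cfg)
        sc, a, b = truth.msr_interval
        assert male[sc].size == female[sc].size + cfg.msr_length
        assert np.array_equal(male[sc][:a], female[sc][:a])
        assert np.array_equal(male[sc][b:], female[sc][a:])

    def test_truth_intervals_within_bounds(self):
        _, male, truth = simgen.make_genomes(_tiny_cfg())
        for sc, a, b in (truth.msr_interval, truth.cassette_interval,
                         truth.paralog_interval):
            assert 0 <= a < b <= male[sc].size


@pytest.fixture(scope="module")
def depth_sim():
    cfg = _tiny_cfg(n_males=2, n_females=2)
    _, _, truth = simgen.make_genomes(cfg)
    return cfg, truth, simgen.simulate_depth(cfg, truth)


class TestSimulateDepth:

    def test_diploid_mean_near_coverage(self, depth_sim):
        cfg, truth, depths = depth_sim
        region = depths["M01"].depths["scaffold_2"][:10_000]
        se = np.sqrt(cfg.coverage / region.size)
        assert abs(region.mean() - 30.0) < 3 * se

    def test_male_msr_half_molarity(self, depth_sim):
        cfg, truth, depths = depth_sim
        sc, a, b = truth.msr_interval
        region = depths["M01"].depths[sc][a:b]
        se = np.sqrt(15.0 / region.size)
        assert abs(region.mean() - 15.0) < 3 * se

    def test_female_msr_zero(self, depth_sim):
        _, truth, depths = depth_sim
        sc, a, b = truth.msr_interval
        assert (depths["F01"].depths[sc][a:b] == 0).all()

    def test_deterministic(self, depth_sim):
        cfg, truth, depths = depth_sim
        again = simgen.simulate_depth(cfg, truth)
        for s in depths:
            for k in depths[s].depths:
                assert np.array_equal(depths[s].depths[k],
                                      again[s].depths[k])

    def test_depth_tsv_roundtrip(self, depth_sim, tmp_path):
        _, _, depths = depth_sim
        dt = depths["F01"]
        dt.to_tsv(tmp_path / "d.tsv")
        back = simgen.DepthTable.from_tsv(
            tmp_path / "d.tsv", sample="F01",
            scaffold_lengths={k: v.size for k, v in dt.depths.items()})
        for k in dt.depths:
            assert np.array_equal(dt.depths[k], back.depths[k])


@pytest.fixture(scope="module")
def read_sim():
    cfg = _tiny_cfg(n_males=1, n_females=1, coverage=5.0)
    female, male, truth = simgen.make_genomes(cfg)
    return cfg, female, male, truth


class TestSimulateReads:

    def test_expected_read_count(self, read_sim):
        cfg, female, male, truth = read_sim
        reads = list(simgen.sample_reads(cfg, truth, female, male, "F01"))
        genome_size = sum(v.size for v in female.values())
        expected = cfg.coverage * genome_size / cfg.read_length
        assert abs(len(reads) - expected) < 3 * np.sqrt(expected)

    def test_error_free_reads_are_exact_substrings(self, read_sim):
        cfg, female, male, truth = read_sim
        hap_map = {"mat": female, "pat": male}
        n = 0
        for name, codes in simgen.sample_reads(cfg, truth, female, male,
                                               "M01"):
            sample, hap, sc, pos, _ = name.split(":")
            pos = int(pos)
            src = hap_map[hap][sc]
            assert 0 <= pos <= src.size - codes.size
            assert np.array_equal(src[pos:pos + codes.size], codes)
            n += 1
        assert n > 0

    def test_origin_names_roundtrip_all_reads(self, read_sim):
        cfg, female, male, truth = read_sim
        for name, codes in simgen.sample_reads(cfg, truth, female, male,
                                               "F01"):
            sample, hap, sc, pos, idx = name.split(":")
            assert sample == "F01" and hap in ("mat", "pat")
            assert sc in female and 0 <= int(pos) < female[sc].size

    def test_fastq_roundtrip(self, read_sim, tmp_path):
        cfg, female, male, truth = read_sim
        paths = simgen.simulate_reads(cfg, truth, female, male,
                                      out_dir=tmp_path)
        back = list(_seq.read_fastq(paths["M01"]))
        orig = list(simgen.sample_reads(cfg, truth, female, male, "M01"))
        assert len(back) == len(orig)
        assert back[0][0] == orig[0][0]
        assert np.array_equal(back[0][1], orig[0][1])


class TestSimulateExpression:
    def test_male_specific_gene_pattern(self):
        counts, lengths, groups = simgen.simulate_expression(10, 10, seed=4)
        row = counts.loc["sult_y"]
        assert (row[groups == "testis"] > 0).all()
        assert (row[groups == "ovary"] == 0).all()

    def test_seed_reproducible(self):
        a, _, _ = simgen.simulate_expression(5, 5, seed=8)
        b, _, _ = simgen.simulate_expression(5, 5, seed=8)
        assert a.equals(b)

    def test_background_means_in_range(self):
        genes = simgen.default_gene_table(seed=0)
        counts, _, groups = simgen.simulate_expression(50, 50, genes=genes,
                                                       seed=0)
        for gene in ("bg001", "bg002", "bg003"):
            mean = genes.loc[gene, "mean_testis"]
            disp = genes.loc[gene, "dispersion"]
            observed = counts.loc[gene].mean()
            se = np.sqrt((mean + disp * mean ** 2) / counts.shape[1])
            assert abs(observed - mean) < 3 * se

    def test_paralog_low_but_mostly_nonzero(self):
        counts, _, groups = simgen.simulate_expression(10, 10, seed=4)
        row = counts.loc["sult_a"]
        assert (row > 0).mean() > 0.5
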