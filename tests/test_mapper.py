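"""Seeded ungapped mapper and pileup genotyper."""

import numpy as np
import pytest

from sexlinkscan import _seq, mapper
from sexlinkscan.mapper import (Alignment, ReferenceIndex, map_reads,
                                pileup_and_call)

from _oracles import brute_force_best_alignment


@pytest.fixture(scope="module")
def random_ref():
    rng = np.random.default_rng(42)
    return {"chrA": _seq.random_codes(rng, 4_000),
            "chrB": _seq.random_codes(rng, 3_000)}


class TestMapReads:
    def test_exact_unique_substring_maps_true(self, random_ref):
        read = random_ref["chrB"][700:800]
        [aln] = map_reads([("r1", read)], random_ref)
        assert (aln.scaffold, aln.start, aln.strand) == ("chrB", 700, "+")
        assert aln.mismatches == 0 and not aln.is_ambiguous

    def test_reverse_strand_read(self, random_ref):
        read = _seq.revcomp(random_ref["chrA"][1000:1100])
        [aln] = map_reads([("r1", read)], random_ref)
        assert (aln.scaffold, aln.start, aln.strand) == ("chrA", 1000, "-")
        assert np.array_equal(aln.read_codes,
                              random_ref["chrA"][1000:1100])

    def test_exact_repeat_flagged_ambiguous(self):
        rng = np.random.default_rng(1)
        repeat = _seq.random_codes(rng, 300)
        ref = {"c1": np.concatenate([_seq.random_codes(rng, 500), repeat,
                                     _seq.random_codes(rng, 500)]),
               "c2": np.concatenate([repeat, _seq.random_codes(rng, 400)])}
        read = repeat[100:200]
        [aln] = map_reads([("r1", read)], ref)
        assert aln.is_ambiguous
        # tie-break: lexicographically first scaffold, leftmost coordinate
        assert (aln.scaffold, aln.start) == ("c1", 600)

    def test_too_many_mismatches_unmapped(self, random_ref):
        read = random_ref["chrA"][100:200].copy()
        read[:13] = (read[:13] + 1) % 4
        assert map_reads([("r1", read)], random_ref,
                         max_mismatch=12) == []

    def test_n_bases_count_as_mismatch(self, random_ref):
        read = random_ref["chrA"][100:200].copy()
        read[50] = _seq.N_CODE
        [aln] = map_reads([("r1", read)], random_ref)
        assert aln.mismatches == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex({})

    def test_order_independence(self, random_ref):
        rng = np.random.default_rng(7)
        reads = [(f"r{i}", _seq.random_codes(rng, 50)) for i in range(20)]
        reads += [(f"t{i}", random_ref["chrA"][i * 100:i * 100 + 100])
                  for i in range(10)]
        fwd = map_reads(reads, random_ref)
        rev = map_reads(reads[::-1], random_ref)
        key = lambda a: (a.read_id, a.scaffold, a.start, a.strand,
                         a.mismatches, a.is_ambiguous)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_matches_brute_force_oracle(self, random_ref):
        # 1000 reads with 0-3 substitutions: seeded search must agree with
        # scoring every position of every scaffold on both strands
        rng = np.random.default_rng(3)
        idx = ReferenceIndex(random_ref, k=15)
        for i in range(1_000):
            name = "chrA" if rng.random() < 0.6 else "chrB"
            src = random_ref[name]
            pos = int(rng.integers(0, src.size - 100))
            read = src[pos:pos + 100].copy()
            n_mut = int(rng.integers(0, 4))
            sites = rng.choice(100, size=n_mut, replace=False)
            read[sites] = (read[sites] + rng.integers(1, 4, n_mut)) % 4
            if rng.random() < 0.5:
                read = _seq.revcomp(read)
            got = map_reads([(f"r{i}", read)], idx, max_mismatch=12)
            ref_best = brute_force_best_alignment(read, random_ref)
            assert got, f"read {i} unmapped but oracle found {ref_best}"
            aln = got[0]
            mism, scaffold, start, strand, ambig = ref_best
            assert (aln.mismatches, aln.scaffold, aln.start, aln.strand) \
                == (mism, scaffold, start, strand)
            assert aln.is_ambiguous == ambig


class TestPileupAndCall:
    def _reads_at(self, ref, scaffold, start, length, n, mutate_at=None,
                  alt_base=None):
        """n identical full-length alignments starting at ``start``."""
        out = []
        for i in range(n):
            codes = ref[scaffold][start:start + length].copy()
            if mutate_at is not None:
                codes[mutate_at] = alt_base
            out.append(Alignment(
                read_id=f"x{i}", scaffold=scaffold, start=start,
                strand="+", mismatches=0 if mutate_at is None else 1,
                score=length, is_ambiguous=False, read_codes=codes))
        return out

    def test_hom_ref_het_and_missing_calls(self, random_ref):
        ref = random_ref
        site = 50
        ref_base = int(ref["chrA"][100 + site])
        alt = (ref_base + 1) % 4
        by_sample = {
            # 30 reads all ref -> 0/0
            "s_ref": self._reads_at(ref, "chrA", 100, 100, 30),
            # 15 ref + 15 alt -> alt fraction 0.5 -> 0/1
            "s_het": (self._reads_at(ref, "chrA", 100, 100, 15)
                      + self._reads_at(ref, "chrA", 100, 100, 15,
                                       mutate_at=site, alt_base=alt)),
            # depth 19 < 20 -> ./.
            "s_thin": self._reads_at(ref, "chrA", 100, 100, 19,
                                     mutate_at=site, alt_base=alt),
            # 30 alt reads -> 1/1
            "s_alt": self._reads_at(ref, "chrA", 100, 100, 30,
                                    mutate_at=site, alt_base=alt),
        }
        table = pileup_and_call(by_sample, ref, min_depth=20,
                                het_band=(0.2, 0.8))
        assert table.n_sites == 1
        row = table.sites.iloc[0]
        assert (row.scaffold, row.pos) == ("chrA", 100 + site + 1)
        assert row.ref == _seq.BASES[ref_base]
        assert row.alt == _seq.BASES[alt]
        gt = dict(zip(table.samples, table.gt[0]))
        dp = dict(zip(table.samples, table.dp[0]))
        assert gt == {"s_ref": 0, "s_het": 1, "s_thin": -1, "s_alt": 2}
        assert dp["s_thin"] == 19 and dp["s_het"] == 30

    def test_monomorphic_pileup_yields_no_sites(self, random_ref):
        by_sample = {"s1": self._reads_at(random_ref, "chrB", 0, 100, 25)}
        table = pileup_and_call(by_sample, random_ref)
        assert table.n_sites == 0

    def test_genotype_table_tsv_roundtrip(self, random_ref, tmp_path):
        site = 10
        alt = int((random_ref["chrA"][200 + site] + 2) % 4)
        by_sample = {
            "a": self._reads_at(random_ref, "chrA", 200, 50, 25),
            "b": self._reads_at(random_ref, "chrA", 200, 50, 25,
                                mutate_at=site, alt_base=alt),
        }
        table = pileup_and_call(by_sample, random_ref)
        table.to_tsv(tmp_path / "gt.tsv")
        back = mapper.SnvGenotypeTable.from_tsv(tmp_path / "gt.tsv")
        assert back.samples == table.samples
        assert np.array_equal(back.gt, table.gt)
        assert np.array_equal(back.dp, table.dp)


class TestAlignmentTsv:
    def test_roundtrip(self, random_ref, tmp_path):
        reads = [("r1", random_ref["chrA"][0:100]),
                 ("r2", _seq.revcomp(random_ref["chrB"][50:150]))]
        aln = map_reads(reads, random_ref)
        mapper.alignments_to_tsv(aln, tmp_path / "aln.tsv")
        back = mapper.alignments_from_tsv(tmp_path / "aln.tsv")
        for a, b in zip(aln, back):
            assert (a.read_id, a.scaffold, a.start, a.strand,
                    a.mismatches, a.is_ambiguous) == \
                (b.read_id, b.scaffold, b.start, b.strand,
                 b.mismatches, b.is_ambiguous)
            assert np.array_equal(a.read_codes, b.read_codes)
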