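"""Adapter trimming and the exact 0/1-mismatch mapper against brute force."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pirnakit import mapping
from pirnakit.mapping import (
    DEFAULT_ADAPTER,
    AlignmentHit,
    SmallRNARead,
    filter_by_length,
    map_reads,
    multimapper_weights,
    revcomp,
    trim_adapter,
    unique_mappers,
)
from conftest import brute_force_placements

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestTrimAdapter:
    @pytest.mark.parametrize(
        "seq,min_match,expected",
        [
            ("ACGT" + DEFAULT_ADAPTER, 6, "ACGT"),  # full adapter appended
            ("ACGTTGGAAT", 6, "ACGT"),  # 6-nt adapter prefix at 3' end
            ("ACGTACGTACGT", 6, "ACGTACGTACGT"),  # no adapter content
            ("ACGT" + DEFAULT_ADAPTER + "ACGT" + DEFAULT_ADAPTER, 6, "ACGT"),  # leftmost wins
        ],
    )
    def test_examples(self, seq, min_match, expected):
        out = trim_adapter(SmallRNARead("r", seq), DEFAULT_ADAPTER, min_match)
        assert out.seq == expected

    def test_brute_force_scan(self):
        """Trimming point equals the leftmost suffix/prefix match found by
        scanning every (position, match-length) combination."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(8, 45)))
            min_match = int(rng.integers(1, 8))
            cut = len(seq)
            for i in range(1, len(seq)):
                k = min(len(DEFAULT_ADAPTER), len(seq) - i)
                if (k >= min_match or k == len(DEFAULT_ADAPTER)) and seq[
                    i : i + k
                ] == DEFAULT_ADAPTER[:k]:
                    cut = i
                    break
            expected = seq[:cut]
            got = trim_adapter(SmallRNARead("r", seq), DEFAULT_ADAPTER, min_match)
            assert got.seq == expected

    @given(dna)
    def test_idempotent(self, seq):
        try:
            once = trim_adapter(SmallRNARead("r", seq))
        except ValueError:
            return  # adapter-only read
        assert trim_adapter(once).seq == once.seq

    def test_adapter_only_read_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter(SmallRNARead("r", DEFAULT_ADAPTER))


class TestMapReads:
    def test_exact_substring_single_hit(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        read = SmallRNARead("r", ref[10:33])
        res = map_reads([read], {"ref": ref}, max_mismatches=0)
        plus = [h for h in res.hits if h.strand == "+"]
        assert AlignmentHit("r", "ref", 10, 33, "+", 0) in plus

    def test_strand_symmetry(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        read = SmallRNARead("r", revcomp(ref[10:33]))
        res = map_reads([read], {"ref": ref}, max_mismatches=0)
        minus = [h for h in res.hits if h.strand == "-"]
        assert AlignmentHit("r", "ref", 10, 33, "-", 0) in minus

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_equals_brute_force(self, max_mm):
        """Seed-and-verify mapper reproduces the exhaustive Hamming scan."""
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), size=3000))
        refs = {"toy": ref}
        reads = []
        for i in range(60):
            L = int(rng.integers(20, 30))
            if rng.random() < 0.7:  # planted (possibly mutated) read
                s = int(rng.integers(0, len(ref) - L))
                seq = list(ref[s : s + L])
                if rng.random() < 0.5:
                    seq[int(rng.integers(L))] = str(rng.choice(list("ACGT")))
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
            else:
                seq = "".join(rng.choice(list("ACGT"), size=L))
            reads.append(SmallRNARead(f"r{i}", seq))
        res = map_reads(reads, refs, max_mismatches=max_mm)
        got = {(h.read_id, h.reference, h.start, h.end, h.strand, h.mismatches) for h in res.hits}
        expected = set()
        for read in reads:
            expected |= brute_force_placements(read, refs, max_mm)
        assert got == expected

    def test_n_reads_skipped_and_counted(self):
        ref = "ACGT" * 50
        reads = [SmallRNARead("a", ref[0:25]), SmallRNARead("b", "ACGTN" + ref[0:20])]
        res = map_reads(reads, {"ref": ref}, max_mismatches=0)
        assert res.n_skipped_with_n == 1
        assert all(h.read_id == "a" for h in res.hits)

    def test_involution_revcomp_swaps_strands(self):
        rng = np.random.default_rng(4)
        ref = "".join(rng.choice(list("ACGT"), size=500))
        read = SmallRNARead("r", ref[100:126])
        fw = map_reads([read], {"ref": ref}, 1).hits
        rc = map_reads([SmallRNARead("r", revcomp(read.seq))], {"ref": ref}, 1).hits
        flip = {"+": "-", "-": "+"}
        assert {(h.start, h.end, flip[h.strand], h.mismatches) for h in fw} == {
            (h.start, h.end, h.strand, h.mismatches) for h in rc
        }


class TestFilters:
    def _hits(self, lengths):
        return [AlignmentHit(f"r{i}", "ref", 100, 100 + L, "+", 0) for i, L in enumerate(lengths)]

    def test_length_window_is_inclusive(self):
        kept = filter_by_length(self._hits([17, 18, 29, 30]), 18, 29)
        assert sorted(h.read_length for h in kept) == [18, 29]

    def test_sirnas_excluded_from_pirna_range(self):
        assert filter_by_length(self._hits([21] * 5), 23, 29) == []

    def test_idempotent(self):
        hits = self._hits(list(range(15, 35)))
        once = filter_by_length(hits, 18, 29)
        assert filter_by_length(once, 18, 29) == once

    def test_unique_mappers_drop_multihit_reads(self):
        h1 = AlignmentHit("multi", "ref", 0, 25, "+", 0)
        h2 = AlignmentHit("multi", "ref", 50, 75, "+", 0)
        h3 = AlignmentHit("solo", "ref", 100, 125, "-", 0)
        assert unique_mappers([h1, h2, h3]) == [h3]
        assert multimapper_weights([h1, h2, h3]) == {"multi": 0.5, "solo": 1.0}

    def test_tandem_repeat_reads_removed_flank_reads_kept(self, tandem_locus, tandem_refs):
        """Reads from a 7-copy array hit every copy; flank reads are unique."""
        refs, _ = tandem_refs
        chrom = refs[tandem_locus.chrom_name]
        s = tandem_locus.block_start
        repeat_read = SmallRNARead("rep", chrom[s + 5 : s + 30])
        flank_read = SmallRNARead("fla", chrom[200:225])
        res = map_reads([repeat_read, flank_read], {tandem_locus.chrom_name: chrom}, 0)
        assert res.placements_per_read()["rep"] == tandem_locus.n_copies
        uniq = unique_mappers(list(res.hits))
        assert {h.read_id for h in uniq} == {"fla"}


def test_fastq_fasta_roundtrip(tmp_path):
    reads = [SmallRNARead("a", "ACGTACGTACGTACGTACGTAAA"), SmallRNARead("b", "TTTTACGT")]
    mapping.write_fastq(reads, tmp_path / "x.fastq")
    assert mapping.read_fastq(tmp_path / "x.fastq") == reads
    refs = {"c1": "ACGT" * 40, "c2": "TTAA" * 30}
    mapping.write_fasta(refs, tmp_path / "x.fasta")
    assert mapping.read_fasta(tmp_path / "x.fasta") == refs
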