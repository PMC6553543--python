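import numpy as np
import pysam
import pytest

from polyac.pas import (
    PasConfig, PolyASite, apply_internal_priming_mask, collect_pas,
    mask_internal_priming, read_pas_bedgraph, read_three_prime_end,
    site_counts_per_sample, write_pas_bedgraph,
)


def _aln(start, cigar="50M", reverse=False, secondary=False, unmapped=False,
         qname="r:30A"):
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chr1", "LN": 1_000_000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.reference_id = 0
    a.reference_start = start
    a.cigarstring = None if unmapped else cigar
    flag = 0
    if reverse:
        flag |= 16
    if secondary:
        flag |= 256
    if unmapped:
        flag |= 4
    a.flag = flag
    return a


class TestThreePrimeEnd:
    def test_forward_rightmost_base(self):
        assert read_three_prime_end(_aln(1000, "50M")) == ("chr1", 1049, "+")

    def test_reverse_leftmost_base(self):
        assert read_three_prime_end(_aln(1000, "50M", reverse=True)) == ("chr1", 1000, "-")

    def test_spliced_alignment_walks_reference_ops(self):
        # 20M100N20M from 1000 consumes 140 reference bases -> last base 1139
        assert read_three_prime_end(_aln(1000, "20M100N20M")) == ("chr1", 1139, "+")

    def test_soft_clips_excluded(self):
        assert read_three_prime_end(_aln(1000, "5S40M5S")) == ("chr1", 1039, "+")

    def test_secondary_and_unmapped_skipped(self):
        assert read_three_prime_end(_aln(1000, secondary=True)) is None
        assert read_three_prime_end(_aln(1000, unmapped=True)) is None


class TestCollectPas:
    def test_five_qualified_reads_emit_site(self, sam_writer):
        path = sam_writer([(f"r{i}:30A", "chr1", 500, "+", 50) for i in range(5)])
        sites = collect_pas([path])
        assert len(sites) == 1
        s = sites[0]
        assert (s.chrom, s.position, s.strand) == ("chr1", 500, "+")
        assert s.qualified_reads == 5 and s.total_reads == 5

    def test_short_tails_do_not_qualify(self, sam_writer):
        path = sam_writer([(f"r{i}:24A", "chr1", 500, "+", 50) for i in range(10)])
        assert collect_pas([path]) == []

    def test_mixed_tails_qualified_below_floor(self, sam_writer):
        reads = [(f"q{i}:30A", "chr1", 500, "+", 50) for i in range(4)]
        reads += [(f"u{i}:12A", "chr1", 500, "+", 50) for i in range(6)]
        assert collect_pas([sam_writer(reads)]) == []
        # at a floor of 4 the site appears, with diagnostics intact
        sites = collect_pas([sam_writer(reads)], PasConfig(pas_min_reads=4))
        assert sites[0].qualified_reads == 4 and sites[0].total_reads == 10

    def test_unannotated_read_id_is_an_error(self, sam_writer):
        path = sam_writer([("plain_read", "chr1", 500, "+", 50)])
        with pytest.raises(ValueError, match="tail annotation"):
            collect_pas([path])

    def test_duplicate_read_ids_first_wins(self, sam_writer):
        reads = [(f"r{i}:30A", "chr1", 500, "+", 50) for i in range(5)]
        path = sam_writer(reads + [("r0:30A", "chr1", 900, "+", 50)])
        sites = collect_pas([path], PasConfig(pas_min_reads=1))
        assert [s.position for s in sites] == [500]

    def test_pooling_equals_per_sample_sum(self, sam_writer):
        rng = np.random.default_rng(0)
        samples = []
        for k in range(3):
            reads = [
                (f"s{k}r{i}:30A", "chr1", int(rng.integers(100, 120)), "+", 50)
                for i in range(40)
            ]
            samples.append(sam_writer(reads, name=f"s{k}.sam"))
        pooled = {
            (s.chrom, s.position, s.strand): s.qualified_reads
            for s in collect_pas(samples, PasConfig(pas_min_reads=1))
        }
        summed: dict = {}
        for path in samples:
            for key, n in site_counts_per_sample(path).items():
                summed[key] = summed.get(key, 0) + n
        assert pooled == summed

    def test_no_emitted_site_below_floor(self, sam_writer):
        rng = np.random.default_rng(1)
        reads = [
            (f"r{i}:{int(rng.integers(10, 40))}A", "chr1",
             int(rng.integers(100, 130)), "+", 50)
            for i in range(200)
        ]
        for s in collect_pas([sam_writer(reads)]):
            assert s.qualified_reads >= 5


class TestInternalPriming:
    def test_twelve_downstream_as_masked(self):
        genome = {"c": "G" * 101 + "A" * 12 + "CGTCGCGT" + "G" * 100}
        pas = PolyASite("c", 100, "+", 5, 5)
        assert mask_internal_priming(pas, genome) is True

    def test_sparse_as_not_masked(self):
        genome = {"c": "G" * 101 + "ACGT" * 5 + "G" * 100}
        pas = PolyASite("c", 100, "+", 5, 5)
        assert mask_internal_priming(pas, genome) is False

    def test_minus_strand_reads_reverse_complement_window(self):
        # 15 forward-strand T's upstream of a '-' site are 15 A's downstream
        # in transcript orientation
        genome = {"c": "G" * 85 + "T" * 15 + "G" * 100}
        pas = PolyASite("c", 100, "-", 5, 5)
        assert mask_internal_priming(pas, genome) is True

    def test_truncated_window_at_chrom_end(self):
        genome = {"c": "G" * 100 + "AAAAA"}  # only 5 nt downstream available
        pas = PolyASite("c", 99, "+", 5, 5)
        assert mask_internal_priming(pas, genome) is False

    def test_brute_force_agreement_on_random_genome(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = {"c": seq}
        cfg = PasConfig()
        for strand in "+-":
            for pos in range(0, 2000, 7):
                expected_win = (
                    seq[pos + 1:pos + 21] if strand == "+"
                    else seq[max(pos - 20, 0):pos]
                )
                base = "A" if strand == "+" else "T"
                expected = expected_win.count(base) >= 12
                got = mask_internal_priming(
                    PolyASite("c", pos, strand, 5, 5), genome, cfg
                )
                assert got == expected, (pos, strand)

    def test_split_kept_masked(self):
        genome = {"c": "G" * 101 + "A" * 20 + "G" * 100}
        sites = [PolyASite("c", 100, "+", 5, 5), PolyASite("c", 180, "+", 5, 5)]
        kept, masked = apply_internal_priming_mask(sites, genome)
        assert [s.position for s in kept] == [180]
        assert [s.position for s in masked] == [100] and masked[0].masked


class TestBedgraph:
    def test_empty_set_header_only(self, tmp_path):
        plus, minus = write_pas_bedgraph([], str(tmp_path / "x"))
        assert open(plus).read().startswith("track")
        assert len(open(plus).readlines()) == 1

    def test_single_site_line(self, tmp_path):
        paths = write_pas_bedgraph(
            [PolyASite("chr", 100, "+", 7, 7)], str(tmp_path / "x")
        )
        body = [l for l in open(paths[0]) if not l.startswith("track")]
        assert body == ["chr\t100\t101\t7\n"]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        sites = [
            PolyASite(
                "chr%d" % rng.integers(1, 3), int(rng.integers(0, 10_000)),
                "+" if rng.random() < 0.5 else "-",
                total_reads=int(n), qualified_reads=int(n),
            )
            for n in rng.integers(1, 50, size=60)
        ]
        # deduplicate positions (serialization keys on chrom/pos/strand)
        uniq = {s.key: s for s in sites}
        sites = sorted(uniq.values(), key=lambda s: s.key)
        plus, minus = write_pas_bedgraph(sites, str(tmp_path / "rt"))
        back = read_pas_bedgraph(plus, minus)
        assert [(s.key, s.qualified_reads) for s in back] == [
            (s.key, s.qualified_reads) for s in sites
        ]

    def test_signed_single_file(self, tmp_path):
        sites = [PolyASite("c", 5, "-", 3, 3)]
        (path,) = write_pas_bedgraph(sites, str(tmp_path / "s"), signed_single_file=True)
        assert "c\t5\t6\t-3" in open(path).read()
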