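import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adnauth import sam_io, simulate
from adnauth.sam_io import AlignmentSet

from conftest import make_read, make_set

DNA = st.text(alphabet="ACGT", min_size=3, max_size=80)


class TestLoadAlignments:
    @pytest.fixture()
    def sim_sam(self, tmp_path):
        cfg = simulate.SimConfig(seed=5, n_reads=100, ref_length=5000)
        ref = simulate.make_reference(cfg, fasta_path=str(tmp_path / "ref.fa"))
        aset = simulate.simulate_reads(ref, cfg,
                                       sam_path=str(tmp_path / "reads.sam"))
        return tmp_path, ref, aset

    def test_mapq_threshold_is_inclusive(self, tmp_path):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr", "LN": 1000}]}
        reads = [make_read("ACGTTGCA" * 5, "ACGTTGCA" * 5, mapq=q,
                           read_id=f"q{q}", start=10 * i)
                 for i, q in enumerate([0, 29, 30])]
        path = str(tmp_path / "mq.sam")
        sam_io.write_alignments(make_set(reads), path, header)
        got = sam_io.load_alignments(path, min_mapq=30, min_length=30)
        assert [r.read_id for r in got.reads] == ["q30"]
        assert got.filter_log["mapq"] == 2

    def test_length_threshold_is_inclusive(self, tmp_path):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr", "LN": 1000}]}
        r29 = make_read("ACGTTGCAA" * 3 + "AC", "ACGTTGCAA" * 3 + "AC",
                        read_id="len29")  # 29 bp
        r30 = make_read("ACGTTGCAA" * 3 + "ACG", "ACGTTGCAA" * 3 + "ACG",
                        read_id="len30", start=100)
        path = str(tmp_path / "len.sam")
        sam_io.write_alignments(make_set([r29, r30]), path, header)
        got = sam_io.load_alignments(path, min_mapq=0, min_length=30)
        assert [r.read_id for r in got.reads] == ["len30"]

    def test_roundtrip_against_simulator_ground_truth(self, sim_sam):
        tmp_path, ref, truth = sim_sam
        got = sam_io.load_alignments(str(tmp_path / "reads.sam"),
                                     min_mapq=0, min_length=1)
        assert len(got.reads) == len(truth.reads)
        by_id = {r.read_id: r for r in got.reads}
        for want in truth.reads:
            have = by_id[want.read_id]
            assert have.query_sequence == want.query_sequence
            assert have.strand == want.strand
            assert have.ref_aligned == want.ref_aligned
            assert have.ref_aligned == ref[want.reference_start:
                                           want.reference_end]

    def test_reference_fasta_substitutes_for_md(self, sim_sam, tmp_path):
        _, ref, truth = sim_sam
        # strip MD/NM tags so the reference FASTA is the only source
        src = str(tmp_path / "reads.sam")
        bare = str(tmp_path / "nomd.sam")
        with pysam.AlignmentFile(src) as fin, \
             pysam.AlignmentFile(bare, "w", template=fin) as fout:
            for rec in fin:
                rec.set_tag("MD", None)
                rec.set_tag("NM", None)
                fout.write(rec)
        with pytest.raises(sam_io.RecordError):
            sam_io.load_alignments(bare, min_mapq=0, min_length=1)
        got = sam_io.load_alignments(bare, reference=str(tmp_path / "ref.fa"),
                                     min_mapq=0, min_length=1)
        by_id = {r.read_id: r for r in got.reads}
        assert all(by_id[w.read_id].ref_aligned == w.ref_aligned
                   for w in truth.reads)

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(sam_io.InputError):
            sam_io.load_alignments(str(tmp_path / "absent.bam"))

    def test_empty_result_warns_not_raises(self, tmp_path):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr", "LN": 1000}]}
        path = str(tmp_path / "low.sam")
        sam_io.write_alignments(
            make_set([make_read("ACGTACGTACGTACGTACGTACGTACGTAC",
                                "ACGTACGTACGTACGTACGTACGTACGTAC", mapq=5)]),
            path, header)
        with pytest.warns(UserWarning):
            got = sam_io.load_alignments(path, min_mapq=30)
        assert len(got.reads) == 0


class TestEntropy:
    def test_homopolymer_scores_zero(self):
        assert sam_io.sequence_entropy("AAAAAAAAAA") == 0.0

    def test_hand_counted_repeat(self):
        # ACGTACGTACGT: 10 3-mers (ACG:3, CGT:3, GTA:2, TAC:2),
        # H = 1.971 bits, normaliser log2(10)
        assert sam_io.sequence_entropy("ACGTACGTACGT") == pytest.approx(
            59.33, abs=0.05)

    def test_all_64_kmers_scores_high(self, rng):
        # de-Bruijn-ish sequence containing every 3-mer about equally often
        bases = "ACGT"
        seq = "".join(a + b + c for a in bases for b in bases for c in bases)
        assert sam_io.sequence_entropy(seq) > 95

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sam_io.sequence_entropy("AC")

    def test_n_kmers_are_ignored(self):
        assert sam_io.sequence_entropy("AAANAAA") == 0.0

    @given(DNA)
    def test_score_bounded(self, seq):
        assert 0.0 <= sam_io.sequence_entropy(seq) <= 100.0


class TestFilterEntropy:
    def test_polya_removed_random_kept(self, rng):
        rand = "".join(rng.choice(list("ACGT"), size=50))
        aset = make_set([make_read("A" * 50, "A" * 50, read_id="polyA"),
                         make_read(rand, rand, read_id="rand", start=100)])
        got = sam_io.filter_entropy(aset, 50.0)
        assert [r.read_id for r in got.reads] == ["rand"]
        assert got.filter_log["entropy"] == 1

    def test_threshold_zero_keeps_non_degenerate(self):
        aset = make_set([make_read("ACACAC", "ACACAC")])
        assert len(sam_io.filter_entropy(aset, 0.0).reads) == 1

    def test_most_random_reads_survive_default_threshold(self, rng):
        reads = [make_read(s := "".join(rng.choice(list("ACGT"), size=40)), s,
                           read_id=f"r{i}", start=i)
                 for i in range(100)]
        got = sam_io.filter_entropy(make_set(reads), 50.0)
        assert len(got.reads) >= 95

    def test_idempotent(self, rng):
        reads = [make_read(s := "".join(rng.choice(list("ACGT"), size=40)), s,
                           read_id=f"r{i}", start=i)
                 for i in range(30)]
        once = sam_io.filter_entropy(make_set(reads), 50.0)
        twice = sam_io.filter_entropy(once, 50.0)
        assert [r.read_id for r in twice.reads] == \
            [r.read_id for r in once.reads]


class TestDeduplicate:
    def test_highest_mapq_wins(self):
        a = make_read("ACGTACGTAC", "ACGTACGTAC", mapq=30, read_id="a")
        b = make_read("ACGTACGTAC", "ACGTACGTAC", mapq=37, read_id="b")
        got = sam_io.deduplicate(make_set([a, b]))
        assert [r.read_id for r in got.reads] == ["b"]

    def test_mapq_tie_smallest_id(self):
        a = make_read("ACGTACGTAC", "ACGTACGTAC", mapq=30, read_id="zz")
        b = make_read("ACGTACGTAC", "ACGTACGTAC", mapq=30, read_id="aa")
        got = sam_io.deduplicate(make_set([a, b]))
        assert [r.read_id for r in got.reads] == ["aa"]

    def test_strand_is_part_of_key(self):
        a = make_read("ACGTACGTAC", "ACGTACGTAC", strand="+", read_id="f")
        b = make_read("ACGTACGTAC", "ACGTACGTAC", strand="-", read_id="r")
        assert len(sam_io.deduplicate(make_set([a, b])).reads) == 2

    def test_known_key_multiset(self):
        # 40 unique keys + 10 reads sharing one key -> 41 survivors
        reads = [make_read("ACGTACGTAC", "ACGTACGTAC", start=i,
                           read_id=f"u{i}") for i in range(40)]
        reads += [make_read("ACGTACGTAC", "ACGTACGTAC", start=999, mapq=q,
                            read_id=f"d{q}") for q in range(10)]
        got = sam_io.deduplicate(make_set(reads))
        assert len(got.reads) == 41
        assert got.filter_log["duplicate"] == 9

    def test_idempotent_and_counts_balance(self, library_pair):
        anc, _ = library_pair
        once = sam_io.deduplicate(anc)
        twice = sam_io.deduplicate(once)
        assert len(twice.reads) == len(once.reads)
        assert sum(once.filter_log.values()) == \
            len(anc.reads) - len(once.reads)


def test_filter_report_roundtrip(tmp_path, library_pair):
    anc, _ = library_pair
    aset = sam_io.filter_entropy(sam_io.deduplicate(anc), 50.0)
    path = tmp_path / "report.tsv"
    sam_io.write_filter_report(aset, str(path))
    lines = path.read_text().strip().split("\n")
    assert lines[0] == "filter_name\treads_removed\treads_remaining"
    total = lines[-1].split("\t")
    assert int(total[2]) == len(aset.reads)
    assert int(total[1]) == sum(aset.filter_log.values())
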