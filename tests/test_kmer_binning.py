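"""k-mer counting, hap-mer extraction and read binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triobin import _kmers
from triobin import kmer_binning as kb
from triobin import simulate as sim
from triobin.io import SequenceRecord, read_fasta


def brute_force_counts(seqs, k):
    """Independent oracle: slide a window, canonicalise each k-mer as a string."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k].upper()
            if any(c not in "ACGT" for c in w):
                continue
            canon = min(w, _kmers.revcomp(w))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


@pytest.mark.parametrize(
    "seqs,k,expected",
    [
        (["ACGT"], 3, {"ACG": 2}),  # ACG and CGT are reverse complements
        (["AAAA"], 3, {"AAA": 2}),
        (["ACNGT"], 3, {}),  # N breaks every window
        (["AC"], 3, {}),  # shorter than k
    ],
)
def test_count_kmers_examples(seqs, k, expected):
    assert kb.count_kmers(seqs, k=k).to_dict() == expected


def test_count_kmers_rejects_even_k():
    with pytest.raises(ValueError, match="odd"):
        kb.count_kmers(["ACGT"], k=4)


def test_count_kmers_min_count_filter():
    ks = kb.count_kmers(["ACGACG"], k=3, min_count_keep=2)
    # ACG appears at offsets 0 and 3; GAC/CGA once each
    assert ks.to_dict() == {"ACG": 2}


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=40), min_size=0, max_size=6),
    st.sampled_from([3, 5, 7, 21]),
)
def test_count_kmers_matches_brute_force(seqs, k):
    got = kb.count_kmers(seqs, k=k).to_dict()
    assert got == brute_force_counts(seqs, k)


def test_count_kmers_reads_fasta_and_fastq(tmp_path):
    from triobin.io import write_fasta, write_fastq

    fa = write_fasta(tmp_path / "r.fasta", {"r1": "ACGTACGT"})
    fq = write_fastq(tmp_path / "r.fastq.gz", [SequenceRecord("r1", "", "ACGTACGT", "IIIIIIII")])
    assert kb.count_kmers(fa, k=3).to_dict() == kb.count_kmers(fq, k=3).to_dict()
    assert kb.count_kmers(fa, k=3).to_dict() == brute_force_counts(["ACGTACGT"], 3)


def test_extract_hapmers_examples():
    a = kb.KmerSet.from_dict({"AAC": 5, "ACG": 4}, 3, "A")
    b = kb.KmerSet.from_dict({"ACG": 6, "ATG": 3}, 3, "B")
    hs = kb.extract_hapmers(a, b, min_count=2)
    assert hs.to_sets() == ({"AAC"}, {"ATG"})
    # identical parents -> both empty
    hs2 = kb.extract_hapmers(a, a, min_count=2)
    assert hs2.to_sets() == (set(), set())
    # noise floor
    hs3 = kb.extract_hapmers(
        kb.KmerSet.from_dict({"AAC": 1}, 3), kb.KmerSet.from_dict({}, 3), min_count=2
    )
    assert hs3.to_sets() == (set(), set())


def test_extract_hapmers_max_count_ceiling():
    a = kb.KmerSet.from_dict({"AAC": 50, "AGC": 5}, 3, "A")
    b = kb.KmerSet.from_dict({}, 3, "B")
    hs = kb.extract_hapmers(a, b, min_count=2, max_count=10)
    assert hs.to_sets()[0] == {"AGC"}


def test_extract_hapmers_k_mismatch():
    with pytest.raises(ValueError, match="k mismatch"):
        kb.extract_hapmers(kb.KmerSet.from_dict({}, 3), kb.KmerSet.from_dict({}, 5))


def test_bin_reads_examples():
    hs = kb.extract_hapmers(
        kb.KmerSet.from_dict({"AAC": 5}, 3, "A"),
        kb.KmerSet.from_dict({"ATG": 5}, 3, "B"),
        min_count=2,
    )
    asg, summary = kb.bin_reads(
        [("r1", "AACACG"), ("r2", "GGGGGG"), ("r3", "AC")], hs
    )
    by_id = {a.read_id: a for a in asg}
    assert (by_id["r1"].score_a, by_id["r1"].score_b, by_id["r1"].bin) == (1, 0, "A")
    assert by_id["r2"].bin == "unknown"  # no evidence
    assert by_id["r3"].bin == "unknown" and by_id["r3"].score_a == 0  # shorter than k
    assert summary.n_total == summary.n_a + summary.n_b + summary.n_unknown == 3


def test_bin_reads_tie_is_unknown():
    hs = kb.extract_hapmers(
        kb.KmerSet.from_dict({"AAC": 5}, 3, "A"),
        kb.KmerSet.from_dict({"ATG": 5}, 3, "B"),
        min_count=2,
    )
    # brute force over AACAGG: windows AAC,ACA,CAG,AGG -> canonical
    # AAC,ACA,CAG,CCT; one hit per parent -> 1-1 tie
    hs = kb.extract_hapmers(
        kb.KmerSet.from_dict({"AAC": 5}, 3, "A"),
        kb.KmerSet.from_dict({"AGG": 5}, 3, "B"),
        min_count=2,
    )
    asg, _ = kb.bin_reads([("r", "AACAGG")], hs)
    assert asg[0].score_a == asg[0].score_b == 1
    assert asg[0].bin == "unknown"


def test_summarize_binning_fractions():
    s = kb.BinningSummary(11_822_010, 4_586_239, 4_505_092, 2_730_679)
    assert f"{s.frac_a:.1f}" == "38.8"
    s2 = kb.summarize_binning(
        [kb.ReadAssignment(f"r{i}", 10, 0, 0, b) for i, b in enumerate(["A", "B", "unknown"])]
    )
    assert f"{s2.frac_a:.1f}" == "33.3"
    assert s2.frac_a + s2.frac_b + s2.frac_unknown == pytest.approx(100.0)


def test_summarize_binning_empty_rejected():
    with pytest.raises(ValueError):
        kb.summarize_binning([])


def test_parent_symmetry(small_long_reads, small_hapmers):
    """Swapping the parental hap-mer sets swaps bins A and B exactly."""
    reads, _, _ = small_long_reads
    subset = reads[:200]
    asg, _ = kb.bin_reads(subset, small_hapmers)
    asg_sw, _ = kb.bin_reads(subset, small_hapmers.swapped())
    flip = {"A": "B", "B": "A", "unknown": "unknown"}
    for x, y in zip(asg, asg_sw):
        assert y.bin == flip[x.bin]
        assert (y.score_a, y.score_b) == (x.score_b, x.score_a)


def test_identical_parents_all_unknown(small_config, small_trio):
    """Identical parental read sets -> no hap-mers -> 100% unknown."""
    hap_a, _, _ = small_trio
    ks = kb.count_kmers(sim.short_read_sequences(hap_a, small_config, "A", seed_salt=33),
                        k=21, parent_id="A")
    hs = kb.extract_hapmers(ks, ks, min_count=5)
    assert hs.n_a == hs.n_b == 0
    reads, _, _ = sim.simulate_long_reads(hap_a, hap_a, small_config)
    asg, summary = kb.bin_reads(reads[:100], hs)
    assert summary.frac_unknown == 100.0


def test_binning_truth_recovery(small_long_reads, small_hapmers):
    """On the simulated trio, assigned reads overwhelmingly match truth labels."""
    reads, truth, _ = small_long_reads
    asg, summary = kb.bin_reads(reads, small_hapmers)
    tb = sim.truth_bins(truth)
    binned = [a for a in asg if a.bin in ("A", "B")]
    assert binned, "no reads were assigned"
    acc = sum(1 for a in binned if a.bin == tb[a.read_id]) / len(binned)
    assert acc >= 0.99
    assert summary.n_a + summary.n_b + summary.n_unknown == len(reads)


def test_score_oracle_on_simulated_reads(small_long_reads, small_hapmers):
    """Scores equal brute-force sliding-window hap-mer occurrence counts."""
    reads, _, _ = small_long_reads
    sa, sb = small_hapmers.to_sets()
    for rec in reads[:5]:
        scored_a, scored_b = kb.score_read(rec.sequence, small_hapmers)
        exp_a = exp_b = 0
        for i in range(len(rec.sequence) - 21 + 1):
            w = rec.sequence[i : i + 21]
            canon = min(w, _kmers.revcomp(w))
            exp_a += canon in sa
            exp_b += canon in sb
        assert (scored_a, scored_b) == (exp_a, exp_b)


def test_write_bins_round_trip(tmp_path):
    hs = kb.extract_hapmers(
        kb.KmerSet.from_dict({"AAC": 5}, 3, "A"),
        kb.KmerSet.from_dict({"ATG": 5}, 3, "B"),
        min_count=2,
    )
    recs = [
        SequenceRecord("r1", "", "AACAACAAC"),
        SequenceRecord("r2", "", "ATGATGATG"),
        SequenceRecord("r3", "", "GGGGGGGGG"),
    ]
    asg, _ = kb.bin_reads(recs, hs)
    paths = kb.write_bins(asg, recs, tmp_path / "bins")
    got = {}
    for p in paths.values():
        for r in read_fasta(p):
            assert r.id not in got, "read written to more than one bin"
            got[r.id] = r.sequence
    assert got == {r.id: r.sequence for r in recs}
    assert [r.id for r in read_fasta(paths["A"])] == ["r1"]
    assert [r.id for r in read_fasta(paths["B"])] == ["r2"]


def test_write_bins_all_unknown_creates_empty_files(tmp_path):
    hs = kb.extract_hapmers(kb.KmerSet.from_dict({}, 3), kb.KmerSet.from_dict({}, 3))
    recs = [SequenceRecord("r1", "", "GGGGGG")]
    asg, _ = kb.bin_reads(recs, hs)
    paths = kb.write_bins(asg, recs, tmp_path / "bins")
    assert paths["A"].exists() and paths["A"].stat().st_size == 0
    assert list(read_fasta(paths["unknown"]))[0].id == "r1"


def test_write_bins_missing_read_is_hard_error(tmp_path):
    asg = [kb.ReadAssignment("ghost", 10, 1, 0, "A")]
    with pytest.raises(ValueError, match="ghost"):
        kb.write_bins(asg, [SequenceRecord("r1", "", "AAA")], tmp_path / "bins")


def test_kmerset_and_hapmers_npz_round_trip(tmp_path):
    ks = kb.KmerSet.from_dict({"AAC": 5, "ACG": 4}, 3, "P1")
    ks2 = kb.KmerSet.load(ks.save(tmp_path / "ks.npz"))
    assert ks2.to_dict() == ks.to_dict() and ks2.parent_id == "P1" and ks2.k == 3
    hs = kb.extract_hapmers(ks, kb.KmerSet.from_dict({"ATG": 9}, 3, "P2"), min_count=2)
    hs2 = kb.HapmerSets.load(hs.save(tmp_path / "hs.npz"))
    assert hs2.to_sets() == hs.to_sets()
    assert (hs2.parent_a, hs2.parent_b, hs2.min_count) == ("P1", "P2", 2)


def test_normalized_decision_rule():
    """Normalisation divides by set size: a 1-1 raw tie breaks toward the
    parent with the smaller hap-mer set."""
    hs = kb.extract_hapmers(
        kb.KmerSet.from_dict({"AAC": 5}, 3, "A"),
        kb.KmerSet.from_dict({"AGG": 5, "ATG": 5}, 3, "B"),
        min_count=2,
    )
    # AACAGG scores 1-1 raw (tie -> unknown), but 1/1 vs 1/2 normalized -> A
    asg_raw, _ = kb.bin_reads([("r", "AACAGG")], hs)
    assert asg_raw[0].bin == "unknown"
    asg, _ = kb.bin_reads([("r", "AACAGG")], hs, normalize=True)
    assert asg[0].bin == "A"
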