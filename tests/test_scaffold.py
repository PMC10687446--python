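"""Contig placement, scaffold construction, gap patching, workflow driver."""

import pytest

from triobin import qc
from triobin import scaffold as sc
from triobin import simulate as sim
from triobin._kmers import revcomp
from triobin.agp import Component, read_agp, write_agp
from triobin.io import PafRecord, read_fasta, write_fasta, write_paf


def paf(qname, qlen, qstart, qend, strand, tname, tstart, tend,
        n_matches=None, mapq=60, tlen=10_000_000):
    bl = max(qend - qstart, tend - tstart)
    return PafRecord(qname, qlen, qstart, qend, strand, tname, tlen, tstart, tend,
                     n_matches if n_matches is not None else bl, bl, mapq)


def test_filter_alignments():
    recs = [paf("q", 2000, 0, 500, "+", "t", 0, 500),
            paf("q", 2000, 0, 1500, "+", "t", 0, 1500),
            paf("q", 2000, 0, 1500, "+", "t", 0, 1500, mapq=5)]
    out = sc.filter_alignments(recs, min_len=1000, min_mapq=10)
    assert out == [recs[1]]
    assert sc.filter_alignments([], 1000, 10) == []


def test_place_contigs_single_record():
    placements, unplaced = sc.place_contigs(
        [paf("c1", 1000, 0, 1000, "+", "chr1", 5000, 6000)], contig_names=["c1", "c2"])
    (p,) = placements
    assert (p.chrom, p.orientation) == ("chr1", "+")
    assert p.location_confidence == 1.0 and p.orientation_confidence == 1.0
    assert unplaced == ["c2"]


def test_place_contigs_split_coverage():
    """70% of the contig aligns to chr1, 30% to chr2."""
    recs = [paf("c1", 1000, 0, 700, "+", "chr1", 0, 700),
            paf("c1", 1000, 700, 1000, "+", "chr2", 0, 300)]
    (p,), _ = sc.place_contigs(recs)
    assert p.chrom == "chr1"
    assert p.location_confidence == pytest.approx(0.7)


def test_place_contigs_tie_lexicographic():
    recs = [paf("c1", 1000, 0, 500, "+", "chrB", 0, 500),
            paf("c1", 1000, 500, 1000, "+", "chrA", 0, 500)]
    (p,), _ = sc.place_contigs(recs)
    assert p.chrom == "chrA"
    assert p.low_confidence


def test_place_contigs_orientation_majority():
    recs = [paf("c1", 1000, 0, 600, "-", "chr1", 0, 600, n_matches=600),
            paf("c1", 1000, 600, 1000, "+", "chr1", 700, 1100, n_matches=400)]
    (p,), _ = sc.place_contigs(recs)
    assert p.orientation == "-"
    assert p.orientation_confidence == pytest.approx(0.6)


def test_build_scaffolds_toy():
    """c1 forward then c2 reverse joined by a 100 N gap, verified by direct
    string assembly."""
    seqs = {"c1": "AAAACCCC", "c2": "ACGTACGTT"}
    placements = [sc.Placement("c1", "chr1", "+", 0, 1.0, 1.0),
                  sc.Placement("c2", "chr1", "-", 2000, 1.0, 1.0)]
    plan, out = sc.build_scaffolds(placements, seqs, gap_len=100)
    assert out["chr1"] == "AAAACCCC" + "N" * 100 + revcomp("ACGTACGTT")


def test_build_scaffolds_single_and_unplaced():
    seqs = {"c1": "AAAA", "c2": "CCCC"}
    placements = [sc.Placement("c1", "chr1", "+", 0, 1.0, 1.0)]
    plan, out = sc.build_scaffolds(placements, seqs)
    assert out["chr1"] == "AAAA"  # no gap for a single component
    assert out["c2"] == "CCCC"  # unplaced emitted unchanged


def test_build_scaffolds_duplicate_placement_rejected():
    seqs = {"c1": "AAAA"}
    placements = [sc.Placement("c1", "chr1", "+", 0, 1.0, 1.0),
                  sc.Placement("c1", "chr2", "+", 0, 1.0, 1.0)]
    with pytest.raises(ValueError, match="more than once"):
        sc.build_scaffolds(placements, seqs)


def test_agp_components_reconstruct_scaffold_bytes(tmp_path):
    seqs = {"c1": "AAAACCCCGGGG", "c2": "ACGTACGT"}
    placements = [sc.Placement("c1", "chr1", "+", 0, 1.0, 1.0),
                  sc.Placement("c2", "chr1", "-", 500, 1.0, 1.0)]
    plan, out = sc.build_scaffolds(placements, seqs)
    p = write_agp(plan, tmp_path / "x.agp")
    again = read_agp(p)
    assert again.sequences(seqs) == out  # byte-identical reconstruction


def test_patch_gaps_toy():
    """Spec-style toy: donor spans the gap anchored on both flanks."""
    target = {"s": "AAAAG" + "N" * 10 + "CCCCG"}
    donor = {"d": "AAAAGTTTTCCCCG"}
    aln = [paf("d", 14, 0, 5, "+", "s", 0, 5, tlen=20),
           paf("d", 14, 9, 14, "+", "s", 15, 20, tlen=20)]
    patched, plan = sc.patch_gaps(target, aln, donor, flank=50)
    assert patched["s"] == "AAAAGTTTTCCCCG"
    assert len(plan.edits) == 1 and plan.edits[0].donor == "d"


def test_patch_gaps_minus_strand_donor():
    target = {"s": "AAAAG" + "N" * 10 + "CCCCG"}
    fill = "AAAAGTTTTCCCCG"
    donor = {"d": revcomp(fill)}  # donor stored reverse-complemented
    # minus-strand anchors: left flank of target maps to the donor's 3' end
    aln = [paf("d", 14, 9, 14, "-", "s", 0, 5, tlen=20),
           paf("d", 14, 0, 5, "-", "s", 15, 20, tlen=20)]
    patched, _ = sc.patch_gaps(target, aln, donor, flank=50)
    assert patched["s"] == fill


def test_patch_gaps_no_spanning_donor_leaves_input():
    target = {"s": "AAAAG" + "N" * 10 + "CCCCG"}
    donor = {"d": "AAAAG"}
    aln = [paf("d", 5, 0, 5, "+", "s", 0, 5, tlen=20)]
    patched, plan = sc.patch_gaps(target, aln, donor)
    assert patched == target
    assert plan.edits == []


def test_patch_gaps_conflicting_donors_logged():
    target = {"s": "AAAAG" + "N" * 10 + "CCCCG"}
    donor = {"d1": "AAAAGTTTTCCCCG", "d2": "AAAAGAAAACCCCG"}
    aln = [paf("d1", 14, 0, 5, "+", "s", 0, 5, tlen=20),
           paf("d1", 14, 9, 14, "+", "s", 15, 20, tlen=20),
           paf("d2", 14, 0, 5, "+", "s", 0, 5, tlen=20),
           paf("d2", 14, 9, 14, "+", "s", 15, 20, tlen=20)]
    patched, plan = sc.patch_gaps(target, aln, donor)
    assert patched == target
    assert len(plan.conflicts) == 1


def test_patch_never_increases_gap_count():
    target = {"s": "AAAAG" + "N" * 10 + "CCCCG" + "N" * 5 + "TTTTT"}
    patched, _ = sc.patch_gaps(target, [], {})
    assert len(qc.find_gaps(patched)) <= len(qc.find_gaps(target))


# ---------------------------------------------------------------------------
# simulation-backed recovery


@pytest.fixture(scope="module")
def shredded_genome():
    cfg = sim.SimConfig(seed=21, n_chroms=2, chrom_len=400_000)
    genome, _, _ = sim.simulate_parents(cfg)
    frags, fmap = sim.shred(genome, frag_mean=40_000, frag_sd=10_000,
                            orient_prob=0.5, seed=21)
    truth_paf = sim.shred_truth_paf(fmap, {c: len(s) for c, s in genome.items()})
    return genome, frags, fmap, truth_paf


def test_shredded_genome_order_and_orientation_recovered(shredded_genome):
    genome, frags, fmap, truth_paf = shredded_genome
    placements, unplaced = sc.place_contigs(sc.filter_alignments(truth_paf), frags)
    assert unplaced == []
    plan, out = sc.build_scaffolds(placements, frags)
    truth_order = {}
    for f in fmap:
        truth_order.setdefault(f.chrom, []).append((f.name, f.strand))
    for scaffold in plan.scaffolds:
        comps = [p for p in scaffold.parts if isinstance(p, Component)]
        assert [(c.contig, c.orientation) for c in comps] == truth_order[scaffold.name]


def test_scaffold_n50_not_below_contig_n50(shredded_genome):
    genome, frags, fmap, truth_paf = shredded_genome
    placements, _ = sc.place_contigs(sc.filter_alignments(truth_paf))
    plan, out = sc.build_scaffolds(placements, frags)
    assert qc.nstats([len(s) for s in out.values()]).n50 >= qc.nstats(
        [len(s) for s in frags.values()]).n50


def test_scaffold_conserves_sequence(shredded_genome):
    """Non-gap bases of the scaffolds equal the input contig bases."""
    genome, frags, fmap, truth_paf = shredded_genome
    placements, _ = sc.place_contigs(sc.filter_alignments(truth_paf))
    plan, out = sc.build_scaffolds(placements, frags)
    assert {c: s.replace("N", "") for c, s in out.items()} == genome


def test_gap_patching_with_truth_donor_restores_genome():
    """Dropout creates gaps; patching with the truth genome as donor fills
    every unique-flank gap and restores the chromosome exactly."""
    cfg = sim.SimConfig(seed=22, n_chroms=1, chrom_len=400_000)
    genome, _, _ = sim.simulate_parents(cfg)
    frags, fmap = sim.shred(genome, frag_mean=30_000, frag_sd=5_000,
                            dropout=0.2, orient_prob=0.5, seed=5)
    lengths = {c: len(s) for c, s in genome.items()}
    placements, _ = sc.place_contigs(sim.shred_truth_paf(fmap, lengths))
    plan, scaffolds = sc.build_scaffolds(placements, frags)
    donor_paf = sim.donor_truth_paf(plan, fmap, lengths)
    patched, patch_plan = sc.patch_gaps(scaffolds, donor_paf, genome)
    assert patch_plan.conflicts == []
    assert qc.find_gaps(patched) == []
    # dropped interior fragments and gap Ns replaced by exact truth sequence:
    # the patched scaffold spans truth from the first to the last kept fragment
    kept = [f for f in fmap if f.kept]
    assert patched["chr1"] == genome["chr1"][kept[0].start : kept[-1].end]


def test_workflow_two_steps(tmp_path):
    cfg = sim.SimConfig(seed=23, n_chroms=1, chrom_len=200_000)
    genome, _, _ = sim.simulate_parents(cfg)
    frags, fmap = sim.shred(genome, frag_mean=20_000, frag_sd=4_000,
                            dropout=0.15, orient_prob=0.5, seed=2)
    lengths = {c: len(s) for c, s in genome.items()}
    write_fasta(tmp_path / "frags.fasta", frags)
    write_fasta(tmp_path / "truth.fasta", genome)
    write_paf(tmp_path / "frags.paf", sim.shred_truth_paf(fmap, lengths))
    placements, _ = sc.place_contigs(sim.shred_truth_paf(fmap, lengths))
    plan, _ = sc.build_scaffolds(placements, frags)
    write_paf(tmp_path / "donor.paf", sim.donor_truth_paf(plan, fmap, lengths))
    steps = [
        sc.WorkflowStep("s1_scaffold", "scaffold", str(tmp_path / "frags.fasta"),
                        str(tmp_path / "truth.fasta"), str(tmp_path / "frags.paf")),
        sc.WorkflowStep("s2_patch", "patch", "previous",
                        str(tmp_path / "truth.fasta"), str(tmp_path / "donor.paf")),
    ]
    final, stats = sc.run_workflow(steps, tmp_path / "wf")
    assert len(stats) == 2
    assert stats.iloc[0]["scaffold_n50"] >= qc.nstats(
        [len(s) for s in frags.values()]).n50
    out = {r.id: r.sequence for r in read_fasta(final)}
    kept = [f for f in fmap if f.kept]
    assert out["chr1"] == genome["chr1"][kept[0].start : kept[-1].end]


def test_workflow_missing_input_aborts(tmp_path):
    steps = [sc.WorkflowStep("s1", "scaffold", str(tmp_path / "nope.fasta"),
                             None, str(tmp_path / "nope.paf"))]
    with pytest.raises(FileNotFoundError, match="s1"):
        sc.run_workflow(steps, tmp_path / "wf")


def test_workflow_empty_step_list(tmp_path):
    final, stats = sc.run_workflow([], tmp_path / "wf")
    assert len(stats) == 0


def test_workflow_config_round_trip(tmp_path):
    cfgfile = tmp_path / "wf.yaml"
    cfgfile.write_text(
        "steps:\n"
        "  - name: one\n    action: scaffold\n    query: q.fasta\n"
        "    reference: r.fasta\n    alignments: a.paf\n"
        "  - action: patch\n    query: previous\n    donor: d.fasta\n"
        "    alignments: b.paf\n    params: {flank: 1000}\n"
    )
    steps = sc.load_workflow_config(cfgfile)
    assert steps[0].name == "one" and steps[0].action == "scaffold"
    assert steps[1].name == "step2" and steps[1].reference == "d.fasta"
    assert steps[1].params == {"flank": 1000}
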