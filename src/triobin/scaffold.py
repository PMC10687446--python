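"""Homology (reference-guided) scaffolding and gap patching.

Contigs are placed whole — never broken — onto the reference chromosome
where their alignments concentrate, oriented by the strand carrying the
most aligned matches, ordered along the chromosome by coverage-weighted
mean alignment start, and joined with fixed-length N gaps into scaffolds
described by an AGP 2.1 plan.  Gap patching fills an N-run when a single
donor sequence aligns to both gap flanks collinearly in one orientation,
splicing in the intervening donor sequence.  A workflow driver chains
scaffold/patch steps and records contiguity statistics after each.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .agp import Component, Gap, Scaffold, ScaffoldPlan, write_agp
from .io import PafRecord, read_fasta, read_paf, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class Placement:
    contig: str
    chrom: str
    orientation: str  # '+' or '-'
    order_key: float  # reference bp
    location_confidence: float
    orientation_confidence: float
    low_confidence: bool = False


@dataclass
class PatchEdit:
    scaffold: str
    gap_start: int
    gap_end: int
    donor: str
    donor_start: int
    donor_end: int
    orientation: str


@dataclass
class PatchPlan:
    edits: list[PatchEdit] = field(default_factory=list)
    conflicts: list[tuple[str, int, int, str]] = field(default_factory=list)


def filter_alignments(
    records: Iterable[PafRecord], min_len: int = 1000, min_mapq: int = 10,
) -> list[PafRecord]:
    """Keep records with block length >= min_len and mapq >= min_mapq."""
    return [r for r in records if r.block_len >= min_len and r.mapq >= min_mapq]


def _union_len(intervals: list[tuple[int, int]]) -> int:
    intervals.sort()
    total = 0
    cur_s, cur_e = None, None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def place_contigs(
    records: Iterable[PafRecord], contig_names: Iterable[str] | None = None,
) -> tuple[list[Placement], list[str]]:
    """Assign each query contig a chromosome, orientation and order key.

    Chromosome: the target with the largest merged query-interval
    coverage (location_confidence = best / total over chromosomes; ties
    broken by lexicographically smaller name, flagged low-confidence).
    Orientation: sign of the strand-weighted match mass on the winning
    chromosome; zero net mass defaults to '+' at confidence 0.5.
    Order key: coverage-weighted mean of target starts.
    Returns (placements, names of contigs with no surviving alignment —
    populated when ``contig_names`` supplies the full contig list).
    """
    by_contig: dict[str, dict[str, list[PafRecord]]] = {}
    for r in records:
        by_contig.setdefault(r.qname, {}).setdefault(r.tname, []).append(r)
    unplaced = (
        sorted(set(contig_names) - set(by_contig)) if contig_names is not None else []
    )

    placements: list[Placement] = []
    for contig in sorted(by_contig):
        per_chrom = by_contig[contig]
        cov = {t: _union_len([(r.qstart, r.qend) for r in rs]) for t, rs in per_chrom.items()}
        total_cov = sum(cov.values())
        best_cov = max(cov.values())
        winners = sorted(t for t, c in cov.items() if c == best_cov)
        chrom = winners[0]
        tied = len(winners) > 1
        loc_conf = best_cov / total_cov if total_cov else 0.0

        win = per_chrom[chrom]
        mass = sum((1 if r.strand == "+" else -1) * r.n_matches for r in win)
        total_mass = sum(r.n_matches for r in win)
        if mass > 0:
            orient, oconf = "+", 0.5 + 0.5 * mass / total_mass
        elif mass < 0:
            orient, oconf = "-", 0.5 - 0.5 * mass / total_mass
        else:
            orient, oconf = "+", 0.5
        weights = [r.qend - r.qstart for r in win]
        order_key = float(np.average([r.tstart for r in win], weights=weights))
        placements.append(Placement(
            contig, chrom, orient, order_key, loc_conf, oconf,
            low_confidence=tied or mass == 0 or loc_conf < 0.5,
        ))
    return placements, unplaced


def build_scaffolds(
    placements: Sequence[Placement], contig_seqs: Mapping[str, str], gap_len: int = 100,
) -> tuple[ScaffoldPlan, dict[str, str]]:
    """Join placed contigs into per-chromosome scaffolds with N gaps.

    Contigs are sorted by order key (ties by name); '-' components are
    reverse-complemented.  Contigs absent from ``placements`` are emitted
    unchanged as single-component objects.  Scaffolds adopt reference
    chromosome names.
    """
    seen: set[str] = set()
    for p in placements:
        if p.contig in seen:
            raise ValueError(f"contig {p.contig!r} placed more than once")
        seen.add(p.contig)
        if p.contig not in contig_seqs:
            raise ValueError(f"placed contig {p.contig!r} has no sequence")

    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p)

    plan = ScaffoldPlan()
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.order_key, p.contig))
        sc = Scaffold(chrom)
        for i, p in enumerate(ordered):
            if i:
                sc.parts.append(Gap(gap_len))
            sc.parts.append(Component(p.contig, 0, len(contig_seqs[p.contig]), p.orientation))
        plan.scaffolds.append(sc)
    for contig in contig_seqs:
        if contig not in seen:
            sc = Scaffold(contig)
            sc.parts.append(Component(contig, 0, len(contig_seqs[contig]), "+"))
            plan.scaffolds.append(sc)
    return plan, plan.sequences(contig_seqs)


def _find_gaps(seq: str, min_run: int = 1) -> list[tuple[int, int]]:
    import re

    return [
        (m.start(), m.end())
        for m in re.finditer(r"[Nn]+", seq)
        if m.end() - m.start() >= min_run
    ]


def patch_gaps(
    target_seqs: Mapping[str, str], donor_alignments: Iterable[PafRecord],
    donor_seqs: Mapping[str, str], flank: int = 50_000,
) -> tuple[dict[str, str], PatchPlan]:
    """Fill N-gaps in the target using donor sequence spanning both flanks.

    A gap is patched when one donor contig has alignments anchoring both
    flanks (within ``flank`` bp of the gap) on the same strand in
    collinear order; the gap plus any flank overlap implied by the anchor
    coordinates is replaced by the intervening donor sequence.  Anchors
    are the longest qualifying flank alignments.  Gaps with conflicting
    qualifying donors are left untouched and logged.
    """
    from ._kmers import revcomp

    by_target: dict[str, list[PafRecord]] = {}
    for r in donor_alignments:
        by_target.setdefault(r.tname, []).append(r)

    patched: dict[str, str] = {}
    plan = PatchPlan()
    for tname, seq in target_seqs.items():
        gaps = _find_gaps(seq)
        if not gaps:
            patched[tname] = seq
            continue
        recs = by_target.get(tname, [])
        edits: list[tuple[int, int, str]] = []  # (cut_start, cut_end, replacement)
        last_cut_end = -1
        for gs, ge in gaps:
            lefts = [r for r in recs if r.tend <= gs and r.tend >= gs - flank
                     and r.tend > last_cut_end]
            rights = [r for r in recs if r.tstart >= ge and r.tstart <= ge + flank]
            candidates = []
            for ln in lefts:
                for rn in rights:
                    if ln.qname != rn.qname or ln.strand != rn.strand:
                        continue
                    if ln.strand == "+":
                        if ln.qend <= rn.qstart:
                            candidates.append((ln, rn, ln.qend, rn.qstart))
                    else:
                        if rn.qend <= ln.qstart:
                            candidates.append((ln, rn, rn.qend, ln.qstart))
            if not candidates:
                continue
            donors = {c[0].qname for c in candidates}
            if len(donors) > 1:
                plan.conflicts.append((tname, gs, ge, "multiple donors: " + ",".join(sorted(donors))))
                continue
            # anchors: nearest to the gap, then longest flank alignment
            def rank(c):
                ln, rn, _, _ = c
                prox = (gs - ln.tend) + (rn.tstart - ge)
                length = (ln.tend - ln.tstart) + (rn.tend - rn.tstart)
                return (prox, -length)

            ln, rn, q_lo, q_hi = min(candidates, key=rank)
            fill = donor_seqs[ln.qname][q_lo:q_hi]
            if ln.strand == "-":
                fill = revcomp(fill)
            edits.append((ln.tend, rn.tstart, fill))
            last_cut_end = rn.tstart
            plan.edits.append(PatchEdit(tname, gs, ge, ln.qname, q_lo, q_hi, ln.strand))
        # apply edits right-to-left so coordinates stay valid
        new_seq = seq
        for cut_s, cut_e, fill in sorted(edits, reverse=True):
            new_seq = new_seq[:cut_s] + fill + new_seq[cut_e:]
        patched[tname] = new_seq
    return patched, plan


# ---------------------------------------------------------------------------
# workflow driver


@dataclass
class WorkflowStep:
    name: str
    action: str  # 'scaffold' | 'patch'
    query: str  # FASTA path (target for patch)
    reference: str | None = None  # reference (scaffold) or donor (patch) FASTA
    alignments: str | None = None  # PAF; aligned with minimap2 when absent
    params: dict = field(default_factory=dict)


def load_workflow_config(path: str | Path) -> list[WorkflowStep]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    steps = []
    for i, s in enumerate(doc.get("steps", [])):
        steps.append(WorkflowStep(
            name=s.get("name", f"step{i + 1}"), action=s["action"], query=s["query"],
            reference=s.get("reference") or s.get("donor"),
            alignments=s.get("alignments"), params=s.get("params", {}),
        ))
    return steps


def _align_with_minimap2(query: Path, reference: Path, out_paf: Path) -> Path:
    exe = shutil.which("minimap2")
    if exe is None:
        raise FileNotFoundError(
            "step lists no alignments file and minimap2 is not on PATH"
        )
    with open(out_paf, "w") as fh:
        subprocess.run([exe, "-x", "asm5", "-c", str(reference), str(query)],
                       stdout=fh, check=True)
    return out_paf


def run_workflow(
    steps: Sequence[WorkflowStep], out_dir: str | Path,
) -> tuple[Path, "pd.DataFrame"]:
    """Execute ordered scaffold/patch steps; after each, write the result
    FASTA and record contig/scaffold contiguity statistics.  Any step's
    reference may be an externally produced (e.g. hybrid) assembly."""
    import pandas as pd

    from .qc import assembly_stats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    current: Path | None = None
    for step in steps:
        query = Path(step.query if current is None or step.query != "previous" else current)
        for p in [query] + ([Path(step.reference)] if step.reference else []):
            if not p.exists():
                raise FileNotFoundError(f"workflow step {step.name!r}: missing input {p}")
        paf_path = Path(step.alignments) if step.alignments else _align_with_minimap2(
            query, Path(step.reference), out_dir / f"{step.name}.paf")
        records = filter_alignments(
            read_paf(paf_path),
            min_len=step.params.get("min_len", 1000),
            min_mapq=step.params.get("min_mapq", 10),
        )
        seqs = {r.id: r.sequence for r in read_fasta(query)}
        if step.action == "scaffold":
            placements, _ = place_contigs(records)
            plan, out_seqs = build_scaffolds(placements, seqs,
                                             gap_len=step.params.get("gap_len", 100))
            write_agp(plan, out_dir / f"{step.name}.agp")
        elif step.action == "patch":
            donor = {r.id: r.sequence for r in read_fasta(Path(step.reference))}
            out_seqs, _ = patch_gaps(seqs, records, donor,
                                     flank=step.params.get("flank", 50_000))
        else:
            raise ValueError(f"workflow step {step.name!r}: unknown action {step.action!r}")
        current = write_fasta(out_dir / f"{step.name}.fasta", out_seqs)
        st = assembly_stats(out_seqs)
        rows.append({
            "step": step.name, "action": step.action,
            "n_scaffolds": st.scaffolds.n, "scaffold_n50": st.scaffolds.n50,
            "scaffold_n90": st.scaffolds.n90, "n_contigs": st.contigs.n,
            "contig_n50": st.contigs.n50, "total_size": st.scaffolds.total,
        })
    stats = pd.DataFrame(rows, columns=["step", "action", "n_scaffolds", "scaffold_n50",
                                        "scaffold_n90", "n_contigs", "contig_n50", "total_size"])
    stats.to_csv(out_dir / "workflow_stats.tsv", sep="\t", index=False)
    return (current if current is not None else Path("")), stats
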