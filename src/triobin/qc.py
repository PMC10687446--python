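"""Assembly QC: contiguity statistics, gap discovery, telomere repeats,
heterozygosity from alignment differences, and dotplot data export.

N50 is the length of the shortest sequence in the minimal set of longest
sequences whose summed length covers at least half the assembly; L50 is
the size of that set (N90/L90 analogously at 90%).  Telomere repeat
units are rotation- and strand-ambiguous, so candidate units are
canonicalised to the lexicographically smallest string over all
rotations of the unit and of its reverse complement.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kmers import revcomp
from .io import PafRecord, read_fasta, read_paf


@dataclass
class SizeStats:
    n: int
    total: int
    longest: int
    n50: int
    l50: int
    n90: int
    l90: int


@dataclass
class AssemblyStats:
    scaffolds: SizeStats
    contigs: SizeStats
    gap_bases: int


@dataclass
class GapRecord:
    contig: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TelomereCandidate:
    unit: str  # canonical rotation class
    example: str  # a unit as observed in the sequence
    length: int
    copies: int  # total tandem copies over all terminal regions


@dataclass
class HetEstimate:
    n_snp: int
    n_indel_positions: int
    denominator: int
    rate: float  # percent


def nstats(lengths: Iterable[int]) -> SizeStats:
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        raise ValueError("no sequences")
    total = sum(ls)
    cum = 0
    n50 = l50 = n90 = l90 = 0
    for i, x in enumerate(ls, start=1):
        cum += x
        if not n50 and cum * 2 >= total:
            n50, l50 = x, i
        if not n90 and cum * 10 >= total * 9:
            n90, l90 = x, i
            break
    return SizeStats(len(ls), total, ls[0], n50, l50, n90, l90)


def split_contigs(seq: str, contig_split_n: int = 10) -> list[str]:
    """Split a scaffold into contigs at N-runs of at least ``contig_split_n``."""
    return [p for p in re.split("[Nn]{%d,}" % contig_split_n, seq) if p]


def assembly_stats(fasta, contig_split_n: int = 10) -> AssemblyStats:
    """Scaffold and contig N-statistics; contigs are scaffolds split at
    N-runs >= ``contig_split_n`` (with remaining Ns counted as contig sequence)."""
    if contig_split_n < 1:
        raise ValueError("contig_split_n must be >= 1")
    seqs = fasta if isinstance(fasta, Mapping) else {r.id: r.sequence for r in read_fasta(fasta)}
    if not seqs:
        raise ValueError("empty FASTA")
    scaffold_lens = [len(s) for s in seqs.values()]
    contig_lens = [len(c) for s in seqs.values() for c in split_contigs(s, contig_split_n)]
    gap_bases = sum(s.upper().count("N") for s in seqs.values())
    return AssemblyStats(nstats(scaffold_lens), nstats(contig_lens), gap_bases)


def find_gaps(fasta, min_run: int = 1) -> list[GapRecord]:
    """Maximal N-runs of length >= min_run, 0-based half-open."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seqs = fasta if isinstance(fasta, Mapping) else {r.id: r.sequence for r in read_fasta(fasta)}
    out = []
    for name, seq in seqs.items():
        for m in re.finditer("[Nn]+", seq):
            if m.end() - m.start() >= min_run:
                out.append(GapRecord(name, m.start(), m.end()))
    return out


# ---------------------------------------------------------------------------
# telomeres


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal string over all rotations of the unit and
    of its reverse complement."""
    rc = revcomp(unit)
    cands = [unit[i:] + unit[:i] for i in range(len(unit))]
    cands += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(cands)


def _primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def telomere_explore(
    fasta, min_len: int = 5, max_len: int = 12, terminal_bp: int = 50_000,
) -> list[TelomereCandidate]:
    """Rank candidate telomere repeat units found in terminal regions.

    For each unit length, tandem arrays (a unit repeated at least twice
    consecutively) within the first/last ``terminal_bp`` of each sequence
    are detected; copies accumulate per canonical rotation class and
    non-primitive units (multiples of a shorter period) are skipped.
    """
    if terminal_bp <= 0:
        raise ValueError("terminal_bp must be > 0")
    seqs = fasta if isinstance(fasta, Mapping) else {r.id: r.sequence for r in read_fasta(fasta)}
    copies: Counter[str] = Counter()
    example: dict[str, str] = {}
    for seq in seqs.values():
        regions = [seq[:terminal_bp]]
        if len(seq) > terminal_bp:
            regions.append(seq[-terminal_bp:])
        for region in regions:
            arr = np.frombuffer(region.encode("ascii"), dtype=np.uint8)
            for L in range(min_len, max_len + 1):
                if len(arr) < 2 * L:
                    continue
                eq = arr[:-L] == arr[L:]
                # maximal True runs of length >= L mark tandem arrays
                idx = np.flatnonzero(np.diff(np.concatenate([[0], eq.view(np.int8), [0]])))
                for s, e in zip(idx[::2], idx[1::2]):
                    run = e - s
                    if run < L:
                        continue
                    unit = region[s : s + L]
                    if "N" in unit or not _primitive(unit):
                        continue
                    canon = canonical_rotation(unit)
                    copies[canon] += run // L + 1
                    example.setdefault(canon, unit)
    ranked = [
        TelomereCandidate(u, example[u], len(u), c)
        for u, c in sorted(copies.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return ranked


def telomere_search(
    fasta, unit: str, window: int = 1000,
) -> pd.DataFrame:
    """Per-window counts of a repeat unit and its reverse complement.

    Overlapping occurrences are counted; an occurrence belongs to the
    window containing its start.  Returns a tidy frame with columns
    contig, start, end, forward, reverse.
    """
    if not unit:
        raise ValueError("empty telomere unit")
    seqs = fasta if isinstance(fasta, Mapping) else {r.id: r.sequence for r in read_fasta(fasta)}
    rc = revcomp(unit)
    rows = []
    for name, seq in seqs.items():
        n_win = (len(seq) + window - 1) // window
        fwd = np.zeros(n_win, dtype=np.int64)
        rev = np.zeros(n_win, dtype=np.int64)
        for motif, arr in ((unit, fwd), (rc, rev)):
            start = seq.find(motif)
            while start != -1:
                arr[start // window] += 1
                start = seq.find(motif, start + 1)  # overlapping scan
        for w in range(n_win):
            rows.append({
                "contig": name, "start": w * window,
                "end": min((w + 1) * window, len(seq)),
                "forward": int(fwd[w]), "reverse": int(rev[w]),
            })
    return pd.DataFrame(rows, columns=["contig", "start", "end", "forward", "reverse"])


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity(
    records, denominator_mode: str = "aligned", genome_size: int | None = None,
) -> HetEstimate:
    """Heterozygosity from unique-alignment difference counts.

    ``records``: iterable of (n_snp, n_indel_positions, aligned_len)
    rows, or a TSV path with those columns.  An indel counts as one
    position regardless of length.  The denominator is the summed aligned
    length (default) or a supplied genome size.
    """
    if isinstance(records, (str, Path)):
        df = pd.read_csv(records, sep="\t")
        rows = [(int(r.n_snp), int(r.n_indel_positions), int(r.aligned_len))
                for r in df.itertuples()]
    else:
        rows = []
        for row in records:
            row = tuple(row)
            if len(row) == 4:  # labelled rows, e.g. (block, n_snp, n_indel, len)
                row = row[1:]
            a, b, c = row
            rows.append((int(a), int(b), int(c)))
    n_snp = sum(r[0] for r in rows)
    n_ind = sum(r[1] for r in rows)
    if denominator_mode == "aligned":
        denom = sum(r[2] for r in rows)
    elif denominator_mode == "genome_size":
        if not genome_size:
            raise ValueError("genome_size required for denominator_mode='genome_size'")
        denom = genome_size
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom == 0:
        raise ValueError("zero denominator")
    return HetEstimate(n_snp, n_ind, denom, 100.0 * (n_snp + n_ind) / denom)


# ---------------------------------------------------------------------------
# dotplots


def dotplot_data(records, min_len: int = 0) -> pd.DataFrame:
    """Plot-ready alignment segments with identity = matches / block length."""
    if isinstance(records, (str, Path)):
        records = read_paf(records)
    rows = [
        {
            "qname": r.qname, "tname": r.tname, "qstart": r.qstart, "qend": r.qend,
            "tstart": r.tstart, "tend": r.tend, "strand": r.strand,
            "identity": r.identity,
        }
        for r in records
        if r.block_len >= min_len
    ]
    return pd.DataFrame(rows, columns=["qname", "tname", "qstart", "qend",
                                       "tstart", "tend", "strand", "identity"])
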