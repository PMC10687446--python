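"""Trio binning: parent-specific k-mer ("hap-mer") extraction and long-read partitioning.

The method: count canonical k-mers (default k=21) in each parent's short
reads, keep as hap-mers the k-mers well supported in one parent (count >=
``min_count``, the sequencing-error noise floor) and effectively absent
(count < ``min_count``) in the other, then score each offspring long read
by how many of its canonical k-mers hit each hap-mer set and bin it to
the higher-scoring parent.  Reads with tied scores — including reads with
no hap-mer hits at all, which at low heterozygosity are mostly sequence
shared by both haplotypes — go to the ``unknown`` bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from . import _kmers
from ._kmers import (
    canonical_codes,
    check_k,
    count_sorted,
    decode,
    encode,
    encode_kmer,
    merge_counts,
)
from .io import SequenceRecord, read_seqs, sniff_format, write_seqs

logger = logging.getLogger(__name__)

_CHUNK_BASES = 24_000_000  # bases aggregated per numpy counting pass


@dataclass
class KmerSet:
    """Canonical k-mer -> count map for one parent, packed as sorted code arrays."""

    parent_id: str
    k: int
    codes: np.ndarray  # sorted uint64 canonical codes
    counts: np.ndarray  # int64, aligned with codes; all >= 1

    def __len__(self) -> int:
        return len(self.codes)

    def get(self, kmer: str) -> int:
        code = encode_kmer(_kmers.canonical_kmer(kmer))
        idx = np.searchsorted(self.codes, np.uint64(code))
        if idx < len(self.codes) and self.codes[idx] == np.uint64(code):
            return int(self.counts[idx])
        return 0

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def to_dict(self) -> dict[str, int]:
        return {decode(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}

    @classmethod
    def from_dict(cls, d: Mapping[str, int], k: int, parent_id: str = "") -> "KmerSet":
        codes = np.array(
            sorted(encode_kmer(_kmers.canonical_kmer(m)) for m in d), dtype=np.uint64
        )
        counts = np.array(
            [d[m] for m in sorted(d, key=lambda m: encode_kmer(_kmers.canonical_kmer(m)))],
            dtype=np.int64,
        )
        return cls(parent_id, k, codes, counts)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, codes=self.codes, counts=self.counts,
                 k=np.int64(self.k), parent_id=np.str_(self.parent_id))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "KmerSet":
        z = np.load(path, allow_pickle=False)
        return cls(str(z["parent_id"]), int(z["k"]), z["codes"], z["counts"])


@dataclass
class HapmerSets:
    """The two parent-specific canonical k-mer sets used to bin reads."""

    k: int
    specific_a: np.ndarray  # sorted uint64
    specific_b: np.ndarray
    min_count: int
    max_count: int | None = None
    parent_a: str = "A"
    parent_b: str = "B"

    @property
    def n_a(self) -> int:
        return len(self.specific_a)

    @property
    def n_b(self) -> int:
        return len(self.specific_b)

    def to_sets(self) -> tuple[set[str], set[str]]:
        return (
            {decode(int(c), self.k) for c in self.specific_a},
            {decode(int(c), self.k) for c in self.specific_b},
        )

    def swapped(self) -> "HapmerSets":
        return HapmerSets(self.k, self.specific_b, self.specific_a,
                          self.min_count, self.max_count, self.parent_b, self.parent_a)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(
            path, specific_a=self.specific_a, specific_b=self.specific_b,
            k=np.int64(self.k), min_count=np.int64(self.min_count),
            max_count=np.int64(-1 if self.max_count is None else self.max_count),
            parent_a=np.str_(self.parent_a), parent_b=np.str_(self.parent_b),
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "HapmerSets":
        z = np.load(path, allow_pickle=False)
        mc = int(z["max_count"])
        return cls(int(z["k"]), z["specific_a"], z["specific_b"], int(z["min_count"]),
                   None if mc < 0 else mc, str(z["parent_a"]), str(z["parent_b"]))


@dataclass
class ReadAssignment:
    read_id: str
    length: int
    score_a: int
    score_b: int
    bin: str  # 'A', 'B' or 'unknown'


@dataclass
class BinningSummary:
    n_total: int
    n_a: int
    n_b: int
    n_unknown: int

    @property
    def frac_a(self) -> float:
        return 100.0 * self.n_a / self.n_total if self.n_total else 0.0

    @property
    def frac_b(self) -> float:
        return 100.0 * self.n_b / self.n_total if self.n_total else 0.0

    @property
    def frac_unknown(self) -> float:
        return 100.0 * self.n_unknown / self.n_total if self.n_total else 0.0

    def report(self, parent_a: str = "A", parent_b: str = "B") -> str:
        return (
            f"binned {self.n_total:,} reads: "
            f"{self.n_a:,} ({self.frac_a:.1f}%) to {parent_a}, "
            f"{self.n_b:,} ({self.frac_b:.1f}%) to {parent_b}, "
            f"{self.n_unknown:,} ({self.frac_unknown:.1f}%) unknown"
        )


def _iter_sequences(reads) -> Iterator[str]:
    """Yield raw sequences.  ``reads`` may be a single path (str or Path),
    or an iterable whose elements are Path objects (files), SequenceRecords,
    or plain strings (raw sequences)."""
    if isinstance(reads, (str, Path)):
        for rec in read_seqs(reads):
            yield rec.sequence
        return
    for r in reads:
        if isinstance(r, SequenceRecord):
            yield r.sequence
        elif isinstance(r, Path):
            yield from _iter_sequences(r)
        else:
            yield r


def count_kmers(
    reads, k: int = 21, min_count_keep: int = 1, parent_id: str = ""
) -> KmerSet:
    """Count canonical k-mers over a read stream in one pass.

    ``reads`` may be one path, a list of paths, or an iterable of
    sequences/records.  Keys seen fewer than ``min_count_keep`` times are
    dropped from the result.  Sequences within a chunk are joined on 'N'
    so no window spans a read boundary.
    """
    check_k(k)
    streams = _iter_sequences(reads)

    counter = _kmers.new_counter() if _kmers.new_counter is not None else None
    codes = np.empty(0, dtype=np.uint64)
    counts = np.empty(0, dtype=np.int64)
    buf: list[str] = []
    buf_bases = 0
    n_reads = 0

    def flush():
        nonlocal codes, counts, buf, buf_bases
        if not buf:
            return
        chunk = canonical_codes(encode("N".join(buf)), k)
        if counter is not None:
            _kmers._count_into(counter, chunk)
        else:
            u, c = count_sorted(chunk)
            codes, counts = merge_counts(codes, counts, u, c)
        buf = []
        buf_bases = 0

    for seq in streams:
        n_reads += 1
        buf.append(seq)
        buf_bases += len(seq)
        if buf_bases >= _CHUNK_BASES:
            flush()
    flush()

    if counter is not None:
        codes, counts = _kmers._dump_counter(counter)
        order = np.argsort(codes)
        codes, counts = codes[order], counts[order]

    if n_reads == 0:
        logger.warning("count_kmers(%s): empty input, returning empty k-mer set", parent_id)
    if min_count_keep > 1 and len(codes):
        keep = counts >= min_count_keep
        codes, counts = codes[keep], counts[keep]
    return KmerSet(parent_id, k, codes, counts)


def extract_hapmers(
    kset_a: KmerSet, kset_b: KmerSet, min_count: int = 5, max_count: int | None = None
) -> HapmerSets:
    """Parent-specific k-mers: supported in one parent, below the noise floor in the other."""
    if kset_a.k != kset_b.k:
        raise ValueError(f"k mismatch: {kset_a.k} vs {kset_b.k}")

    def specific(own: KmerSet, other: KmerSet) -> np.ndarray:
        mask = own.counts >= min_count
        if max_count is not None:
            mask &= own.counts <= max_count
        other_counts = _kmers.lookup_counts(other.codes, other.counts, own.codes)
        mask &= other_counts < min_count
        return own.codes[mask]

    return HapmerSets(
        k=kset_a.k,
        specific_a=specific(kset_a, kset_b),
        specific_b=specific(kset_b, kset_a),
        min_count=min_count,
        max_count=max_count,
        parent_a=kset_a.parent_id or "A",
        parent_b=kset_b.parent_id or "B",
    )


def score_read(sequence: str, hapmers: HapmerSets) -> tuple[int, int]:
    """Occurrences of each parent's hap-mers among the read's canonical k-mers."""
    if len(sequence) < hapmers.k:
        return 0, 0
    codes = canonical_codes(encode(sequence), hapmers.k)
    sa = _kmers.count_hits(hapmers.specific_a, codes)
    sb = _kmers.count_hits(hapmers.specific_b, codes)
    return sa, sb


def _decide(score_a: int, score_b: int, hapmers: HapmerSets, normalize: bool) -> str:
    if normalize:
        na = score_a / hapmers.n_a if hapmers.n_a else 0.0
        nb = score_b / hapmers.n_b if hapmers.n_b else 0.0
    else:
        na, nb = score_a, score_b
    if na > nb:
        return "A"
    if nb > na:
        return "B"
    return "unknown"


def bin_reads(
    long_reads, hapmers: HapmerSets, normalize: bool = False
) -> tuple[list[ReadAssignment], BinningSummary]:
    """Assign each long read to parent A, parent B or unknown.

    Decision rule: argmax of hap-mer hit counts; any tie (including 0-0)
    is unknown.  ``normalize=True`` divides scores by the hap-mer set
    sizes first, correcting asymmetric set sizes.
    """
    assignments: list[ReadAssignment] = []
    if isinstance(long_reads, (str, Path)):
        long_reads = read_seqs(long_reads)
    for rec in long_reads:
        if isinstance(rec, SequenceRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        sa, sb = score_read(seq, hapmers)
        assignments.append(ReadAssignment(rid, len(seq), sa, sb, _decide(sa, sb, hapmers, normalize)))
    return assignments, summarize_binning(assignments)


def summarize_binning(assignments: Sequence[ReadAssignment]) -> BinningSummary:
    if not assignments:
        raise ValueError("no assignments to summarize")
    n_a = sum(1 for a in assignments if a.bin == "A")
    n_b = sum(1 for a in assignments if a.bin == "B")
    n_u = sum(1 for a in assignments if a.bin == "unknown")
    return BinningSummary(len(assignments), n_a, n_b, n_u)


def write_bins(
    assignments: Sequence[ReadAssignment], long_reads, out_prefix: str | Path,
    fmt: str | None = None,
) -> dict[str, Path]:
    """Write each read to exactly one of three bin files (A / B / unknown).

    Output format matches the input record type unless ``fmt`` overrides.
    Downstream per-parent assembly conventionally uses a parent bin plus
    the unknown bin together.
    """
    out_prefix = Path(out_prefix)
    by_id = {a.read_id: a.bin for a in assignments}
    if isinstance(long_reads, (str, Path)):
        if fmt is None:
            fmt = sniff_format(long_reads)
        long_reads = read_seqs(long_reads)
    elif fmt is None:
        fmt = "fasta"
    ext = ".fasta" if fmt == "fasta" else ".fastq"
    paths = {b: out_prefix.parent / f"{out_prefix.name}.haplotype-{b}{ext}"
             for b in ("A", "B", "unknown")}
    buckets: dict[str, list[SequenceRecord]] = {"A": [], "B": [], "unknown": []}
    seen: set[str] = set()
    for rec in long_reads:
        seen.add(rec.id)
        b = by_id.get(rec.id)
        if b is not None:
            buckets[b].append(rec)
    missing = set(by_id) - seen
    if missing:
        raise ValueError(f"assigned read(s) missing from input stream: {sorted(missing)[:5]}")
    for b, p in paths.items():
        write_seqs(p, buckets[b], fmt)
    return paths


def write_assignments_tsv(assignments: Sequence[ReadAssignment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tlength\tscore_a\tscore_b\tbin\n")
        for a in assignments:
            fh.write(f"{a.read_id}\t{a.length}\t{a.score_a}\t{a.score_b}\t{a.bin}\n")
    return path


def read_assignments_tsv(path: str | Path) -> list[ReadAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: expected assignment TSV header")
        for line in fh:
            rid, length, sa, sb, b = line.rstrip("\n").split("\t")
            out.append(ReadAssignment(rid, int(length), int(sa), int(sb), b))
    return out


def write_summary_tsv(summary: BinningSummary, path: str | Path,
                      parent_a: str = "A", parent_b: str = "B") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("bin\tn_reads\tfraction_pct\n")
        fh.write(f"{parent_a}\t{summary.n_a}\t{summary.frac_a:.1f}\n")
        fh.write(f"{parent_b}\t{summary.n_b}\t{summary.frac_b:.1f}\n")
        fh.write(f"unknown\t{summary.n_unknown}\t{summary.frac_unknown:.1f}\n")
    return path
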