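"""Shared readers and writers: FASTA/FASTQ (plain or gzip), PAF, BED, TSV.

Coordinate conventions: everything in memory and in BED/PAF/TSV output is
0-based half-open; AGP (see :mod:`triobin.agp`) is 1-based inclusive per
the standard.  FASTA/FASTQ parsing is delegated to Biopython's low-level
iterators; gzip is auto-detected from magic bytes on read and chosen by a
``.gz`` suffix on write.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class SequenceRecord:
    """One FASTA/FASTQ record; ``qualities`` is None for FASTA."""

    id: str
    description: str = ""
    sequence: str = ""
    qualities: str | None = None

    @property
    def is_fastq(self) -> bool:
        return self.qualities is not None

    def __len__(self) -> int:
        return len(self.sequence)


def open_text(path: str | Path, mode: str = "rt"):
    """Open plain or gzipped text; gzip detected by magic bytes for reads."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: str | Path) -> str:
    """'fasta' or 'fastq' from the first non-blank character."""
    with open_text(path) as fh:
        for line in fh:
            if line.strip():
                c = line[0]
                if c == ">":
                    return "fasta"
                if c == "@":
                    return "fastq"
                raise ValueError(f"{path}: not FASTA or FASTQ (first record starts {c!r})")
    raise ValueError(f"{path}: empty file")


def _split_title(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        raise ValueError("record with empty title")
    return parts[0], (parts[1] if len(parts) > 1 else "")


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    with open_text(path) as fh:
        for i, (title, seq) in enumerate(SimpleFastaParser(fh)):
            rid, desc = _split_title(title)
            if not seq:
                raise ValueError(f"{path}: record {i} ({rid}) has empty sequence")
            yield SequenceRecord(rid, desc, seq.replace("\r", ""))


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    with open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise ValueError(f"{path}: malformed FASTQ at record {i}: {e}") from e
            rid, desc = _split_title(title)
            yield SequenceRecord(rid, desc, seq, qual)
            i += 1


def read_seqs(path: str | Path) -> Iterator[SequenceRecord]:
    """Auto-detecting FASTA/FASTQ reader."""
    fmt = sniff_format(path)
    return read_fasta(path) if fmt == "fasta" else read_fastq(path)


def _as_records(seqs) -> Iterator[SequenceRecord]:
    if isinstance(seqs, Mapping):
        for name, s in seqs.items():
            yield SequenceRecord(name, "", s)
    else:
        for r in seqs:
            yield r


def write_fasta(path: str | Path, seqs, width: int = 80) -> Path:
    """Write records (or a name->sequence mapping) as FASTA; ``.gz`` gzips."""
    path = Path(path)
    with open_text(path, "wt") as fh:
        for rec in _as_records(seqs):
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            s = rec.sequence
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
    return path


def write_fastq(path: str | Path, seqs) -> Path:
    path = Path(path)
    with open_text(path, "wt") as fh:
        for rec in _as_records(seqs):
            qual = rec.qualities if rec.qualities is not None else "I" * len(rec.sequence)
            header = f"@{rec.id} {rec.description}".rstrip()
            fh.write(f"{header}\n{rec.sequence}\n+\n{qual}\n")
    return path


def write_seqs(path: str | Path, seqs, fmt: str) -> Path:
    if fmt == "fasta":
        return write_fasta(path, seqs)
    if fmt == "fastq":
        return write_fastq(path, seqs)
    raise ValueError(f"unknown sequence format {fmt!r}")


def contig_lengths(path_or_seqs) -> dict[str, int]:
    """name -> length from a FASTA path or name->sequence mapping."""
    if isinstance(path_or_seqs, Mapping):
        return {k: len(v) for k, v in path_or_seqs.items()}
    return {r.id: len(r.sequence) for r in read_fasta(path_or_seqs)}


# ---------------------------------------------------------------------------
# PAF


@dataclass
class PafRecord:
    """One PAF alignment line (12 mandatory columns, tags kept verbatim)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_matches: int
    block_len: int
    mapq: int
    tags: list[str] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.n_matches / self.block_len if self.block_len else 0.0

    def to_line(self) -> str:
        cols = [
            self.qname, str(self.qlen), str(self.qstart), str(self.qend), self.strand,
            self.tname, str(self.tlen), str(self.tstart), str(self.tend),
            str(self.n_matches), str(self.block_len), str(self.mapq),
        ]
        return "\t".join(cols + list(self.tags))


def parse_paf_line(line: str, lineno: int = 0) -> PafRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
    try:
        return PafRecord(
            qname=cols[0], qlen=int(cols[1]), qstart=int(cols[2]), qend=int(cols[3]),
            strand=cols[4], tname=cols[5], tlen=int(cols[6]), tstart=int(cols[7]),
            tend=int(cols[8]), n_matches=int(cols[9]), block_len=int(cols[10]),
            mapq=int(cols[11]), tags=cols[12:],
        )
    except ValueError as e:
        raise ValueError(f"PAF line {lineno}: {e}") from e


def read_paf(path: str | Path) -> Iterator[PafRecord]:
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                yield parse_paf_line(line, lineno)


def write_paf(path: str | Path, records: Iterable[PafRecord]) -> Path:
    path = Path(path)
    with open_text(path, "wt") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
    return path


# ---------------------------------------------------------------------------
# BED


def write_bed(path: str | Path, intervals: Iterable[tuple]) -> Path:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
    return path


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            row = [cols[0], int(cols[1]), int(cols[2])] + cols[3:]
            out.append(tuple(row))
    return out
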