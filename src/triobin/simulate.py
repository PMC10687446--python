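"""Synthetic trio generator with full ground truth.

Emulates the study design this toolkit targets: two fully homozygous
(double-haploid) parents sequenced with short reads, and their F1 hybrid
sequenced with long, low-error reads.  Each parent contributes exactly
one haplotype, so the F1's two haplotypes are the two parental genomes.

The model: an i.i.d. ancestor sequence with GC bias and telomere arrays
appended to both chromosome ends; the two haplotypes are derived by
planting SNPs and short indels, each variant applied to exactly one
haplotype, so ``snp_rate + indel_rate`` is the target per-bp rate of
haplotype-differing positions (heterozygosity).  Defaults correspond to
a 5 Mb genome at 0.1168% heterozygosity with 45x parental 150 bp
paired-end coverage and 58x ~15 kb F1 long reads.

Ground truth (variant list, read origins, switch blocks, shred map) is
recorded so binning, switch detection, scaffolding and QC can all be
validated without external data or an aligner: truth PAF files carry
exact placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from ._kmers import revcomp
from .io import PafRecord, SequenceRecord

_DEC_TABLE = np.frombuffer(b"ACGT", dtype=np.uint8)

# rng stream salts, one per operation, so ops are independently reproducible
_SALT_ANCESTOR = 11
_SALT_VARIANTS = 12
_SALT_SHORT = 13
_SALT_LONG = 14
_SALT_SHRED = 15


@dataclass
class SimConfig:
    """Study conditions for one synthetic trio (defaults: desk-scale analogue
    of a 3.5 Gb pepper trio — 5 Mb genome, same rates and coverages)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 2_500_000
    gc: float = 0.38  # pepper-like AT-rich composition
    snp_rate: float = 1.0e-3
    indel_rate: float = 1.68e-4  # snp+indel = 0.1168% heterozygous positions
    indel_size_mean: float = 3.0
    telomere_unit: str = "TTAGGG"
    telomere_copies: int = 150
    short_read_len: int = 150
    short_insert_mean: int = 400
    short_coverage: float = 45.0
    short_error: float = 1.0e-3
    long_len_mean: float = 15_000.0
    long_len_sigma: float = 0.25
    long_coverage: float = 58.0
    long_error: float = 1.0e-3

    def __post_init__(self):
        for name in ("snp_rate", "indel_rate", "short_error", "long_error"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0,1): got {v}")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def paper_scaled(seed: int = 0, **overrides) -> SimConfig:
    """The 'paper-scaled' preset: a 5 Mb trio at the published rates/coverages."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class Variant:
    chrom: str
    pos: int  # ancestor coordinate, 0-based
    ref: str  # '-' for insertion
    alt: str  # '-' for deletion
    vtype: str  # 'snp' | 'ins' | 'del'
    haplotype: str  # 'A' | 'B' (the haplotype carrying the alternative)


@dataclass
class ReadOrigin:
    read_id: str
    haplotype: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class ShredFragment:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    kept: bool


@dataclass
class SimTruth:
    """Ground truth accumulated by the simulator operations."""

    variants: list[Variant] = field(default_factory=list)
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)
    switch_blocks: list[tuple] = field(default_factory=list)  # (contig, start, end, hap)
    shred_map: list[ShredFragment] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def alignment_summary(self) -> list[tuple[str, int, int, int]]:
        """Per-chromosome (chrom, n_snp, n_indel_positions, aligned_len) rows,
        as an idealised whole-chromosome unique alignment between haplotypes."""
        rows = []
        for chrom, length in self.chrom_lengths.items():
            n_snp = sum(1 for v in self.variants if v.chrom == chrom and v.vtype == "snp")
            n_ind = sum(1 for v in self.variants if v.chrom == chrom and v.vtype != "snp")
            rows.append((chrom, n_snp, n_ind, length))
        return rows

    def het_rate(self) -> float:
        """Realized heterozygous-position rate (fraction, not percent)."""
        total = sum(self.chrom_lengths.values())
        return len(self.variants) / total if total else 0.0


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), salt])


def _random_core(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _DEC_TABLE[codes].tobytes().decode("ascii")


def simulate_parents(config: SimConfig) -> tuple[dict[str, str], dict[str, str], SimTruth]:
    """Generate haplotype A and B genomes plus truth.

    Telomere arrays (reverse-complement unit at the left end, forward at
    the right) are identical between haplotypes; variants are planted
    only in the single-copy core.  Overlapping indels are resolved by
    left-to-right application (later overlapping variants dropped from
    both sequence and truth).
    """
    rng_a = _rng(config, _SALT_ANCESTOR)
    rng_v = _rng(config, _SALT_VARIANTS)
    tel = revcomp(config.telomere_unit) * config.telomere_copies
    tel_r = config.telomere_unit * config.telomere_copies
    tel_len = len(tel)
    core_len = config.chrom_len - 2 * tel_len
    if core_len <= 0:
        raise ValueError("chrom_len too small for telomere arrays")

    hap_a: dict[str, str] = {}
    hap_b: dict[str, str] = {}
    truth = SimTruth()
    bases = "ACGT"
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        core = _random_core(rng_a, core_len, config.gc)
        ancestor = tel + _to_str(core) + tel_r
        # sample variant positions in the core, away from the very ends
        lo, hi = tel_len, config.chrom_len - tel_len - 200
        n_snp = rng_v.binomial(core_len, config.snp_rate)
        n_ind = rng_v.binomial(core_len, config.indel_rate)
        pos = rng_v.choice(hi - lo, size=n_snp + n_ind, replace=False) + lo
        pos.sort()
        is_snp = np.zeros(len(pos), dtype=bool)
        is_snp[rng_v.choice(len(pos), size=n_snp, replace=False)] = True
        variants: list[Variant] = []
        for p, snp in zip(pos, is_snp):
            p = int(p)
            hap = "A" if rng_v.integers(2) == 0 else "B"
            if snp:
                ref = ancestor[p]
                alt = bases[(bases.index(ref) + int(rng_v.integers(1, 4))) % 4]
                variants.append(Variant(chrom, p, ref, alt, "snp", hap))
            else:
                size = int(rng_v.geometric(1.0 / config.indel_size_mean))
                size = min(size, 50)
                if rng_v.integers(2) == 0:
                    ins = _to_str(rng_v.integers(0, 4, size=size).astype(np.uint8))
                    variants.append(Variant(chrom, p, "-", ins, "ins", hap))
                else:
                    variants.append(Variant(chrom, p, ancestor[p : p + size], "-", "del", hap))
        applied_a, seq_a = _apply_variants(ancestor, [v for v in variants if v.haplotype == "A"])
        applied_b, seq_b = _apply_variants(ancestor, [v for v in variants if v.haplotype == "B"])
        hap_a[chrom] = seq_a
        hap_b[chrom] = seq_b
        kept = set(id(v) for v in applied_a) | set(id(v) for v in applied_b)
        truth.variants.extend(v for v in variants if id(v) in kept)
        truth.chrom_lengths[chrom] = len(ancestor)
    return hap_a, hap_b, truth


def _apply_variants(ancestor: str, variants: Sequence[Variant]) -> tuple[list[Variant], str]:
    pieces: list[str] = []
    cur = 0
    applied: list[Variant] = []
    for v in variants:
        if v.pos < cur:
            continue  # overlapped by a previous deletion: left-to-right rule
        if v.vtype == "snp":
            pieces.append(ancestor[cur : v.pos])
            pieces.append(v.alt)
            cur = v.pos + 1
        elif v.vtype == "ins":
            pieces.append(ancestor[cur : v.pos + 1])
            pieces.append(v.alt)
            cur = v.pos + 1
        else:  # del
            pieces.append(ancestor[cur : v.pos])
            cur = v.pos + len(v.ref)
        applied.append(v)
    pieces.append(ancestor[cur:])
    return applied, "".join(pieces)


# ---------------------------------------------------------------------------
# reads


def _choose_chroms(rng, chrom_names, lengths, n):
    p = lengths / lengths.sum()
    return rng.choice(len(chrom_names), size=n, p=p)


def simulate_short_reads(
    haplotype: Mapping[str, str], config: SimConfig, parent_id: str = "P",
    seed_salt: int = _SALT_SHORT, chunk: int = 200_000,
) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    """Paired 150 bp reads, FR (inward) orientation, uniform starts.

    Insert sizes ~ Normal(mean, 0.1*mean); substitution errors at
    ``short_error``.  Pair count = coverage * genome / (2 * read_len).
    """
    rng = _rng(config, seed_salt)
    rl = config.short_read_len
    names = list(haplotype.keys())
    enc = {c: _encode_fast(haplotype[c]) for c in names}
    lengths = np.array([len(haplotype[c]) for c in names], dtype=np.float64)
    usable = [c for c in names if len(haplotype[c]) >= config.short_insert_mean * 2]
    if len(usable) < len(names):
        import logging

        logging.getLogger(__name__).warning(
            "short-read simulation: %d chromosome(s) shorter than the insert skipped",
            len(names) - len(usable),
        )
        names = usable
        enc = {c: enc[c] for c in names}
        lengths = np.array([len(haplotype[c]) for c in names], dtype=np.float64)
    total = lengths.sum()
    n_pairs = int(round(config.short_coverage * total / (2 * rl)))
    emitted = 0
    pair_i = 0
    while emitted < n_pairs:
        m = min(chunk, n_pairs - emitted)
        ch_idx = _choose_chroms(rng, names, lengths, m)
        ins = rng.normal(config.short_insert_mean, 0.1 * config.short_insert_mean, size=m)
        ins = np.clip(np.rint(ins), rl, None).astype(np.int64)
        for gi in range(len(names)):
            sel = np.where(ch_idx == gi)[0]
            if len(sel) == 0:
                continue
            chrom = names[gi]
            arr = enc[chrom]
            L = len(arr)
            ins_g = np.minimum(ins[sel], L)
            starts = np.floor(rng.random(len(sel)) * (L - ins_g + 1)).astype(np.int64)
            r1 = arr[starts[:, None] + np.arange(rl)]
            ends = starts + ins_g
            r2 = arr[(ends - rl)[:, None] + np.arange(rl)]
            r2 = 3 - r2[:, ::-1]  # reverse complement: inward-facing mate
            if config.short_error > 0:
                for block in (r1, r2):
                    errs = rng.random(block.shape) < config.short_error
                    block[errs] = (block[errs] + rng.integers(1, 4, size=int(errs.sum()))) % 4
            for j in range(len(sel)):
                rid = f"{parent_id}_pair{pair_i + int(sel[j]):09d}"
                yield (
                    SequenceRecord(rid + "/1", "", _to_str(r1[j]), "I" * rl),
                    SequenceRecord(rid + "/2", "", _to_str(r2[j]), "I" * rl),
                )
        emitted += m
        pair_i += m


def _encode_fast(seq: str) -> np.ndarray:
    from ._kmers import encode

    e = encode(seq)
    return np.where(e > 3, 0, e).astype(np.uint8)


def short_read_sequences(haplotype, config, parent_id="P", seed_salt=_SALT_SHORT) -> Iterator[str]:
    """Flat stream of the paired-read sequences (for k-mer counting)."""
    for r1, r2 in simulate_short_reads(haplotype, config, parent_id, seed_salt):
        yield r1.sequence
        yield r2.sequence


def simulate_long_reads(
    hap_a: Mapping[str, str], hap_b: Mapping[str, str], config: SimConfig,
    truth: SimTruth | None = None, seed_salt: int = _SALT_LONG,
) -> tuple[list[SequenceRecord], SimTruth, list[PafRecord]]:
    """F1 long reads drawn 50/50 from the two haplotypes.

    Lengths are lognormal with mean ``long_len_mean``; each read is taken
    from either strand; substitution errors at ``long_error``.  Read
    descriptions and the returned truth PAF encode the exact origin
    (coordinates of the error-free template on its source haplotype).
    """
    rng = _rng(config, seed_salt)
    if truth is None:
        truth = SimTruth()
    haps = {"A": hap_a, "B": hap_b}
    names = list(hap_a.keys())
    lengths_a = np.array([len(hap_a[c]) for c in names], dtype=np.float64)
    total = lengths_a.sum()
    n = int(round(config.long_coverage * total / config.long_len_mean))
    sigma = config.long_len_sigma
    mu = np.log(config.long_len_mean) - sigma**2 / 2
    read_lens = np.clip(rng.lognormal(mu, sigma, size=n), 1000, None).astype(np.int64)
    hap_pick = rng.integers(2, size=n)
    strand_pick = rng.integers(2, size=n)
    ch_idx = _choose_chroms(rng, names, lengths_a, n)
    records: list[SequenceRecord] = []
    paf: list[PafRecord] = []
    for i in range(n):
        hap = "A" if hap_pick[i] == 0 else "B"
        chrom = names[ch_idx[i]]
        source = haps[hap][chrom]
        L = len(source)
        l = int(min(read_lens[i], L))
        start = int(rng.integers(0, L - l + 1))
        end = start + l
        seq = source[start:end]
        strand = "+" if strand_pick[i] == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)
        if config.long_error > 0:
            seq = _mutate(seq, config.long_error, rng)
        rid = f"lr{i:07d}"
        desc = f"hap={hap} chrom={chrom} start={start} end={end} strand={strand}"
        records.append(SequenceRecord(rid, desc, seq))
        truth.read_origins[rid] = ReadOrigin(rid, hap, chrom, start, end, strand)
        paf.append(PafRecord(rid, l, 0, l, strand, chrom, L, start, end, l, l, 60))
    return records, truth, paf


def _mutate(seq: str, rate: float, rng) -> str:
    arr = _encode_fast(seq)
    errs = rng.random(len(arr)) < rate
    if errs.any():
        arr[errs] = (arr[errs] + rng.integers(1, 4, size=int(errs.sum()))) % 4
    return _to_str(arr)


def truth_bins(truth: SimTruth) -> dict[str, str]:
    """read_id -> haplotype label, usable as a perfect bin assignment."""
    return {rid: o.haplotype for rid, o in truth.read_origins.items()}


# ---------------------------------------------------------------------------
# assemblies


def simulate_mosaic_assembly(
    hap_a: Mapping[str, str], hap_b: Mapping[str, str],
    switch_points: Mapping[str, Sequence[int]],
) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """A haplotype-switching assembly: alternating blocks copied from A and B
    at homologous coordinates, starting with A.  Returns the mosaic and the
    truth switch blocks (mosaic coordinates)."""
    mosaic: dict[str, str] = {}
    blocks: list[tuple[str, int, int, str]] = []
    for chrom in hap_a:
        a, b = hap_a[chrom], hap_b[chrom]
        limit = min(len(a), len(b))
        points = sorted(p for p in switch_points.get(chrom, []) if 0 < p < limit)
        bounds = [0] + points + [limit]
        pieces = []
        pos = 0
        for i in range(len(bounds) - 1):
            hap = "A" if i % 2 == 0 else "B"
            src = a if hap == "A" else b
            piece = src[bounds[i] : bounds[i + 1]]
            pieces.append(piece)
            blocks.append((chrom, pos, pos + len(piece), hap))
            pos += len(piece)
        mosaic[chrom] = "".join(pieces)
    return mosaic, blocks


def phased_blocks(haplotype: Mapping[str, str], hap: str) -> list[tuple[str, int, int, str]]:
    """Whole-chromosome truth blocks for a fully phased assembly."""
    return [(c, 0, len(s), hap) for c, s in haplotype.items()]


def placements_on_assembly(
    truth: SimTruth, blocks: Sequence[tuple[str, int, int, str]],
    contig_lengths: Mapping[str, int],
) -> list[PafRecord]:
    """Truth placements of the simulated long reads onto an assembly.

    A read is placed (at homologous coordinates) only where the assembly
    block at the read's midpoint carries the read's own haplotype — an
    idealised haplotype-exclusive mapping; see the methods note.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, hap in blocks:
        by_chrom.setdefault(chrom, []).append((s, e, hap))
    paf: list[PafRecord] = []
    for rid, o in truth.read_origins.items():
        if o.chrom not in by_chrom or o.chrom not in contig_lengths:
            continue
        mid = (o.start + o.end) // 2
        for s, e, hap in by_chrom[o.chrom]:
            if s <= mid < e and hap == o.haplotype:
                tlen = contig_lengths[o.chrom]
                start = min(o.start, tlen)
                end = min(o.end, tlen)
                if end > start:
                    l = o.end - o.start
                    paf.append(PafRecord(rid, l, 0, l, o.strand, o.chrom, tlen,
                                         start, end, l, l, 60))
                break
    return paf


def shred(
    seqs: Mapping[str, str], frag_mean: float = 200_000.0, frag_sd: float = 60_000.0,
    dropout: float = 0.0, orient_prob: float = 0.0, min_frag: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], list[ShredFragment]]:
    """Cut a genome into sequential fragments (scaffolder fixture).

    Fragment sizes ~ Normal(frag_mean, frag_sd) clipped at ``min_frag``;
    each fragment is dropped with probability ``dropout`` and
    reverse-complemented with probability ``orient_prob`` (truth strand
    recorded).  Names encode truth coordinates.
    """
    rng = np.random.default_rng([seed % (2**31), _SALT_SHRED])
    frags: dict[str, str] = {}
    fmap: list[ShredFragment] = []
    i = 0
    for chrom, seq in seqs.items():
        pos = 0
        L = len(seq)
        while pos < L:
            size = max(min_frag, int(rng.normal(frag_mean, frag_sd)))
            end = min(pos + size, L)
            if L - end < min_frag:  # absorb a tiny remainder into the last fragment
                end = L
            name = f"frag{i:05d}"
            strand = "-" if rng.random() < orient_prob else "+"
            kept = rng.random() >= dropout
            fmap.append(ShredFragment(name, chrom, pos, end, strand, kept))
            if kept:
                piece = seq[pos:end]
                frags[name] = revcomp(piece) if strand == "-" else piece
            pos = end
            i += 1
    return frags, fmap


def shred_truth_paf(fmap: Sequence[ShredFragment], chrom_lengths: Mapping[str, int]) -> list[PafRecord]:
    """Exact fragment-to-genome alignments for kept fragments."""
    out = []
    for f in fmap:
        if not f.kept:
            continue
        l = f.end - f.start
        out.append(PafRecord(f.name, l, 0, l, f.strand, f.chrom,
                             chrom_lengths[f.chrom], f.start, f.end, l, l, 60))
    return out


def donor_truth_paf(plan, fmap: Sequence[ShredFragment], chrom_lengths: Mapping[str, int]) -> list[PafRecord]:
    """Truth alignments of the original genome (donor) onto a scaffold built
    from shredded fragments — the gap-patching fixture."""
    from .agp import Component

    by_name = {f.name: f for f in fmap}
    out: list[PafRecord] = []
    for sc in plan.scaffolds:
        pos = 0
        for part in sc.parts:
            if isinstance(part, Component):
                f = by_name.get(part.contig)
                if f is not None:
                    strand = "+" if part.orientation == f.strand else "-"
                    l = part.length
                    out.append(PafRecord(
                        f.chrom, chrom_lengths[f.chrom], f.start, f.end, strand,
                        sc.name, sc.length, pos, pos + l, l, l, 60))
            pos += part.length
    return out


# ---------------------------------------------------------------------------
# truth serialisation


def write_variants_tsv(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\ttype\thaplotype\n")
        for v in truth.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vtype}\t{v.haplotype}\n")
    return path


def write_origins_tsv(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tchrom\tstart\tend\tstrand\n")
        for o in truth.read_origins.values():
            fh.write(f"{o.read_id}\t{o.haplotype}\t{o.chrom}\t{o.start}\t{o.end}\t{o.strand}\n")
    return path


def write_alignment_summary_tsv(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("block\tn_snp\tn_indel_positions\taligned_len\n")
        for chrom, n_snp, n_ind, length in truth.alignment_summary():
            fh.write(f"{chrom}\t{n_snp}\t{n_ind}\t{length}\n")
    return path
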