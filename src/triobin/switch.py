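"""Haplotype-switch detection from binned-read placements.

An assembly is tiled into fixed windows (default 1 Mb).  For each window
the percent of bases covered by at least one parent-A-binned read and by
at least one parent-B-binned read is computed (breadth of coverage, the
bedtools-coverage fraction; a mean-depth mode is available).  The signed
difference ``pct_a - pct_b`` classifies each window to a parent; for a
haplotype-resolved assembly every non-tie window should favour its own
parent, and maximal runs of windows favouring the unexpected parent are
reported as switch blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PafRecord, read_paf, write_bed


@dataclass(frozen=True)
class Window:
    contig: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ReadPlacement:
    read_id: str
    bin: str  # 'A' or 'B'
    contig: str
    start: int
    end: int


@dataclass
class WindowCoverage:
    window: Window
    pct_a: float
    pct_b: float

    @property
    def diff(self) -> float:
        return self.pct_a - self.pct_b


@dataclass
class PlacementTally:
    n_placed: int = 0
    n_unlabeled_skipped: int = 0
    n_unknown_excluded: int = 0


@dataclass
class SwitchReport:
    classes: list[str]  # per window: 'A' | 'B' | 'tie'
    windows: list[Window]
    expected_parent: str | None
    concordance_pct: float | None  # None when undefined (no non-tie windows)
    switch_blocks: list[tuple[str, int, int, str]]  # (contig, start, end, observed)
    n_windows: int = 0
    n_tie: int = 0
    n_transitions: int = 0


def make_windows(contig_lengths: Mapping[str, int], width: int = 1_000_000) -> list[Window]:
    """Tile each contig with non-overlapping windows; the final window is
    truncated to the contig end."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    out = []
    for contig, length in contig_lengths.items():
        for s in range(0, length, width):
            out.append(Window(contig, s, min(s + width, length)))
    return out


def read_placements(
    alignments, assignments: Mapping[str, str], min_mapq: int = 0,
) -> tuple[list[ReadPlacement], PlacementTally]:
    """One placement per read: the PAF record with the most residue matches
    (ties broken by earliest record).  Unknown-bin reads are excluded and
    aligned reads with no bin label are skipped; both are tallied."""
    if isinstance(alignments, (str, Path)):
        alignments = read_paf(alignments)
    best: dict[str, PafRecord] = {}
    tally = PlacementTally()
    skipped_unlabeled: set[str] = set()
    excluded_unknown: set[str] = set()
    for rec in alignments:
        if rec.mapq < min_mapq:
            continue
        label = assignments.get(rec.qname)
        if label is None:
            skipped_unlabeled.add(rec.qname)
            continue
        if label not in ("A", "B"):
            excluded_unknown.add(rec.qname)
            continue
        cur = best.get(rec.qname)
        if cur is None or rec.n_matches > cur.n_matches:
            best[rec.qname] = rec
    tally.n_unlabeled_skipped = len(skipped_unlabeled)
    tally.n_unknown_excluded = len(excluded_unknown)
    tally.n_placed = len(best)
    placements = [
        ReadPlacement(r.qname, assignments[r.qname], r.tname, r.tstart, r.tend)
        for r in best.values()
    ]
    return placements, tally


def window_coverage(
    placements: Sequence[ReadPlacement], windows: Sequence[Window], mode: str = "breadth",
) -> list[WindowCoverage]:
    """Per-window coverage of each bin.

    ``breadth`` (default): percent of window bases covered by the union
    of that bin's intervals — never above 100 regardless of depth.
    ``depth``: mean per-base read depth over the window.
    """
    if mode not in ("breadth", "depth"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    span: dict[str, int] = {}
    win_by_contig: dict[str, list[Window]] = {}
    for w in windows:
        span[w.contig] = max(span.get(w.contig, 0), w.end)
        win_by_contig.setdefault(w.contig, []).append(w)
    for p in placements:
        if p.contig not in span:
            raise ValueError(f"placement on unknown contig {p.contig!r}")

    cov_arrays: dict[tuple[str, str], np.ndarray] = {}
    for p in placements:
        key = (p.contig, p.bin)
        arr = cov_arrays.get(key)
        if arr is None:
            dtype = bool if mode == "breadth" else np.int32
            arr = np.zeros(span[p.contig], dtype=dtype)
            cov_arrays[key] = arr
        s, e = max(0, p.start), min(span[p.contig], p.end)
        if mode == "breadth":
            arr[s:e] = True
        else:
            arr[s:e] += 1

    out: list[WindowCoverage] = []
    for contig, wins in win_by_contig.items():
        a = cov_arrays.get((contig, "A"))
        b = cov_arrays.get((contig, "B"))
        for w in wins:
            width = w.width
            va = float(a[w.start : w.end].sum()) if a is not None else 0.0
            vb = float(b[w.start : w.end].sum()) if b is not None else 0.0
            if mode == "breadth":
                out.append(WindowCoverage(w, 100.0 * va / width, 100.0 * vb / width))
            else:
                out.append(WindowCoverage(w, va / width, vb / width))
    return out


def classify_and_score(
    coverages: Sequence[WindowCoverage], expected_parent: str | None = None,
    min_abs_diff: float = 0.0,
) -> SwitchReport:
    """Classify windows by signed coverage difference and score concordance.

    A window is 'A' if diff > min_abs_diff, 'B' if diff < -min_abs_diff,
    else a tie.  Concordance is the percent of non-tie windows matching
    the expected parent (ties are excluded from the denominator).  Switch
    blocks are maximal runs of windows classified to the unexpected
    parent, reported at window resolution.
    """
    classes = []
    for c in coverages:
        if c.diff > min_abs_diff:
            classes.append("A")
        elif c.diff < -min_abs_diff:
            classes.append("B")
        else:
            classes.append("tie")
    windows = [c.window for c in coverages]
    n_tie = classes.count("tie")
    non_tie = [cl for cl in classes if cl != "tie"]
    n_transitions = sum(1 for x, y in zip(non_tie, non_tie[1:]) if x != y)

    concordance = None
    blocks: list[tuple[str, int, int, str]] = []
    if expected_parent is not None:
        if expected_parent not in ("A", "B"):
            raise ValueError("expected_parent must be 'A' or 'B'")
        if non_tie:
            n_match = sum(1 for cl in non_tie if cl == expected_parent)
            concordance = 100.0 * n_match / len(non_tie)
        unexpected = "B" if expected_parent == "A" else "A"
        cur: list[int] | None = None  # [start_idx, end_idx]
        for i, cl in enumerate(classes):
            same_run = (
                cur is not None
                and cl == unexpected
                and windows[i].contig == windows[cur[1]].contig
                and i == cur[1] + 1
            )
            if same_run:
                cur[1] = i
            else:
                if cur is not None:
                    blocks.append(_block(windows, cur, unexpected))
                cur = [i, i] if cl == unexpected else None
        if cur is not None:
            blocks.append(_block(windows, cur, unexpected))
    return SwitchReport(classes, windows, expected_parent, concordance, blocks,
                        n_windows=len(classes), n_tie=n_tie, n_transitions=n_transitions)


def _block(windows, idx, observed):
    return (windows[idx[0]].contig, windows[idx[0]].start, windows[idx[1]].end, observed)


def export_tracks(
    coverages: Sequence[WindowCoverage], report: SwitchReport, out_prefix: str | Path,
) -> dict[str, Path]:
    """Plot-ready per-window TSV, switch-block BED and a one-row summary TSV.
    All coordinates 0-based half-open."""
    out_prefix = Path(out_prefix)
    windows_tsv = out_prefix.parent / f"{out_prefix.name}.windows.tsv"
    df = pd.DataFrame(
        {
            "contig": [c.window.contig for c in coverages],
            "start": [c.window.start for c in coverages],
            "end": [c.window.end for c in coverages],
            "pct_a": [c.pct_a for c in coverages],
            "pct_b": [c.pct_b for c in coverages],
            "diff": [c.diff for c in coverages],
            "class": report.classes,
        }
    )
    df.to_csv(windows_tsv, sep="\t", index=False)
    bed = out_prefix.parent / f"{out_prefix.name}.switch_blocks.bed"
    write_bed(bed, [(c, s, e, f"switch_to_{obs}") for c, s, e, obs in report.switch_blocks])
    summary = out_prefix.parent / f"{out_prefix.name}.summary.tsv"
    pd.DataFrame(
        [
            {
                "expected_parent": report.expected_parent or "NA",
                "n_windows": report.n_windows,
                "n_tie": report.n_tie,
                "n_transitions": report.n_transitions,
                "concordance_pct": "NA" if report.concordance_pct is None
                else f"{report.concordance_pct:.1f}",
                "n_switch_blocks": len(report.switch_blocks),
            }
        ]
    ).to_csv(summary, sep="\t", index=False)
    return {"windows": windows_tsv, "switch_blocks": bed, "summary": summary}


def read_windows_tsv(path: str | Path) -> list[WindowCoverage]:
    df = pd.read_csv(path, sep="\t")
    return [
        WindowCoverage(Window(r.contig, int(r.start), int(r.end)), float(r.pct_a), float(r.pct_b))
        for r in df.itertuples()
    ]
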