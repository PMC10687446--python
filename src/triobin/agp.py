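"""Scaffold plans and AGP v2.1 serialisation.

A :class:`ScaffoldPlan` describes how output scaffolds are composed of
oriented contig components alternating with gap records.  AGP coordinates
are 1-based inclusive (the only place this package departs from 0-based
half-open); in-memory component coordinates are 0-based half-open into
the source contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._kmers import revcomp


@dataclass
class Component:
    """A contig (or contig slice) placed in a scaffold."""

    contig: str
    start: int  # 0-based half-open into the contig
    end: int
    orientation: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Gap:
    length: int
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "align_genus"


@dataclass
class Scaffold:
    name: str
    parts: list = field(default_factory=list)  # Component | Gap, alternating

    @property
    def length(self) -> int:
        return sum(p.length for p in self.parts)


@dataclass
class ScaffoldPlan:
    scaffolds: list[Scaffold] = field(default_factory=list)

    def sequence(self, name: str, contig_seqs) -> str:
        for sc in self.scaffolds:
            if sc.name == name:
                return _build_seq(sc, contig_seqs)
        raise KeyError(name)

    def sequences(self, contig_seqs) -> dict[str, str]:
        """Reconstruct every scaffold sequence from component contigs."""
        return {sc.name: _build_seq(sc, contig_seqs) for sc in self.scaffolds}


def _build_seq(sc: Scaffold, contig_seqs) -> str:
    pieces = []
    for p in sc.parts:
        if isinstance(p, Gap):
            pieces.append("N" * p.length)
        else:
            s = contig_seqs[p.contig][p.start : p.end]
            pieces.append(revcomp(s) if p.orientation == "-" else s)
    return "".join(pieces)


def write_agp(plan: ScaffoldPlan, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for sc in plan.scaffolds:
            pos = 0
            for partno, p in enumerate(sc.parts, start=1):
                obj_beg = pos + 1
                obj_end = pos + p.length
                if isinstance(p, Gap):
                    fh.write(
                        f"{sc.name}\t{obj_beg}\t{obj_end}\t{partno}\tU\t"
                        f"{p.length}\t{p.gap_type}\t{p.linkage}\t{p.evidence}\n"
                    )
                else:
                    fh.write(
                        f"{sc.name}\t{obj_beg}\t{obj_end}\t{partno}\tW\t"
                        f"{p.contig}\t{p.start + 1}\t{p.end}\t{p.orientation}\n"
                    )
                pos = obj_end
    return path


def read_agp(path: str | Path) -> ScaffoldPlan:
    plan = ScaffoldPlan()
    current: Scaffold | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"AGP line {lineno}: expected 9 columns")
            name, obj_beg, obj_end, _partno, ctype = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4]
            if current is None or current.name != name:
                current = Scaffold(name)
                plan.scaffolds.append(current)
            expected_beg = current.length + 1
            if obj_beg != expected_beg:
                raise ValueError(
                    f"AGP line {lineno}: object_beg {obj_beg} not contiguous "
                    f"(expected {expected_beg})"
                )
            if ctype in ("N", "U"):
                current.parts.append(Gap(int(cols[5]), cols[6], cols[7], cols[8]))
            else:
                comp = Component(cols[5], int(cols[6]) - 1, int(cols[7]), cols[8])
                if comp.length != obj_end - obj_beg + 1:
                    raise ValueError(f"AGP line {lineno}: component span mismatch")
                current.parts.append(comp)
    return plan
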