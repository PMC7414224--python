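"""Genome coordinate model, interval types and standard-format I/O.

Coordinates are 0-based, half-open (BED convention) throughout the
package.  Anchor points (TSS/TTS) are single 0-based base positions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

Strand = Literal["+", "-"]
AnchorKind = Literal["TSS", "TTS"]


class ParseError(ValueError):
    """Raised on malformed input rows; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in base pairs."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"missing length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        return self.lengths[chrom]

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.lengths[chrom] // bin_size)

    def chrom_order(self, chrom: str) -> int:
        return self.names.index(chrom)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) with an optional score."""

    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate_against(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > layout.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {layout.length_of(self.chrom)}"
            )


@dataclass(frozen=True)
class AnchorPoint:
    """A single-base TSS or TTS anchor with the strand of its gene."""

    kind: AnchorKind
    chrom: str
    position: int
    strand: Strand


@dataclass(frozen=True)
class GeneRecord:
    """Stranded gene interval with an expression level (RPKM)."""

    gene_id: str
    interval: Interval
    strand: Strand
    expression_rpkm: float = 0.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.expression_rpkm < 0:
            raise ValueError("expression_rpkm must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return len(self.interval)

    def with_expression(self, rpkm: float) -> "GeneRecord":
        return GeneRecord(self.gene_id, self.interval, self.strand, rpkm)


def anchor_of(gene: GeneRecord, kind: AnchorKind) -> AnchorPoint:
    """Anchor position of a gene.

    For a + gene TSS = start and TTS = end - 1; for a - gene the two
    swap (TSS = end - 1, TTS = start).  Positions are 0-based.
    """
    if kind not in ("TSS", "TTS"):
        raise ValueError(f"unknown anchor kind {kind!r}")
    at_start = (gene.strand == "+") == (kind == "TSS")
    pos = gene.start if at_start else gene.end - 1
    return AnchorPoint(kind, gene.chrom, pos, gene.strand)


def sort_key(layout: GenomeLayout | None):
    """Deterministic interval ordering: (chrom, start, end)."""

    def key(iv: Interval):
        c = layout.chrom_order(iv.chrom) if layout is not None else iv.chrom
        return (c, iv.start, iv.end)

    return key


def overlap_query(
    query: Sequence[Interval],
    subject: Sequence[Interval],
    layout: GenomeLayout | None = None,
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs with nonzero overlap.

    Half-open semantics: touching intervals do not overlap.  Runs a
    per-chromosome sweep over start-sorted queries, keeping a min-heap of
    active subject ends, so it is O((n + m) log(n + m) + k) for k hits.
    Result is sorted by (query index, subject index).
    """
    if layout is not None:
        for iv in list(query) + list(subject):
            if iv.chrom not in layout:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")

    by_chrom_q: dict[str, list[tuple[int, Interval]]] = {}
    by_chrom_s: dict[str, list[tuple[int, Interval]]] = {}
    for i, iv in enumerate(query):
        by_chrom_q.setdefault(iv.chrom, []).append((i, iv))
    for j, iv in enumerate(subject):
        by_chrom_s.setdefault(iv.chrom, []).append((j, iv))

    pairs: list[tuple[int, int]] = []
    for chrom, qs in by_chrom_q.items():
        ss = by_chrom_s.get(chrom)
        if not ss:
            continue
        qs_sorted = sorted(qs, key=lambda t: (t[1].start, t[1].end, t[0]))
        ss_sorted = sorted(ss, key=lambda t: (t[1].start, t[1].end, t[0]))
        active: list[tuple[int, int, int]] = []  # (end, start, subject index)
        si = 0
        for qi, qiv in qs_sorted:
            while si < len(ss_sorted) and ss_sorted[si][1].start < qiv.end:
                sj, siv = ss_sorted[si]
                heapq.heappush(active, (siv.end, siv.start, sj))
                si += 1
            while active and active[0][0] <= qiv.start:
                heapq.heappop(active)
            # a subject admitted for an earlier (longer) query may start
            # at or past this query's end; re-check the start here
            pairs.extend((qi, sj) for _, st, sj in active if st < qiv.end)
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeLayout:
    """Read a 2-column tab-separated chrom-sizes file into a GenomeLayout."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 tab-separated columns", path, lineno)
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return GenomeLayout.from_dict(lengths)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name in layout.names:
            fh.write(f"{name}\t{layout.lengths[name]}\n")


def read_gene_annotation(
    path,
    layout: GenomeLayout | None = None,
    expression: dict[str, float] | None = None,
    score_is_expression: bool = False,
) -> list[GeneRecord]:
    """Read genes from a BED6 (or BED12; blocks ignored) file.

    Expression is taken from the ``expression`` mapping (gene id ->
    RPKM) when given, from the BED score column when
    ``score_is_expression``, and defaults to 0 otherwise.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"expected >= 6 BED columns, got {len(fields)}", path, lineno
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", path, lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"invalid strand {strand!r}", path, lineno)
            try:
                iv = Interval(chrom, start, end)
                if layout is not None:
                    iv.validate_against(layout)
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
            rpkm = 0.0
            if expression is not None:
                rpkm = float(expression.get(name, 0.0))
            elif score_is_expression:
                rpkm = float(score_s)
            genes.append(GeneRecord(name, iv, strand, rpkm))
    return genes


def write_gene_annotation(genes: Iterable[GeneRecord], path) -> None:
    """Write genes as BED6; the score column carries RPKM."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t"
                f"{g.expression_rpkm:g}\t{g.strand}\n"
            )


def iter_bedgraph_records(path) -> Iterator[tuple[int, str, int, int, float]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("expected 4 tab-separated columns", path, lineno)
            try:
                yield lineno, fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None


def read_bed_intervals(path) -> list[Interval]:
    """Read a BED3+ file into Intervals (score column used when present)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >= 3 BED columns", path, lineno)
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = 0.0
            try:
                out.append(Interval(fields[0], int(fields[1]), int(fields[2]), score))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return out


def write_bed_intervals(
    intervals: Iterable[Interval], path, names: Iterable[str] | None = None
) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names else f"iv{k}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.score:g}\t.\n")
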