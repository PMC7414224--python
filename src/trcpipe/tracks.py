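"""Binned signal tracks: I/O, normalization, active-gene filtering and
expression-quintile assignment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import GeneRecord, GenomeLayout, ParseError, iter_bedgraph_records

Flavor = Literal["raw", "ratio"]


@dataclass
class SignalTrack:
    """Per-bin signal values over a genome layout.

    ``values`` maps chromosome name to a float array of length
    ceil(length / bin_size).  ``flavor`` distinguishes raw counts from
    normalized ratios.
    """

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    flavor: Flavor = "raw"

    def __post_init__(self):
        for chrom in self.layout.names:
            n = self.layout.n_bins(chrom, self.bin_size)
            arr = np.asarray(
                self.values.get(chrom, np.zeros(n)), dtype=float
            )
            if arr.shape != (n,):
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite values")
            self.values[chrom] = arr

    @classmethod
    def zeros(
        cls, layout: GenomeLayout, bin_size: int, flavor: Flavor = "raw"
    ) -> "SignalTrack":
        vals = {
            c: np.zeros(layout.n_bins(c, bin_size)) for c in layout.names
        }
        return cls(layout, bin_size, vals, flavor)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def n_bins_total(self) -> int:
        return int(sum(v.size for v in self.values.values()))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.layout.names])

    def bin_of(self, position: int) -> int:
        return position // self.bin_size

    def same_binning(self, other: "SignalTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.layout.names == other.layout.names
            and self.layout.lengths == other.layout.lengths
        )

    def scaled(self, factor: float, flavor: Flavor | None = None) -> "SignalTrack":
        return SignalTrack(
            self.layout,
            self.bin_size,
            {c: v * factor for c, v in self.values.items()},
            flavor or self.flavor,
        )

    def rpm(self) -> "SignalTrack":
        """Scale to reads per million (no-op total if track sums to 0)."""
        tot = self.total()
        if tot == 0:
            return self.scaled(1.0)
        return self.scaled(1e6 / tot)


def read_bedgraph(
    path,
    layout: GenomeLayout,
    bin_size: int,
    flavor: Flavor = "raw",
    sort: bool = False,
) -> SignalTrack:
    """Read a 4-column bedGraph into a binned SignalTrack.

    Records must be non-overlapping and sorted per chromosome (set
    ``sort=True`` to sort instead of erroring).  Each record's value is
    spread over the bins it covers, weighted by covered base pairs, so a
    bin-aligned file round-trips bit-exactly through
    :func:`write_bedgraph`.
    """
    records: dict[str, list[tuple[int, int, float]]] = {c: [] for c in layout.names}
    for lineno, chrom, start, end, value in iter_bedgraph_records(path):
        if chrom not in layout:
            raise ParseError(f"unknown chromosome {chrom!r}", path, lineno)
        if not (0 <= start < end <= layout.length_of(chrom)):
            raise ParseError(f"bad coordinates {start}-{end}", path, lineno)
        records[chrom].append((start, end, value))

    track = SignalTrack.zeros(layout, bin_size, flavor)
    for chrom, recs in records.items():
        if sort:
            recs = sorted(recs)
        prev_end = -1
        arr = track.values[chrom]
        weight = np.zeros_like(arr)
        hits = np.zeros(arr.size, dtype=np.int32)
        last = np.zeros_like(arr)
        length = layout.length_of(chrom)
        for start, end, value in recs:
            if start < prev_end:
                raise ParseError(
                    f"{chrom}: overlapping or unsorted records at {start}", path
                )
            prev_end = end
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                arr[b] += value * (hi - lo)
                weight[b] += hi - lo
                hits[b] += 1
                last[b] = value
        covered = weight > 0
        arr[covered] /= weight[covered]
        # a bin fully covered by one record carries that record's value
        # verbatim (exact round-trip, no multiply/divide rounding)
        bin_extent = np.minimum(
            (np.arange(arr.size) + 1) * bin_size, length
        ) - np.arange(arr.size) * bin_size
        exact = (hits == 1) & (weight == bin_extent)
        arr[exact] = last[exact]
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write one bedGraph row per bin (zero-valued bins included)."""
    with open(path, "w") as fh:
        for chrom in track.layout.names:
            length = track.layout.length_of(chrom)
            bs = track.bin_size
            for b, v in enumerate(track.values[chrom]):
                fh.write(
                    f"{chrom}\t{b * bs}\t{min((b + 1) * bs, length)}\t{float(v)!r}\n"
                )


def rpkm(count: float, feature_length: int, library_size: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0:
        raise ValueError("feature length must be > 0")
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 1e9 / (feature_length * library_size)


def ip_over_input(
    ip: SignalTrack, input_: SignalTrack, pseudocount: float = 1.0
) -> SignalTrack:
    """Per-bin (ip + pc) / (input + pc) after scaling both to equal totals.

    Both tracks are scaled to reads-per-million first, so the ratio is
    invariant to sequencing depth.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not ip.same_binning(input_):
        raise ValueError("IP and input tracks have mismatched binning")
    ip_s, in_s = ip.rpm(), input_.rpm()
    vals = {
        c: (ip_s.values[c] + pseudocount) / (in_s.values[c] + pseudocount)
        for c in ip.layout.names
    }
    return SignalTrack(ip.layout, ip.bin_size, vals, "ratio")


def filter_active(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Genes with expression RPKM strictly greater than zero."""
    return [g for g in genes if g.expression_rpkm > 0]


@dataclass(frozen=True)
class QuintileAssignment:
    """Expression quintiles: 1 = highest expression, 5 = lowest.

    Groups 1-4 hold floor(N/5) genes each; group 5 holds the remainder.
    """

    quintile_of: dict[str, int]
    group_sizes: tuple[int, int, int, int, int]

    def genes_in(self, q: int) -> list[str]:
        return [g for g, qq in self.quintile_of.items() if qq == q]


def expression_quintiles(genes: Sequence[GeneRecord]) -> QuintileAssignment:
    """Partition genes into five expression groups of decreasing RPKM.

    Genes are sorted by expression descending (ties broken by gene id);
    the first four groups take floor(N/5) genes each and the last group
    takes the rest.
    """
    n = len(genes)
    if n < 5:
        raise ValueError(f"need >= 5 genes for quintiles, got {n}")
    order = sorted(genes, key=lambda g: (-g.expression_rpkm, g.gene_id))
    base = n // 5
    sizes = (base, base, base, base, n - 4 * base)
    assign: dict[str, int] = {}
    idx = 0
    for q, size in enumerate(sizes, start=1):
        for g in order[idx : idx + size]:
            assign[g.gene_id] = q
        idx += size
    return QuintileAssignment(assign, sizes)


def read_expression_table(path, header: bool = False) -> dict[str, float]:
    """Read a 2-column tab-separated (gene id, value) expression table."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 tab-separated columns", path, lineno)
            try:
                table[fields[0]] = float(fields[1])
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return table
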