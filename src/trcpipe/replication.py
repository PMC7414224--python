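"""Replication fork direction from stranded Okazaki-fragment counts,
initiation-zone detection and orientation classification at gene anchors.

Sign convention: Crick-mapping Okazaki fragments indicate rightward
forks, so RFD = (C - W) / (C + W) with +1 = purely rightward movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import AnchorPoint, GeneRecord, GenomeLayout, Interval, ParseError, anchor_of

Orientation = Literal["HO", "CD", "ambiguous"]


@dataclass
class StrandedBinCounts:
    """Per-bin Watson (W) and Crick (C) Okazaki-fragment counts."""

    layout: GenomeLayout
    bin_size: int
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom in self.layout.names:
            n = self.layout.n_bins(chrom, self.bin_size)
            for attr in ("watson", "crick"):
                arr = np.asarray(getattr(self, attr)[chrom])
                if arr.shape != (n,):
                    raise ValueError(f"{chrom}/{attr}: expected {n} bins")
                if np.any(arr < 0):
                    raise ValueError(f"{chrom}/{attr}: negative counts")
                getattr(self, attr)[chrom] = arr.astype(np.int64)


@dataclass
class RFDTrack:
    """Per-bin replication fork direction in [-1, 1] with a coverage mask.

    ``valid`` marks bins with enough fragments; RFD values on masked
    bins are NaN and must not be consumed.
    """

    layout: GenomeLayout
    bin_size: int
    rfd: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]

    def value_at(self, chrom: str, position: int) -> float:
        b = position // self.bin_size
        if not self.valid[chrom][b]:
            return float("nan")
        return float(self.rfd[chrom][b])


@dataclass(frozen=True)
class InitiationZone:
    """Ascending-RFD segment marking preferential origin firing."""

    interval: Interval
    center: int
    efficiency_proxy: float  # (RFD right - RFD left) / 2, in (0, 1]


@dataclass(frozen=True)
class ConflictParams:
    """Thresholds for orientation calls and zone detection."""

    orientation_threshold: float = 0.25
    min_coverage: int = 30
    # 5-bin centered moving average: at typical per-bin coverage the RFD
    # noise is small and wider windows blur transitions enough to push
    # zone centers off the strand switch
    smoothing_window: int = 5
    ascent_slack: float = 0.03  # tolerated dip within one ascending run

    def __post_init__(self):
        if not (0 < self.orientation_threshold < 1):
            raise ValueError("orientation threshold must be in (0, 1)")
        if self.min_coverage < 0 or self.smoothing_window < 1:
            raise ValueError("invalid coverage/smoothing parameters")


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, NaN-aware, edge-shortened."""
    if window <= 1:
        return x.copy()
    half = window // 2
    n = x.size
    out = np.empty(n)
    finite = np.isfinite(x)
    xs = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
    return out


def compute_rfd(
    counts: StrandedBinCounts,
    params: ConflictParams = ConflictParams(),
    smooth: bool = False,
) -> RFDTrack:
    """RFD = (C - W) / (C + W) per bin; low-coverage bins are masked.

    Bins with C + W < ``min_coverage`` are invalid.  With
    ``smooth=True``, a centered moving average over the configured
    window is applied after the ratio.
    """
    rfd: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for chrom in counts.layout.names:
        w = counts.watson[chrom].astype(float)
        c = counts.crick[chrom].astype(float)
        tot = w + c
        ok = tot >= max(params.min_coverage, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(ok, (c - w) / np.where(tot > 0, tot, 1), np.nan)
        if smooth:
            r = _moving_average(r, params.smoothing_window)
        valid[chrom] = ok & np.isfinite(r)
        rfd[chrom] = np.where(valid[chrom], r, np.nan)
    return RFDTrack(counts.layout, counts.bin_size, rfd, valid)


def detect_initiation_zones(
    rfd: RFDTrack, params: ConflictParams = ConflictParams()
) -> list[InitiationZone]:
    """Maximal ascending runs of smoothed RFD rising by at least
    2 x theta.

    The track is smoothed with the configured moving average; runs are
    allowed to dip by at most ``ascent_slack`` so sampling noise does
    not fragment one transition into several.  A run qualifies when its
    total rise is >= 2 x theta (which includes, but is not limited to,
    runs crossing from <= -theta to >= +theta: an efficient origin
    inside a rightward-replicated neighborhood produces a large ascent
    that never goes negative).  The zone center is the midpoint of the
    run; zones are sorted by position.
    """
    theta = params.orientation_threshold
    zones: list[InitiationZone] = []
    bs = rfd.bin_size
    for chrom in rfd.layout.names:
        s = _moving_average(rfd.rfd[chrom], params.smoothing_window)
        n = s.size
        i = 0
        while i < n:
            if not np.isfinite(s[i]):
                i += 1
                continue
            # extend an ascending run [i, j] tolerating small dips
            j = i
            peak = s[i]
            while j + 1 < n and np.isfinite(s[j + 1]):
                if s[j + 1] >= peak - params.ascent_slack:
                    j += 1
                    peak = max(peak, s[j])
                else:
                    break
            if j > i:
                run = s[i : j + 1]
                lo_idx = int(np.argmin(run)) + i
                hi_idx = int(np.argmax(run)) + i
                lo, hi = s[lo_idx], s[hi_idx]
                if hi - lo >= 2 * theta and hi_idx > lo_idx:
                    # trim flat plateaus flanking the transition: keep the
                    # 10%-90% segment of the rise so the center sits on
                    # the strand switch, not the plateau midpoint
                    rise = hi - lo
                    seg = s[lo_idx : hi_idx + 1]
                    below = np.flatnonzero(seg <= lo + 0.1 * rise)
                    start_idx = lo_idx + int(below[-1]) if below.size else lo_idx
                    above = np.flatnonzero(s[start_idx : hi_idx + 1] >= hi - 0.1 * rise)
                    end_idx = start_idx + int(above[0]) if above.size else hi_idx
                    start_bp = start_idx * bs
                    end_bp = min((end_idx + 1) * bs, rfd.layout.length_of(chrom))
                    center = (start_bp + end_bp) // 2
                    zones.append(
                        InitiationZone(
                            Interval(chrom, start_bp, end_bp, (hi - lo) / 2),
                            center,
                            float((hi - lo) / 2),
                        )
                    )
            i = max(j, i + 1)
    zones.sort(key=lambda z: (rfd.layout.chrom_order(z.interval.chrom), z.center))
    return zones


def signed_codirectional_rfd(
    anchor: AnchorPoint, rfd: RFDTrack
) -> float:
    """RFD at the anchor bin, signed so that + means the fork moves with
    transcription (NaN when the bin is masked)."""
    sign = 1.0 if anchor.strand == "+" else -1.0
    return sign * rfd.value_at(anchor.chrom, anchor.position)


def orientation_at(
    anchor: AnchorPoint,
    rfd: RFDTrack,
    params: ConflictParams = ConflictParams(),
) -> Orientation:
    """Classify replication-transcription orientation at an anchor.

    s = strand sign x RFD(anchor bin); s >= theta -> CD (fork moves
    with transcription), s <= -theta -> HO (head-on), otherwise
    ambiguous.  Masked bins are ambiguous.
    """
    s = signed_codirectional_rfd(anchor, rfd)
    if not np.isfinite(s):
        return "ambiguous"
    if s >= params.orientation_threshold:
        return "CD"
    if s <= -params.orientation_threshold:
        return "HO"
    return "ambiguous"


def distance_to_downstream_origin(
    gene: GeneRecord, zones: Sequence[InitiationZone]
) -> int | None:
    """Distance (bp) from the TTS to the nearest zone center past the
    TTS in the direction of transcription; None when no such zone
    exists on the gene's chromosome."""
    tts = anchor_of(gene, "TTS")
    centers = [
        z.center for z in zones if z.interval.chrom == gene.chrom
    ]
    if gene.strand == "+":
        downstream = [c - tts.position for c in centers if c > tts.position]
    else:
        downstream = [tts.position - c for c in centers if c < tts.position]
    return min(downstream) if downstream else None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_okseq(path, layout: GenomeLayout, bin_size: int) -> StrandedBinCounts:
    """Read 5-column tab-separated (chrom, start, end, watson, crick)
    bin counts; rows must be bin-aligned."""
    watson = {c: np.zeros(layout.n_bins(c, bin_size), dtype=np.int64) for c in layout.names}
    crick = {c: np.zeros(layout.n_bins(c, bin_size), dtype=np.int64) for c in layout.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError("expected 5 tab-separated columns", path, lineno)
            chrom = fields[0]
            if chrom not in layout:
                raise ParseError(f"unknown chromosome {chrom!r}", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
                w, c = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
            if start % bin_size != 0:
                raise ParseError(f"row not aligned to {bin_size} bp bins", path, lineno)
            if w < 0 or c < 0:
                raise ParseError("negative counts", path, lineno)
            b = start // bin_size
            watson[chrom][b] = w
            crick[chrom][b] = c
    return StrandedBinCounts(layout, bin_size, watson, crick)


def write_okseq(counts: StrandedBinCounts, path) -> None:
    with open(path, "w") as fh:
        for chrom in counts.layout.names:
            length = counts.layout.length_of(chrom)
            bs = counts.bin_size
            w, c = counts.watson[chrom], counts.crick[chrom]
            for b in range(w.size):
                fh.write(
                    f"{chrom}\t{b * bs}\t{min((b + 1) * bs, length)}\t{w[b]}\t{c[b]}\n"
                )


def write_rfd_bedgraph(rfd: RFDTrack, path) -> None:
    """Write valid RFD bins as bedGraph (masked bins omitted)."""
    with open(path, "w") as fh:
        for chrom in rfd.layout.names:
            length = rfd.layout.length_of(chrom)
            bs = rfd.bin_size
            vals, ok = rfd.rfd[chrom], rfd.valid[chrom]
            for b in range(vals.size):
                if ok[b]:
                    fh.write(
                        f"{chrom}\t{b * bs}\t{min((b + 1) * bs, length)}\t{vals[b]:.6g}\n"
                    )


def write_zones_bed(zones: Sequence[InitiationZone], path) -> None:
    with open(path, "w") as fh:
        for k, z in enumerate(zones):
            fh.write(
                f"{z.interval.chrom}\t{z.interval.start}\t{z.interval.end}\t"
                f"zone{k}\t{z.efficiency_proxy:.4g}\t.\n"
            )
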