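"""Poisson local-background peak calling with BH q-values, replicate
reproducibility filtering, peak-to-feature annotation, gene/peak overlap
statistics and broad-domain width measurement.

The caller is a deliberate bin-level simplification of MACS2-style
calling: per bin, lambda is the larger of the genome-wide and the 10 kb
local input mean, scaled to the IP library size; p-values are Poisson
upper tails and are BH-adjusted across all bins genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GeneRecord, Interval, anchor_of, overlap_query
from .tracks import SignalTrack


@dataclass(frozen=True)
class Peak:
    """Enriched interval with summit, IP/background enrichment and q-value."""

    interval: Interval
    summit: int
    enrichment: float
    q_value: float

    def __post_init__(self):
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must be in [0, 1]")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class PeakCallConfig:
    q_threshold: float = 0.05
    local_window: int = 10_000  # bp, centered local-lambda window
    merge_gap: int = 1  # bins
    min_width: int = 2  # bins

    def __post_init__(self):
        if not (0.0 < self.q_threshold < 1.0):
            raise ValueError("q threshold must be in (0, 1)")
        if self.local_window <= 0 or self.merge_gap < 0 or self.min_width < 1:
            raise ValueError("invalid window/merge/width configuration")


def _local_mean(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered moving average with edge-shortened windows."""
    half = max(window_bins // 2, 1)
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _merge_runs(sig_idx: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Group sorted significant bin indices into runs, merging across
    gaps of at most ``merge_gap`` bins.  Returns inclusive (start, end)."""
    runs: list[tuple[int, int]] = []
    if sig_idx.size == 0:
        return runs
    start = prev = int(sig_idx[0])
    for b in sig_idx[1:]:
        b = int(b)
        if b - prev - 1 <= merge_gap:
            prev = b
        else:
            runs.append((start, prev))
            start = prev = b
    runs.append((start, prev))
    return runs


def call_peaks(
    ip: SignalTrack,
    input_: SignalTrack,
    cfg: PeakCallConfig = PeakCallConfig(),
) -> list[Peak]:
    """Bin-level Poisson peak calling against a local/global input lambda.

    Per bin, lambda = max(genome-wide input mean, local input mean over
    the configured window) scaled by IP total / input total; the p-value
    is the Poisson upper tail P(X >= x | lambda).  q-values are BH
    across all bins genome-wide; bins with q <= threshold are merged
    within the merge gap and peaks narrower than min_width bins are
    dropped.  The summit is the leftmost bin of maximal IP count.
    """
    if not ip.same_binning(input_):
        raise ValueError("IP and input tracks have mismatched binning")
    ip_total, input_total = ip.total(), input_.total()
    if ip_total == 0 and input_total == 0:
        return []
    if input_total == 0:
        raise ValueError("input track is empty but IP is not")
    scale = ip_total / input_total
    genome_mean = input_total / input_.n_bins_total()
    window_bins = max(1, cfg.local_window // ip.bin_size)

    chroms = ip.layout.names
    pvals: list[np.ndarray] = []
    lambdas: dict[str, np.ndarray] = {}
    for chrom in chroms:
        local = _local_mean(input_.values[chrom], window_bins)
        lam = np.maximum(genome_mean, local) * scale
        lambdas[chrom] = lam
        x = ip.values[chrom]
        pvals.append(stats.poisson.sf(np.round(x) - 1, lam))
    p_all = np.concatenate(pvals)
    q_all = stats.false_discovery_control(p_all, method="bh")

    peaks: list[Peak] = []
    offset = 0
    for chrom in chroms:
        n = ip.values[chrom].size
        q = q_all[offset : offset + n]
        offset += n
        sig = np.flatnonzero(q <= cfg.q_threshold)
        for b0, b1 in _merge_runs(sig, cfg.merge_gap):
            if b1 - b0 + 1 < cfg.min_width:
                continue
            x = ip.values[chrom][b0 : b1 + 1]
            lam = lambdas[chrom][b0 : b1 + 1]
            summit_bin = b0 + int(np.argmax(x))
            bs = ip.bin_size
            start = b0 * bs
            end = min((b1 + 1) * bs, ip.layout.length_of(chrom))
            summit = min(summit_bin * bs + bs // 2, end - 1)
            enrich = float(x.sum() / max(lam.sum(), 1e-300))
            qmin = float(q[b0 : b1 + 1].min())
            peaks.append(Peak(Interval(chrom, start, end, enrich), summit, enrich, qmin))
    peaks.sort(key=lambda p: (ip.layout.chrom_order(p.chrom), p.interval.start))
    return peaks


def _reciprocal_overlap(a: Interval, b: Interval, frac: float = 0.5) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov > 0 and ov >= frac * len(a) and ov >= frac * len(b)


def reproducible_peaks(
    replicates: Sequence[Sequence[Peak]], min_overlap: float = 0.5
) -> list[Peak]:
    """Replicate-consistency filter (reciprocal-overlap intersection).

    A peak from the first replicate is kept when every other replicate
    (2-5 supported) contains a peak with >= ``min_overlap`` reciprocal
    overlap; the consensus interval is the intersection of all matched
    peaks.  Enrichment and q-value are taken from the first replicate.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    if len(replicates) > 5:
        raise ValueError("at most 5 replicate peak sets are supported")
    consensus: list[Peak] = []
    for peak in replicates[0]:
        lo, hi = peak.interval.start, peak.interval.end
        matched_all = True
        for other in replicates[1:]:
            match = next(
                (
                    p
                    for p in other
                    if _reciprocal_overlap(peak.interval, p.interval, min_overlap)
                ),
                None,
            )
            if match is None:
                matched_all = False
                break
            lo = max(lo, match.interval.start)
            hi = min(hi, match.interval.end)
        if not matched_all or lo >= hi:
            continue
        summit = min(max(peak.summit, lo), hi - 1)
        consensus.append(
            Peak(
                Interval(peak.chrom, lo, hi, peak.interval.score),
                summit,
                peak.enrichment,
                peak.q_value,
            )
        )
    return consensus


CATEGORIES = ("TSS_region", "TTS_region", "gene_body", "intergenic")


def _feature_regions(
    gene: GeneRecord, upstream: int, downstream: int, utr_proxy: int
) -> dict[str, tuple[int, int]]:
    """Half-open TSS/TTS region spans for one gene (strand-aware)."""
    tss = anchor_of(gene, "TSS").position
    tts = anchor_of(gene, "TTS").position
    if gene.strand == "+":
        tss_span = (tss - upstream, tss + utr_proxy)
        tts_span = (tts - utr_proxy + 1, tts + downstream + 1)
    else:
        tss_span = (tss - utr_proxy + 1, tss + upstream + 1)
        tts_span = (tts - downstream, tts + utr_proxy)
    return {"TSS_region": tss_span, "TTS_region": tts_span}


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneRecord],
    upstream: int = 3_000,
    downstream: int = 3_000,
    utr_proxy: int = 500,
    layout=None,
) -> tuple[dict[str, float], list[str], dict[str, float]]:
    """Classify peak summits into TSS region / TTS region / gene body /
    intergenic (in that priority) and report category fractions.

    TSS region: 3 kb upstream of the TSS through ``utr_proxy`` bp into
    the gene; TTS region: ``utr_proxy`` bp before the TTS through 3 kb
    past it.  Also returns the random baseline: the genomic base-pair
    fraction of each category under the same priority (requires a
    layout; taken from the first gene's coordinates span otherwise).

    Returns (fractions, per-peak categories, baseline fractions).
    """
    tss_spans: dict[str, list[tuple[int, int]]] = {}
    tts_spans: dict[str, list[tuple[int, int]]] = {}
    body_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        regions = _feature_regions(g, upstream, downstream, utr_proxy)
        tss_spans.setdefault(g.chrom, []).append(regions["TSS_region"])
        tts_spans.setdefault(g.chrom, []).append(regions["TTS_region"])
        body_spans.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in (tss_spans, tts_spans, body_spans):
        for chrom in spans:
            spans[chrom].sort()

    def classify(chrom: str, pos: int) -> str:
        for name, spans in (
            ("TSS_region", tss_spans),
            ("TTS_region", tts_spans),
            ("gene_body", body_spans),
        ):
            for lo, hi in spans.get(chrom, ()):
                if lo <= pos < hi:
                    return name
                if lo > pos:
                    break
        return "intergenic"

    categories = [classify(p.chrom, p.summit) for p in peaks]
    n = max(len(categories), 1)
    fractions = {c: categories.count(c) / n for c in CATEGORIES}

    # baseline: paint the genome at bp resolution with the same priority
    if layout is None:
        lengths = {}
        for g in genes:
            lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end + downstream + upstream)
    else:
        lengths = {c: layout.length_of(c) for c in layout.names}
    counts = dict.fromkeys(CATEGORIES, 0)
    total = 0
    for chrom, L in lengths.items():
        paint = np.full(L, 3, dtype=np.uint8)  # intergenic
        for lo, hi in body_spans.get(chrom, ()):
            paint[max(lo, 0) : min(hi, L)] = 2
        for lo, hi in tts_spans.get(chrom, ()):
            paint[max(lo, 0) : min(hi, L)] = 1
        for lo, hi in tss_spans.get(chrom, ()):
            paint[max(lo, 0) : min(hi, L)] = 0
        binc = np.bincount(paint, minlength=4)
        for i, c in enumerate(CATEGORIES):
            counts[c] += int(binc[i])
        total += L
    baseline = {c: counts[c] / total for c in CATEGORIES}
    return fractions, categories, baseline


def gene_peak_overlap(
    genes: Sequence[GeneRecord], peak_sets: dict[str, Sequence[Peak]]
) -> tuple[dict[str, set[str]], dict[tuple[str, str], float]]:
    """Per-gene positive labels for each named peak set plus pairwise
    overlap percentages |A inter B| / |A| for every ordered set pair."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    spans = [g.interval for g in genes]
    labels: dict[str, set[str]] = {}
    for name, peaks in peak_sets.items():
        pairs = overlap_query(spans, [p.interval for p in peaks])
        labels[name] = {genes[qi].gene_id for qi, _ in pairs}
    pct: dict[tuple[str, str], float] = {}
    for a, sa in labels.items():
        for b, sb in labels.items():
            if a == b:
                continue
            pct[(a, b)] = 100.0 * len(sa & sb) / len(sa) if sa else 0.0
    return labels, pct


def broad_domain_width(
    track: SignalTrack, threshold: float, merge_gap: int = 2_000
) -> list[int]:
    """Widths (bp) of maximal runs of bins at or above ``threshold``,
    merged across gaps of at most ``merge_gap`` bp."""
    gap_bins = merge_gap // track.bin_size
    widths: list[int] = []
    for chrom in track.layout.names:
        above = np.flatnonzero(track.values[chrom] >= threshold)
        L = track.layout.length_of(chrom)
        for b0, b1 in _merge_runs(above, gap_bins):
            widths.append(min((b1 + 1) * track.bin_size, L) - b0 * track.bin_size)
    return widths
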