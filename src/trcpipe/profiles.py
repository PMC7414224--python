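"""Anchor-centered and scaled-gene metaprofiles with SEM, window
quantification, and quintile-stratified sorted TTS heatmaps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import AnchorPoint, GeneRecord, anchor_of
from .tracks import QuintileAssignment, SignalTrack

ProfileMode = Literal["scaled-body", "anchor-window"]


@dataclass
class MetaProfile:
    """Per-gene signal matrix plus column means and SEM.

    In scaled-body mode columns are [upstream flank bins | body bins |
    downstream flank bins]; in anchor-window mode they are the bins of a
    fixed window centered on the anchor.  Rows are oriented 5'->3'
    (minus-strand genes reversed).  Out-of-chromosome positions are NaN
    and excluded from the column statistics.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    mode: ProfileMode
    flank_bins: int
    body_bins: int
    skipped: int = 0

    @property
    def column_means(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    @property
    def column_sem(self) -> np.ndarray:
        n = np.sum(np.isfinite(self.matrix), axis=0)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(self.matrix, axis=0, ddof=1)
        return np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _gene_row_bins(track: SignalTrack, chrom: str, b0: int, b1: int) -> np.ndarray:
    """Bin values for [b0, b1), NaN-padded outside the chromosome."""
    vals = track.values[chrom]
    out = np.full(b1 - b0, np.nan)
    lo, hi = max(b0, 0), min(b1, vals.size)
    if hi > lo:
        out[lo - b0 : hi - b0] = vals[lo:hi]
    return out


def _pool_body(vals: np.ndarray, body_bins: int) -> np.ndarray:
    """Rescale a gene-body bin vector to ``body_bins`` columns.

    Mean pooling when the body has at least ``body_bins`` bins,
    index-based upsampling otherwise.
    """
    m = vals.size
    if m >= body_bins:
        edges = np.round(np.linspace(0, m, body_bins + 1)).astype(int)
        edges = np.maximum.accumulate(edges)
        return np.array(
            [np.mean(vals[edges[i] : max(edges[i + 1], edges[i] + 1)]) for i in range(body_bins)]
        )
    idx = np.minimum((np.arange(body_bins) * m) // body_bins, m - 1)
    return vals[idx]


def meta_profile(
    track: SignalTrack,
    genes: Sequence[GeneRecord],
    mode: ProfileMode = "scaled-body",
    flank: int = 10_000,
    body_bins: int = 100,
    anchor_kind: str = "TSS",
) -> MetaProfile:
    """Metaprofile of a track over genes.

    scaled-body: each gene contributes upstream flank bins, a body
    rescaled to ``body_bins`` columns by mean pooling, and downstream
    flank bins.  anchor-window: a fixed window of +/- ``flank`` bp
    around the chosen anchor.  Rows for minus-strand genes are
    reversed so every row reads 5'->3'.  Genes shorter than one bin are
    skipped and counted.
    """
    if not genes:
        raise ValueError("gene collection is empty")
    bs = track.bin_size
    flank_bins = flank // bs
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped = 0
    for g in genes:
        if g.length < bs:
            skipped += 1
            continue
        if mode == "scaled-body":
            gb0, gb1 = g.start // bs, (g.end - 1) // bs + 1
            left = _gene_row_bins(track, g.chrom, gb0 - flank_bins, gb0)
            body = _pool_body(_gene_row_bins(track, g.chrom, gb0, gb1), body_bins)
            right = _gene_row_bins(track, g.chrom, gb1, gb1 + flank_bins)
            row = np.concatenate([left, body, right])
        elif mode == "anchor-window":
            pos = anchor_of(g, anchor_kind).position
            b = pos // bs
            row = _gene_row_bins(track, g.chrom, b - flank_bins, b + flank_bins)
        else:
            raise ValueError(f"unknown profile mode {mode!r}")
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * flank_bins + body_bins))
    return MetaProfile(
        matrix,
        ids,
        mode,
        flank_bins,
        body_bins if mode == "scaled-body" else 0,
        skipped,
    )


def window_quantify(
    track: SignalTrack, anchor: AnchorPoint, half_width: int
) -> float:
    """Mean track value over [position - half_width, position +
    half_width), bp-weighted across bins and clipped at chromosome ends."""
    L = track.layout.length_of(anchor.chrom)
    lo = max(0, anchor.position - half_width)
    hi = min(L, anchor.position + half_width)
    if hi <= lo:
        return float("nan")
    bs = track.bin_size
    vals = track.values[anchor.chrom]
    b0, b1 = lo // bs, (hi - 1) // bs
    total = 0.0
    weight = 0
    for b in range(b0, b1 + 1):
        w = min(hi, (b + 1) * bs) - max(lo, b * bs)
        total += vals[b] * w
        weight += w
    return total / weight


def window_scores(
    track: SignalTrack,
    genes: Sequence[GeneRecord],
    anchor_kind: str = "TTS",
    half_width: int = 2_000,
) -> dict[str, float]:
    """window_quantify at one anchor kind for every gene."""
    return {
        g.gene_id: window_quantify(track, anchor_of(g, anchor_kind), half_width)
        for g in genes
    }


@dataclass
class TTSHeatmap:
    """Per-track anchor-window matrices sharing one row order.

    Rows are grouped by expression quintile (1 first); within each
    quintile they are sorted by descending mean of the sort track's
    window, ties broken by gene id.
    """

    matrices: dict[str, np.ndarray]
    gene_ids: list[str]
    quintile_blocks: tuple[int, ...]
    sort_track: str


def tts_heatmap(
    tracks: dict[str, SignalTrack],
    genes: Sequence[GeneRecord],
    quintiles: QuintileAssignment,
    window: int = 10_000,
    sort_track: str | None = None,
) -> TTSHeatmap:
    """Quintile-blocked, signal-sorted TTS heatmap matrices.

    The row order is computed once from the sort track (default: first
    track) and applied identically to every track matrix.
    """
    if not tracks:
        raise ValueError("no tracks given")
    sort_track = sort_track or next(iter(tracks))
    if sort_track not in tracks:
        raise ValueError(f"sort track {sort_track!r} not among tracks")
    missing = [g.gene_id for g in genes if g.gene_id not in quintiles.quintile_of]
    if missing:
        raise ValueError(f"quintile assignment missing {len(missing)} genes")

    profiles = {
        name: meta_profile(t, genes, mode="anchor-window", flank=window, anchor_kind="TTS")
        for name, t in tracks.items()
    }
    ref = profiles[sort_track]
    if any(p.gene_ids != ref.gene_ids for p in profiles.values()):
        raise ValueError("tracks disagree on usable genes")
    with np.errstate(invalid="ignore"):
        sort_vals = np.nanmean(ref.matrix, axis=1)
    order = sorted(
        range(len(ref.gene_ids)),
        key=lambda i: (
            quintiles.quintile_of[ref.gene_ids[i]],
            -(sort_vals[i] if np.isfinite(sort_vals[i]) else -np.inf),
            ref.gene_ids[i],
        ),
    )
    ids = [ref.gene_ids[i] for i in order]
    blocks = tuple(
        sum(1 for g in ids if quintiles.quintile_of[g] == q) for q in range(1, 6)
    )
    matrices = {name: p.matrix[order] for name, p in profiles.items()}
    return TTSHeatmap(matrices, ids, blocks, sort_track)
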