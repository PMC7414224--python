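"""Gene-pair geometry and the integrative conflict statistics:
distance- and expression-stratified TTS signal, orientation-stratified
enrichment, and origin-distance curves."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import GeneRecord, anchor_of
from .profiles import window_quantify
from .replication import (
    ConflictParams,
    InitiationZone,
    RFDTrack,
    distance_to_downstream_origin,
    orientation_at,
)
from .tracks import QuintileAssignment, SignalTrack

Relation = Literal["converging", "codirectional", "divergent"]


@dataclass(frozen=True)
class GenePair:
    """Adjacent gene pair, ordered by coordinate."""

    upstream_id: str
    downstream_id: str
    relation: Relation
    gap: int  # bp between facing ends, 0 when overlapping

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


@dataclass(frozen=True)
class AnalysisParams:
    converging_gap_threshold: int = 5_000
    tts_half_width: int = 2_000
    flank: int = 10_000
    top_fraction: float = 0.25
    n_quintiles: int = 5
    bootstrap_samples: int = 1_000
    pair_expression: Literal["min", "max", "mean"] = "min"

    def __post_init__(self):
        if min(self.converging_gap_threshold, self.tts_half_width, self.flank) <= 0:
            raise ValueError("window parameters must be positive")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top fraction must be in (0, 1]")
        if self.n_quintiles != 5:
            raise ValueError("quintile count is fixed at 5")


def classify_gene_pairs(genes: Sequence[GeneRecord]) -> list[GenePair]:
    """Classify every adjacent gene pair per chromosome.

    The upstream member is the one with the smaller coordinate.
    (+,-) is converging (facing 3' ends), (-,+) divergent, same strand
    codirectional.  Gap = downstream.start - upstream.end, clipped at 0
    for overlapping annotations.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[GenePair] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for a, b in zip(ordered, ordered[1:]):
            if a.strand == b.strand:
                relation: Relation = "codirectional"
            elif a.strand == "+":
                relation = "converging"
            else:
                relation = "divergent"
            pairs.append(
                GenePair(a.gene_id, b.gene_id, relation, max(0, b.start - a.end))
            )
    return pairs


@dataclass
class StratumSummary:
    n: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class GapStratification:
    below: StratumSummary | None  # gap < threshold
    at_or_above: StratumSummary | None
    curve: list[tuple[int, int, int, float]]  # (gap_lo, gap_hi, n, mean)


def _bootstrap_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    if values.size == 1:
        v = float(values[0])
        return v, v
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    return float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


def signal_by_gap(
    pairs: Sequence[GenePair],
    track: SignalTrack,
    genes: Sequence[GeneRecord],
    params: AnalysisParams = AnalysisParams(),
    gap_bins: Sequence[int] = (0, 2_500, 5_000, 10_000, 20_000, 40_000),
    seed: int = 0,
) -> GapStratification:
    """TTS-window signal of converging pairs, stratified by gap.

    For each converging pair, both members' TTS windows are quantified;
    strata (< threshold vs >=) report mean and a seeded 95% bootstrap
    CI.  A gap-binned curve is also returned.  An empty stratum is
    reported as absent (None).
    """
    by_id = {g.gene_id: g for g in genes}
    rng = np.random.default_rng(seed)
    gap_values: list[tuple[int, float]] = []
    for p in pairs:
        if p.relation != "converging":
            continue
        for gid in (p.upstream_id, p.downstream_id):
            score = window_quantify(
                track, anchor_of(by_id[gid], "TTS"), params.tts_half_width
            )
            if np.isfinite(score):
                gap_values.append((p.gap, score))

    def summarize(vals: list[float]) -> StratumSummary | None:
        if not vals:
            return None
        arr = np.asarray(vals)
        lo, hi = _bootstrap_ci(arr, params.bootstrap_samples, rng)
        return StratumSummary(arr.size, float(arr.mean()), lo, hi)

    thr = params.converging_gap_threshold
    below = summarize([v for g, v in gap_values if g < thr])
    above = summarize([v for g, v in gap_values if g >= thr])
    curve: list[tuple[int, int, int, float]] = []
    edges = list(gap_bins)
    for lo_e, hi_e in zip(edges, edges[1:]):
        vals = [v for g, v in gap_values if lo_e <= g < hi_e]
        curve.append(
            (lo_e, hi_e, len(vals), float(np.mean(vals)) if vals else float("nan"))
        )
    return GapStratification(below, above, curve)


@dataclass
class QuintileRow:
    quintile: int
    n: int
    mean: float
    sem: float


def signal_by_expression(
    genes: Sequence[GeneRecord],
    track: SignalTrack,
    quintiles: QuintileAssignment,
    params: AnalysisParams = AnalysisParams(),
    anchor_kind: str = "TTS",
) -> list[QuintileRow]:
    """Per-expression-quintile mean TTS-window signal with SEM.

    Quintiles with no usable genes are flagged with n = 0 and NaN mean.
    """
    scores: dict[int, list[float]] = {q: [] for q in range(1, 6)}
    for g in genes:
        q = quintiles.quintile_of.get(g.gene_id)
        if q is None:
            continue
        v = window_quantify(track, anchor_of(g, anchor_kind), params.tts_half_width)
        if np.isfinite(v):
            scores[q].append(v)
    rows = []
    for q in range(1, 6):
        vals = np.asarray(scores[q])
        if vals.size == 0:
            rows.append(QuintileRow(q, 0, float("nan"), float("nan")))
        else:
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append(QuintileRow(q, vals.size, float(vals.mean()), sem))
    return rows


@dataclass
class OrientationCell:
    anchor: str  # TSS or TTS
    orientation: str  # HO, CD or ambiguous
    n: int
    mean: float
    sem: float


def ho_cd_enrichment(
    genes: Sequence[GeneRecord],
    rfd: RFDTrack,
    track: SignalTrack,
    params: AnalysisParams = AnalysisParams(),
    conflict_params: ConflictParams = ConflictParams(),
) -> list[OrientationCell]:
    """Mean anchor-window signal for {TSS, TTS} x {HO, CD, ambiguous}."""
    cells: dict[tuple[str, str], list[float]] = {
        (a, o): [] for a in ("TSS", "TTS") for o in ("HO", "CD", "ambiguous")
    }
    for g in genes:
        for kind in ("TSS", "TTS"):
            anchor = anchor_of(g, kind)
            orient = orientation_at(anchor, rfd, conflict_params)
            v = window_quantify(track, anchor, params.tts_half_width)
            if np.isfinite(v):
                cells[(kind, orient)].append(v)
    out = []
    for (kind, orient), vals in cells.items():
        arr = np.asarray(vals)
        if arr.size == 0:
            out.append(OrientationCell(kind, orient, 0, float("nan"), float("nan")))
        else:
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            out.append(OrientationCell(kind, orient, arr.size, float(arr.mean()), sem))
    return out


@dataclass
class DistanceCurve:
    bins: list[tuple[int, int, int, float, float]]  # (lo, hi, n, mean, sem)
    excluded: int  # genes with no downstream origin
    per_gene: list[tuple[str, int, float]]  # (gene id, distance, score)


def signal_vs_origin_distance(
    genes: Sequence[GeneRecord],
    zones: Sequence[InitiationZone],
    track: SignalTrack,
    distance_bins: Sequence[int] = (0, 10_000, 25_000, 50_000, 100_000, 250_000),
    params: AnalysisParams = AnalysisParams(),
) -> DistanceCurve:
    """Mean TTS-window signal binned by distance to the nearest
    downstream initiation-zone center (in the direction of
    transcription).  Genes with no downstream zone are excluded and
    counted."""
    per_gene: list[tuple[str, int, float]] = []
    excluded = 0
    for g in genes:
        d = distance_to_downstream_origin(g, zones)
        if d is None:
            excluded += 1
            continue
        v = window_quantify(track, anchor_of(g, "TTS"), params.tts_half_width)
        if np.isfinite(v):
            per_gene.append((g.gene_id, d, v))
    edges = list(distance_bins)
    bins = []
    for lo, hi in zip(edges, edges[1:]):
        vals = np.asarray([v for _, d, v in per_gene if lo <= d < hi])
        if vals.size == 0:
            bins.append((lo, hi, 0, float("nan"), float("nan")))
        else:
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            bins.append((lo, hi, int(vals.size), float(vals.mean()), sem))
    return DistanceCurve(bins, excluded, per_gene)
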