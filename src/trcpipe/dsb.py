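"""DSB-positive gene calling from break-end sequencing signal at TTS:
top-fraction ranking, hierarchical clustering, rank-sum comparisons and
orientation composition of the resulting groups."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .conflicts import AnalysisParams, GenePair
from .core import GeneRecord
from .profiles import MetaProfile, meta_profile, window_scores
from .tracks import SignalTrack


@dataclass
class DSBRanking:
    """Genes ordered by TTS break signal with the top fraction labeled."""

    scores: dict[str, float]
    ordered_ids: list[str]
    top_set: set[str]
    degenerate: bool  # all scores equal: top set decided by tie-break only


def rank_tts_dsb(
    ibless: SignalTrack,
    genes: Sequence[GeneRecord],
    params: AnalysisParams = AnalysisParams(),
    anchor_kind: str = "TTS",
) -> DSBRanking:
    """Score = mean reads-per-million break signal over the anchor
    window (+/- tts_half_width); genes sorted by descending score with
    gene-id tie-break; the top ceil(fraction x N) genes are labeled."""
    scores = window_scores(ibless.rpm(), genes, anchor_kind, params.tts_half_width)
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    k = math.ceil(params.top_fraction * len(ordered))
    vals = list(scores.values())
    degenerate = len(set(vals)) <= 1
    if degenerate:
        warnings.warn("all TTS scores identical; top set is tie-break only")
    return DSBRanking(scores, ordered, set(ordered[:k]), degenerate)


@dataclass
class DSBClassification:
    """DSB+/DSB- gene labels with the per-condition scores that produced
    them."""

    labels: dict[str, str]  # gene id -> "DSB+" | "DSB-"
    scores: dict[str, tuple[float, float]]  # gene id -> (control, shTop1)
    method: Literal["top-fraction", "clustering"]

    def positives(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == "DSB+"}

    def negatives(self) -> set[str]:
        return {g for g, l in self.labels.items() if l == "DSB-"}


def cluster_dsb_genes(
    features: dict[str, tuple[float, float]], linkage: str = "ward"
) -> DSBClassification:
    """Two-group agglomerative clustering of per-gene (control, shTop1)
    TTS scores.

    Features are standardized per column; Ward linkage on Euclidean
    distance, cut at k = 2; the cluster with the higher mean shTop1
    score is DSB+.  All-identical feature rows degenerate to a single
    all-DSB- cluster with a warning.
    """
    ids = sorted(features)
    if len(ids) < 2:
        raise ValueError("need >= 2 genes to cluster")
    X = np.array([features[g] for g in ids], dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if np.allclose(X, X[0]):
        warnings.warn("identical feature rows: degenerate single cluster")
        return DSBClassification(
            {g: "DSB-" for g in ids}, {g: tuple(features[g]) for g in ids}, "clustering"
        )
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    assign = AgglomerativeClustering(n_clusters=2, linkage=linkage).fit_predict(Z)
    mean_sh = [X[assign == k, 1].mean() for k in (0, 1)]
    pos_cluster = int(np.argmax(mean_sh))
    labels = {
        g: ("DSB+" if a == pos_cluster else "DSB-") for g, a in zip(ids, assign)
    }
    return DSBClassification(labels, {g: tuple(features[g]) for g in ids}, "clustering")


def top_fraction_classification(
    ranking: DSBRanking, scores: dict[str, tuple[float, float]] | None = None
) -> DSBClassification:
    labels = {
        g: ("DSB+" if g in ranking.top_set else "DSB-") for g in ranking.scores
    }
    if scores is None:
        scores = {g: (float("nan"), s) for g, s in ranking.scores.items()}
    return DSBClassification(labels, scores, "top-fraction")


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test, two-sided, normal
    approximation with tie and continuity corrections.

    Returns (U statistic of the first group, p-value)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class OrientationComposition:
    """HO/CD percentages within DSB+ and DSB- plus a two-proportion
    z-test on the HO fraction."""

    table: dict[str, dict[str, float]]  # group -> orientation -> percent
    counts: dict[str, dict[str, int]]
    p_value: float


def _two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> float:
    if n1 == 0 or n2 == 0:
        return float("nan")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))


def orientation_composition(
    classification: DSBClassification, orientations: dict[str, str]
) -> OrientationComposition:
    """Composition of HO and CD genes within the DSB+ and DSB- groups.

    ``orientations`` maps gene id to an HO/CD(/ambiguous) label (from
    orientation calls or pair geometry).  Percentages are over genes
    with a known orientation in each group.
    """
    counts = {g: {"HO": 0, "CD": 0, "other": 0} for g in ("DSB+", "DSB-")}
    for gid, label in classification.labels.items():
        orient = orientations.get(gid, "other")
        key = orient if orient in ("HO", "CD") else "other"
        counts[label][key] += 1
    table: dict[str, dict[str, float]] = {}
    for grp, c in counts.items():
        n = c["HO"] + c["CD"]
        table[grp] = {
            "HO": 100.0 * c["HO"] / n if n else float("nan"),
            "CD": 100.0 * c["CD"] / n if n else float("nan"),
        }
    p = _two_proportion_z(
        counts["DSB+"]["HO"],
        counts["DSB+"]["HO"] + counts["DSB+"]["CD"],
        counts["DSB-"]["HO"],
        counts["DSB-"]["HO"] + counts["DSB-"]["CD"],
    )
    return OrientationComposition(table, counts, p)


def pair_orientation_labels(pairs: Sequence[GenePair]) -> dict[str, str]:
    """HO/CD labels from adjacent-pair geometry: members of a converging
    pair are HO at their TTS, members of codirectional pairs CD.
    Converging membership wins when a gene appears in both."""
    labels: dict[str, str] = {}
    for p in pairs:
        if p.relation == "codirectional":
            for gid in (p.upstream_id, p.downstream_id):
                labels.setdefault(gid, "CD")
    for p in pairs:
        if p.relation == "converging":
            for gid in (p.upstream_id, p.downstream_id):
                labels[gid] = "HO"
    return labels


@dataclass
class GroupComparison:
    profile_pos: MetaProfile
    profile_neg: MetaProfile
    mean_pos: float
    mean_neg: float
    p_value: float


def group_signal_profiles(
    classification: DSBClassification,
    tracks: dict[str, SignalTrack],
    genes: Sequence[GeneRecord],
    params: AnalysisParams = AnalysisParams(),
) -> dict[str, GroupComparison]:
    """Per-track DSB+ vs DSB- TTS metaprofiles plus a rank-sum test on
    the TTS-window scores of the two groups."""
    pos_ids, neg_ids = classification.positives(), classification.negatives()
    pos = [g for g in genes if g.gene_id in pos_ids]
    neg = [g for g in genes if g.gene_id in neg_ids]
    if not pos or not neg:
        raise ValueError("both DSB groups must be non-empty")
    out: dict[str, GroupComparison] = {}
    for name, track in tracks.items():
        prof_pos = meta_profile(track, pos, mode="anchor-window", flank=params.flank, anchor_kind="TTS")
        prof_neg = meta_profile(track, neg, mode="anchor-window", flank=params.flank, anchor_kind="TTS")
        s_pos = [
            v
            for v in window_scores(track, pos, "TTS", params.tts_half_width).values()
            if np.isfinite(v)
        ]
        s_neg = [
            v
            for v in window_scores(track, neg, "TTS", params.tts_half_width).values()
            if np.isfinite(v)
        ]
        _, p = compare_groups(s_pos, s_neg)
        out[name] = GroupComparison(
            prof_pos, prof_neg, float(np.mean(s_pos)), float(np.mean(s_neg)), p
        )
    return out
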