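"""Seeded synthetic multi-omics genome generator with planted truth.

Generates a toy genome with non-overlapping genes, promoter-enriched
replication origins, a Monte-Carlo replication-fork-direction field,
stranded Okazaki-fragment counts, and condition-specific signal tracks
(DRIP IP/input, p-RPA, gamma-H2AX, i-BLESS).  Every stochastic draw is
governed by the config seed, so identical configs produce bit-identical
output.  The planted truth (origins, RFD field, bump positions, DSB+
labels, orientations) backs all parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    GeneRecord,
    GenomeLayout,
    Interval,
    anchor_of,
    write_chrom_sizes,
    write_gene_annotation,
)
from .replication import StrandedBinCounts, write_okseq
from .tracks import SignalTrack, write_bedgraph

CONDITIONS = ("control", "shTop1")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # genome geometry
    chrom_lengths: tuple[int, ...] = (40_000_000,)
    bin_size: int = 1_000
    n_genes: int = 2_000
    gene_length_log_mean: float = math.log(3_500.0)
    gene_length_log_sigma: float = 0.4
    gene_length_range: tuple[int, int] = (1_500, 12_000)
    # gene-pair geometry: strand flip probability 0.6 makes ~30% of
    # adjacent pairs converging; half of the gaps fall below 5 kb
    converging_fraction: float = 0.30
    near_gap_fraction: float = 0.5
    near_gap_range: tuple[int, int] = (500, 4_800)
    far_gap_range: tuple[int, int] = (18_000, 36_000)
    # expression
    zero_expression_fraction: float = 0.2
    expression_log_mean: float = 1.5
    expression_log_sigma: float = 0.5
    # origins
    promoter_origin_prob: float = 0.7  # top expression quintile
    promoter_origin_prob_other: float = 0.2  # other active genes
    origin_upstream_range: tuple[int, int] = (1_000, 3_000)
    intergenic_origin_rate: float = 1.0 / 100_000  # per intergenic bp
    # candidate origins closer than this are thinned (highest efficiency
    # wins) so each kept origin marks one resolvable initiation zone
    origin_min_separation: int = 12_000
    efficiency_range: tuple[float, float] = (0.2, 0.9)
    n_cells: int = 200
    # sequencing depths / amplitudes (per bin)
    okseq_depth: float = 500.0
    drip_background: float = 20.0
    drip_amp_scale: float = 115.0
    drip_shtop1_multiplier: float = 1.3
    bump_sigma: float = 1_500.0
    prpa_background: float = 10.0
    prpa_amp_scale: float = 60.0
    ibless_background: float = 1.0
    ibless_amp: float = 25.0
    ibless_half_width: int = 2_000
    gh2ax_background: float = 20.0
    gh2ax_amp: float = 60.0
    gh2ax_domain_width: int = 100_000
    # converging-gene DRIP boost at TTS (1.0 disables)
    conv_drip_boost: float = 2.0
    conv_gap_threshold: int = 5_000
    # DSB planting
    dsb_fraction: float = 0.27
    dsb_orientation_targeted: bool = True
    dsb_orientation_leak: float = 0.15
    condition: str = "control"

    def __post_init__(self):
        for name in (
            "converging_fraction",
            "near_gap_fraction",
            "zero_expression_fraction",
            "promoter_origin_prob",
            "promoter_origin_prob_other",
            "dsb_fraction",
            "dsb_orientation_leak",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for L in self.chrom_lengths:
            if L % self.bin_size != 0:
                raise ValueError("chromosome length must be divisible by bin size")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PlantedBump:
    """A planted Gaussian signal bump tied to a gene anchor."""

    gene_id: str
    anchor_kind: str  # TSS or TTS
    chrom: str
    center: int
    amplitude: float
    interval: Interval  # center +/- 3 sigma, the declared footprint


@dataclass
class SimTruth:
    """Planted ground truth for every downstream recovery test."""

    config: SimConfig
    layout: GenomeLayout
    genes: list[GeneRecord]
    origin_positions: dict[str, np.ndarray]
    origin_efficiencies: dict[str, np.ndarray]
    rfd_true: dict[str, np.ndarray]  # per-bin, in [-1, 1]
    s_true: dict[str, dict[str, float]]  # gene id -> {TSS: s, TTS: s}
    orientation_true: dict[str, dict[str, str]]  # gene id -> {TSS/TTS: HO|CD|ambiguous}
    dsb_positive: list[str]
    drip_bumps: list[PlantedBump]
    prpa_bumps: list[PlantedBump]
    converging_boosted: list[str]
    gh2ax_domains: list[Interval]  # planted only in shTop1 tracks
    ibless_sites: list[Interval]  # planted only in shTop1 tracks

    def rfd_true_at(self, chrom: str, position: int) -> float:
        return float(self.rfd_true[chrom][position // self.config.bin_size])

    def active_gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.expression_rpkm > 0]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _true_orientation(s: float) -> str:
    if s < 0:
        return "HO"
    if s > 0:
        return "CD"
    return "ambiguous"


def simulate_rfd_field(
    positions: np.ndarray,
    efficiencies: np.ndarray,
    n_bins: int,
    bin_size: int,
    n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo replication-fork-direction field for one chromosome.

    Per cell, each origin fires independently with its efficiency; every
    bin is replicated by the nearest firing origin and moves away from
    it (direction = sign(bin center - origin), +1 at the origin bin
    itself).  Returns the per-bin mean direction over ``n_cells``, in
    [-1, 1].  A chromosome without origins yields all zeros.
    """
    centers = (np.arange(n_bins) + 0.5) * bin_size
    P = np.asarray(positions, dtype=float)
    E = np.asarray(efficiencies, dtype=float)
    if P.size == 0:
        return np.zeros(n_bins)
    acc = np.zeros(n_bins)
    for _ in range(n_cells):
        fired = np.zeros(P.size, dtype=bool)
        for _try in range(100):
            fired = rng.random(P.size) < E
            if fired.any():
                break
        Pf = P[fired]
        idx = np.searchsorted(Pf, centers)
        left = Pf[np.clip(idx - 1, 0, Pf.size - 1)]
        right = Pf[np.clip(idx, 0, Pf.size - 1)]
        d_left = np.where(idx > 0, centers - left, np.inf)
        d_right = np.where(idx < Pf.size, right - centers, np.inf)
        nearest = np.where(d_left <= d_right, left, right)
        acc += np.sign(centers - nearest) + (centers == nearest)
    return np.clip(acc / n_cells, -1.0, 1.0)


def simulate_genome(config: SimConfig) -> tuple[GenomeLayout, list[GeneRecord], SimTruth]:
    """Generate genes, origins and the true RFD field.

    Genes are packed left to right with gaps drawn from a near/far
    mixture; strands follow a two-state Markov chain whose flip
    probability 2 x converging_fraction yields the requested fraction of
    converging adjacent pairs.  Origins are placed upstream of promoters
    (probability depending on expression) plus a Poisson scatter in
    intergenic space.  The true RFD field is the Monte-Carlo mean over
    n_cells of sign(bin center - nearest firing origin).
    """
    rng = _rng(config, 0)
    names = tuple(f"chr{i + 1}" for i in range(len(config.chrom_lengths)))
    layout = GenomeLayout(names, dict(zip(names, config.chrom_lengths)))

    total_len = sum(config.chrom_lengths)
    genes: list[GeneRecord] = []
    gene_counter = 0
    flip_prob = min(1.0, 2.0 * config.converging_fraction)
    for chrom, L in zip(names, config.chrom_lengths):
        n_chrom = round(config.n_genes * L / total_len)
        cursor = int(rng.integers(2_000, 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(n_chrom):
            length = int(
                np.clip(
                    rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sigma),
                    *config.gene_length_range,
                )
            )
            if cursor + length > L - 2_000:
                raise ValueError(
                    f"infeasible packing: cannot place {config.n_genes} genes "
                    f"of this length distribution on {total_len} bp"
                )
            gene_counter += 1
            genes.append(
                GeneRecord(
                    f"g{gene_counter:05d}", Interval(chrom, cursor, cursor + length), strand
                )
            )
            if rng.random() < flip_prob:
                strand = "-" if strand == "+" else "+"
            if rng.random() < config.near_gap_fraction:
                gap = int(rng.integers(*config.near_gap_range))
            else:
                gap = int(rng.integers(*config.far_gap_range))
            cursor += length + gap

    # expression
    n = len(genes)
    zero = rng.random(n) < config.zero_expression_fraction
    rpkm = rng.lognormal(config.expression_log_mean, config.expression_log_sigma, n)
    rpkm[zero] = 0.0
    genes = [g.with_expression(float(r)) for g, r in zip(genes, rpkm)]

    # origins: promoter-proximal with expression-dependent probability
    q1_cut = np.quantile(rpkm[rpkm > 0], 0.8) if np.any(rpkm > 0) else np.inf
    origin_positions: dict[str, list[float]] = {c: [] for c in names}
    origin_efficiencies: dict[str, list[float]] = {c: [] for c in names}
    for g in genes:
        if g.expression_rpkm <= 0:
            continue
        p = (
            config.promoter_origin_prob
            if g.expression_rpkm >= q1_cut
            else config.promoter_origin_prob_other
        )
        if rng.random() >= p:
            continue
        offset = int(rng.integers(*config.origin_upstream_range))
        tss = anchor_of(g, "TSS").position
        pos = tss - offset if g.strand == "+" else tss + offset
        if 0 < pos < layout.length_of(g.chrom):
            origin_positions[g.chrom].append(pos)
            origin_efficiencies[g.chrom].append(rng.uniform(*config.efficiency_range))

    # intergenic Poisson scatter
    for chrom, L in zip(names, config.chrom_lengths):
        spans = sorted(
            (g.start, g.end) for g in genes if g.chrom == chrom
        )
        gaps: list[tuple[int, int]] = []
        prev = 0
        for s, e in spans:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < L:
            gaps.append((prev, L))
        gap_lens = np.array([e - s for s, e in gaps], dtype=float)
        total_gap = gap_lens.sum()
        k = rng.poisson(total_gap * config.intergenic_origin_rate)
        if k > 0 and total_gap > 0:
            which = rng.choice(len(gaps), size=k, p=gap_lens / total_gap)
            for gi in which:
                s, e = gaps[gi]
                origin_positions[chrom].append(int(rng.integers(s, e)))
                origin_efficiencies[chrom].append(rng.uniform(*config.efficiency_range))

    opos: dict[str, np.ndarray] = {}
    oeff: dict[str, np.ndarray] = {}
    for chrom in names:
        pos = np.asarray(origin_positions[chrom], dtype=np.int64)
        eff = np.asarray(origin_efficiencies[chrom], dtype=float)
        # thin clustered candidates: strongest first, drop any within
        # origin_min_separation of an already-kept origin
        keep_pos: list[int] = []
        keep_eff: list[float] = []
        for i in np.argsort(-eff, kind="stable"):
            p = int(pos[i])
            if all(abs(p - k) >= config.origin_min_separation for k in keep_pos):
                keep_pos.append(p)
                keep_eff.append(float(eff[i]))
        order = np.argsort(keep_pos)
        opos[chrom] = np.asarray(keep_pos, dtype=np.int64)[order]
        oeff[chrom] = np.asarray(keep_eff, dtype=float)[order]

    # Monte-Carlo RFD field: nearest firing origin replicates each bin
    rfd_true: dict[str, np.ndarray] = {}
    for chrom, L in zip(names, config.chrom_lengths):
        rfd_true[chrom] = simulate_rfd_field(
            opos[chrom], oeff[chrom], L // config.bin_size, config.bin_size,
            config.n_cells, rng,
        )

    # true orientations at anchors
    s_true: dict[str, dict[str, float]] = {}
    orientation_true: dict[str, dict[str, str]] = {}
    for g in genes:
        sign = 1.0 if g.strand == "+" else -1.0
        entry_s, entry_o = {}, {}
        for kind in ("TSS", "TTS"):
            pos = anchor_of(g, kind).position
            s = sign * rfd_true[g.chrom][pos // config.bin_size]
            entry_s[kind] = float(s)
            entry_o[kind] = _true_orientation(s)
        s_true[g.gene_id] = entry_s
        orientation_true[g.gene_id] = entry_o

    # converging close pairs (independent adjacent-pair scan)
    boosted: set[str] = set()
    for chrom in names:
        cg = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: (g.start, g.end)
        )
        for a, b in zip(cg, cg[1:]):
            if a.strand == "+" and b.strand == "-":
                gap = max(0, b.start - a.end)
                if gap < config.conv_gap_threshold:
                    boosted.update((a.gene_id, b.gene_id))

    # DSB+ genes: preferentially high-expression head-on-TTS active genes
    active = [g for g in genes if g.expression_rpkm > 0]
    k_dsb = round(config.dsb_fraction * len(active))
    if k_dsb > 0 and active:
        expr = np.array([g.expression_rpkm for g in active])
        rank_pct = np.argsort(np.argsort(expr)) / max(len(active) - 1, 1)
        if config.dsb_orientation_targeted:
            ho = np.array(
                [orientation_true[g.gene_id]["TTS"] == "HO" for g in active]
            )
            w = (0.2 + rank_pct) * np.where(ho, 1.0, config.dsb_orientation_leak)
        else:
            w = np.ones(len(active))
        w = w / w.sum()
        chosen = rng.choice(len(active), size=k_dsb, replace=False, p=w)
        dsb_positive = sorted(active[i].gene_id for i in chosen)
    else:
        dsb_positive = []
    dsb_set = set(dsb_positive)

    # planted bumps
    sigma = config.bump_sigma
    drip_bumps: list[PlantedBump] = []
    prpa_bumps: list[PlantedBump] = []
    for g in genes:
        if g.expression_rpkm <= 0:
            continue
        base = math.log1p(g.expression_rpkm)
        for kind in ("TSS", "TTS"):
            pos = anchor_of(g, kind).position
            amp = config.drip_amp_scale * base
            if kind == "TTS" and g.gene_id in boosted:
                amp *= config.conv_drip_boost
            lo = max(0, int(pos - 3 * sigma))
            hi = min(layout.length_of(g.chrom), int(pos + 3 * sigma))
            drip_bumps.append(
                PlantedBump(g.gene_id, kind, g.chrom, pos, amp, Interval(g.chrom, lo, hi))
            )
        stall = max(0.0, -s_true[g.gene_id]["TTS"])
        if stall > 0:
            pos = anchor_of(g, "TTS").position
            amp = config.prpa_amp_scale * base * stall
            lo = max(0, int(pos - 3 * sigma))
            hi = min(layout.length_of(g.chrom), int(pos + 3 * sigma))
            prpa_bumps.append(
                PlantedBump(g.gene_id, "TTS", g.chrom, pos, amp, Interval(g.chrom, lo, hi))
            )

    gh2ax_domains: list[Interval] = []
    ibless_sites: list[Interval] = []
    half_dom = config.gh2ax_domain_width // 2
    for g in genes:
        if g.gene_id not in dsb_set:
            continue
        tts = anchor_of(g, "TTS").position
        L = layout.length_of(g.chrom)
        gh2ax_domains.append(
            Interval(g.chrom, max(0, tts - half_dom), min(L, tts + half_dom))
        )
        ibless_sites.append(
            Interval(
                g.chrom,
                max(0, tts - config.ibless_half_width),
                min(L, tts + config.ibless_half_width),
            )
        )

    truth = SimTruth(
        config=config,
        layout=layout,
        genes=genes,
        origin_positions=opos,
        origin_efficiencies=oeff,
        rfd_true=rfd_true,
        s_true=s_true,
        orientation_true=orientation_true,
        dsb_positive=dsb_positive,
        drip_bumps=drip_bumps,
        prpa_bumps=prpa_bumps,
        converging_boosted=sorted(boosted),
        gh2ax_domains=gh2ax_domains,
        ibless_sites=ibless_sites,
    )
    return layout, genes, truth


def simulate_okseq(truth: SimTruth, depth: float | None = None) -> StrandedBinCounts:
    """Stranded Okazaki counts: total ~ Poisson(depth) per bin,
    crick ~ Binomial(total, (1 + RFD_true) / 2), watson = total - crick."""
    config = truth.config
    depth = config.okseq_depth if depth is None else depth
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _rng(config, 1)
    watson: dict[str, np.ndarray] = {}
    crick: dict[str, np.ndarray] = {}
    for chrom in truth.layout.names:
        r = truth.rfd_true[chrom]
        total = rng.poisson(depth, r.size)
        p_crick = np.clip((1.0 + r) / 2.0, 0.0, 1.0)
        c = rng.binomial(total, p_crick)
        crick[chrom] = c.astype(np.int64)
        watson[chrom] = (total - c).astype(np.int64)
    return StrandedBinCounts(truth.layout, config.bin_size, watson, crick)


def _add_bump(arr: np.ndarray, bin_size: int, center: int, amp: float, sigma: float):
    b0 = max(0, int((center - 4 * sigma) // bin_size))
    b1 = min(arr.size - 1, int((center + 4 * sigma) // bin_size))
    if b1 < b0:
        return
    bc = (np.arange(b0, b1 + 1) + 0.5) * bin_size
    arr[b0 : b1 + 1] += amp * np.exp(-0.5 * ((bc - center) / sigma) ** 2)


def _add_plateau(arr: np.ndarray, bin_size: int, start: int, end: int, amp: float):
    b0 = start // bin_size
    b1 = (end - 1) // bin_size
    arr[b0 : b1 + 1] += amp


def simulate_tracks(truth: SimTruth, config: SimConfig | None = None) -> dict[str, SignalTrack]:
    """Condition-specific raw-count tracks.

    Returns DRIP IP, DRIP input, p-RPA, gamma-H2AX and i-BLESS tracks as
    Poisson draws around the planted expectation.  In the control
    condition i-BLESS and gamma-H2AX carry background only; the shTop1
    condition plants i-BLESS plateaus at DSB+ TTS (+/- 2 kb) and
    flat-top gamma-H2AX domains centered on DSB+ TTS, and scales DRIP
    bump amplitudes by the shTop1 multiplier.
    """
    config = truth.config if config is None else config
    shtop1 = config.condition == "shTop1"
    rng = _rng(config, 3 if shtop1 else 2)
    bs = config.bin_size
    layout = truth.layout

    mu = {
        name: {c: np.zeros(layout.n_bins(c, bs)) for c in layout.names}
        for name in ("drip_ip", "drip_input", "prpa", "gh2ax", "ibless")
    }
    for c in layout.names:
        mu["drip_ip"][c] += config.drip_background
        mu["drip_input"][c] += config.drip_background
        mu["prpa"][c] += config.prpa_background
        mu["gh2ax"][c] += config.gh2ax_background
        mu["ibless"][c] += config.ibless_background

    drip_factor = config.drip_shtop1_multiplier if shtop1 else 1.0
    for b in truth.drip_bumps:
        _add_bump(mu["drip_ip"][b.chrom], bs, b.center, b.amplitude * drip_factor, config.bump_sigma)
    for b in truth.prpa_bumps:
        _add_bump(mu["prpa"][b.chrom], bs, b.center, b.amplitude, config.bump_sigma)
    if shtop1:
        for iv in truth.gh2ax_domains:
            _add_plateau(mu["gh2ax"][iv.chrom], bs, iv.start, iv.end, config.gh2ax_amp)
        for iv in truth.ibless_sites:
            _add_plateau(mu["ibless"][iv.chrom], bs, iv.start, iv.end, config.ibless_amp)

    out: dict[str, SignalTrack] = {}
    for name in ("drip_ip", "drip_input", "prpa", "gh2ax", "ibless"):
        vals = {c: rng.poisson(mu[name][c]).astype(float) for c in layout.names}
        out[name] = SignalTrack(layout, bs, vals, "raw")
    return out


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def truth_to_dict(truth: SimTruth) -> dict:
    """JSON-serializable view of the planted truth."""
    return {
        "config": dataclasses.asdict(truth.config),
        "chromosomes": {c: truth.layout.lengths[c] for c in truth.layout.names},
        "origins": {
            c: [
                {"position": int(p), "efficiency": float(e)}
                for p, e in zip(truth.origin_positions[c], truth.origin_efficiencies[c])
            ]
            for c in truth.layout.names
        },
        "rfd_true": {c: [round(float(v), 6) for v in truth.rfd_true[c]] for c in truth.layout.names},
        "s_true": truth.s_true,
        "orientation_true": truth.orientation_true,
        "dsb_positive": truth.dsb_positive,
        "converging_boosted": truth.converging_boosted,
        "drip_bumps": [
            {
                "gene_id": b.gene_id,
                "anchor": b.anchor_kind,
                "chrom": b.chrom,
                "center": b.center,
                "amplitude": round(b.amplitude, 6),
                "start": b.interval.start,
                "end": b.interval.end,
            }
            for b in truth.drip_bumps
        ],
        "prpa_bumps": [
            {
                "gene_id": b.gene_id,
                "anchor": b.anchor_kind,
                "chrom": b.chrom,
                "center": b.center,
                "amplitude": round(b.amplitude, 6),
                "start": b.interval.start,
                "end": b.interval.end,
            }
            for b in truth.prpa_bumps
        ],
        "gh2ax_domains": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in truth.gh2ax_domains
        ],
        "ibless_sites": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in truth.ibless_sites
        ],
    }


def write_dataset(truth: SimTruth, outdir, conditions=CONDITIONS) -> dict[str, str]:
    """Write the complete plain-text dataset; returns a name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    write_chrom_sizes(truth.layout, outdir / "chrom.sizes")
    manifest["chrom_sizes"] = str(outdir / "chrom.sizes")
    write_gene_annotation(truth.genes, outdir / "genes.bed")
    manifest["genes"] = str(outdir / "genes.bed")
    write_okseq(simulate_okseq(truth), outdir / "okseq.tsv")
    manifest["okseq"] = str(outdir / "okseq.tsv")

    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\trpkm\n")
        for g in truth.genes:
            fh.write(f"{g.gene_id}\t{g.expression_rpkm:.6g}\n")
    manifest["expression"] = str(outdir / "expression.tsv")

    for condition in conditions:
        tracks = simulate_tracks(truth, truth.config.replace(condition=condition))
        for name, track in tracks.items():
            path = outdir / f"{name}.{condition}.bedgraph"
            write_bedgraph(track, path)
            manifest[f"{name}.{condition}"] = str(path)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_to_dict(truth), fh)
    manifest["truth"] = str(outdir / "truth.json")
    return manifest
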