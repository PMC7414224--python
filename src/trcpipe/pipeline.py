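"""Pipeline orchestration: wiring simulation/ingestion, RFD, peak
calling, annotation, profiles, conflict statistics and DSB
classification into one deterministic run with a manifest and a summary
report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import conflicts as cf
from . import dsb as dsbmod
from . import enrichment as en
from . import profiles as pr
from . import replication as rp
from . import simulate as sim
from . import tracks as tr
from .core import GenomeLayout, read_chrom_sizes, read_gene_annotation

log = logging.getLogger("trcpipe")

TRACK_NAMES = ("drip_ip", "drip_input", "prpa", "gh2ax", "ibless")


@dataclass
class PipelineConfig:
    """Run configuration; built from a YAML document.

    Either a ``simulate`` block (SimConfig overrides) or explicit input
    paths (genes, chrom_sizes, okseq, expression, per-condition
    bedGraph tracks) must be provided.
    """

    outdir: str = "trcpipe_out"
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    bin_size: int = 1_000
    analysis: cf.AnalysisParams = field(default_factory=cf.AnalysisParams)
    conflict: rp.ConflictParams = field(default_factory=rp.ConflictParams)
    peaks: en.PeakCallConfig = field(default_factory=en.PeakCallConfig)
    upstream: int = 3_000
    downstream: int = 3_000
    utr_proxy: int = 500
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kw: dict[str, Any] = {}
        for key in ("outdir", "seed", "simulate", "inputs", "bin_size",
                    "upstream", "downstream", "utr_proxy", "log_level"):
            if key in d:
                kw[key] = d.pop(key)
        if "analysis" in d:
            kw["analysis"] = cf.AnalysisParams(**d.pop("analysis"))
        if "conflict" in d:
            kw["conflict"] = rp.ConflictParams(**d.pop("conflict"))
        if "peaks" in d:
            kw["peaks"] = en.PeakCallConfig(**d.pop("peaks"))
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)


def _write_tsv(path: Path, header: list[str], rows: list[list[Any]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.6g}" if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def _fmt(v: float) -> str:
    return f"{v:.6g}"


class PipelineRun:
    """Stateful single run; stages append to the manifest and summary."""

    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.cfg = config
        self.resume = resume
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, str] = {}
        self.summary: list[tuple[str, str]] = []

    def _emit(self, name: str, path: Path) -> None:
        self.manifest[name] = str(path)

    def _skip(self, path: Path) -> bool:
        return self.resume and path.exists()

    # -- stage: inputs ------------------------------------------------
    def load_inputs(self):
        cfg = self.cfg
        t0 = time.monotonic()
        if cfg.simulate is not None:
            simcfg = sim.SimConfig(seed=cfg.seed, **cfg.simulate)
            layout, genes, truth = sim.simulate_genome(simcfg)
            counts = sim.simulate_okseq(truth)
            tracks = {
                cond: sim.simulate_tracks(truth, simcfg.replace(condition=cond))
                for cond in sim.CONDITIONS
            }
            datadir = self.outdir / "data"
            if not self._skip(datadir / "truth.json"):
                for name, p in sim.write_dataset(truth, datadir).items():
                    self._emit(f"data/{name}", Path(p))
            self.truth = truth
        elif cfg.inputs is not None:
            paths = cfg.inputs
            for key in ("chrom_sizes", "genes", "okseq", "expression"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(
                        f"required input {key!r} missing or not found: "
                        f"{paths.get(key)}"
                    )
            layout = read_chrom_sizes(paths["chrom_sizes"])
            expr = tr.read_expression_table(paths["expression"], header=True)
            genes = read_gene_annotation(paths["genes"], layout, expression=expr)
            counts = rp.read_okseq(paths["okseq"], layout, cfg.bin_size)
            tracks = {}
            for cond in sim.CONDITIONS:
                tracks[cond] = {}
                for name in TRACK_NAMES:
                    key = f"{name}.{cond}"
                    if key not in paths:
                        raise FileNotFoundError(f"required track {key!r} missing")
                    tracks[cond][name] = tr.read_bedgraph(
                        paths[key], layout, cfg.bin_size
                    )
            self.truth = None
        else:
            raise ValueError("config needs either a 'simulate' block or 'inputs'")
        self.layout, self.genes, self.counts, self.tracks = layout, genes, counts, tracks
        self.active = tr.filter_active(self.genes)
        self.quintiles = tr.expression_quintiles(self.genes)
        log.info("inputs ready in %.1fs (%d genes, %d active)",
                 time.monotonic() - t0, len(self.genes), len(self.active))

    # -- stage: replication -------------------------------------------
    def stage_rfd(self):
        t0 = time.monotonic()
        self.rfd = rp.compute_rfd(self.counts, self.cfg.conflict)
        self.zones = rp.detect_initiation_zones(self.rfd, self.cfg.conflict)
        p1, p2 = self.outdir / "rfd.bedgraph", self.outdir / "zones.bed"
        if not self._skip(p1):
            rp.write_rfd_bedgraph(self.rfd, p1)
        if not self._skip(p2):
            rp.write_zones_bed(self.zones, p2)
        self._emit("rfd", p1)
        self._emit("zones", p2)
        self.summary.append(("initiation_zones", str(len(self.zones))))
        log.info("rfd stage in %.1fs (%d zones)", time.monotonic() - t0, len(self.zones))

    # -- stage: peaks --------------------------------------------------
    def stage_peaks(self):
        t0 = time.monotonic()
        ctl = self.tracks["control"]
        self.drip_peaks = en.call_peaks(ctl["drip_ip"], ctl["drip_input"], self.cfg.peaks)
        self.prpa_peaks = en.call_peaks(ctl["prpa"], ctl["drip_input"], self.cfg.peaks)
        for name, peaks in (("drip_peaks", self.drip_peaks), ("prpa_peaks", self.prpa_peaks)):
            path = self.outdir / f"{name}.bed"
            if not self._skip(path):
                with open(path, "w") as fh:
                    for k, p in enumerate(peaks):
                        fh.write(
                            f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                            f"{name[:4]}{k}\t{p.enrichment:.6g}\t.\t{p.summit}\t"
                            f"{p.q_value:.6g}\n"
                        )
            self._emit(name, path)
            self.summary.append((name, str(len(peaks))))
        log.info("peak stage in %.1fs", time.monotonic() - t0)

    def stage_annotation(self):
        cfg = self.cfg
        fractions, _, baseline = en.annotate_peaks(
            self.drip_peaks, self.genes, cfg.upstream, cfg.downstream,
            cfg.utr_proxy, self.layout,
        )
        path = self.outdir / "peak_annotation.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["category", "fraction", "random_baseline"],
                [[c, fractions[c], baseline[c]] for c in en.CATEGORIES],
            )
        self._emit("peak_annotation", path)
        for c in en.CATEGORIES:
            self.summary.append((f"drip_frac_{c}", _fmt(fractions[c])))

        labels, pct = en.gene_peak_overlap(
            self.genes, {"drip": self.drip_peaks, "prpa": self.prpa_peaks}
        )
        self.overlap_labels = labels
        for (a, b), v in sorted(pct.items()):
            self.summary.append((f"overlap_{a}_and_{b}_pct_of_{a}", _fmt(v)))

    # -- stage: profiles ----------------------------------------------
    def stage_profiles(self):
        t0 = time.monotonic()
        ctl = self.tracks["control"]
        ratio = tr.ip_over_input(ctl["drip_ip"], ctl["drip_input"])
        prof = pr.meta_profile(
            ratio, self.active, mode="scaled-body", flank=self.cfg.analysis.flank
        )
        path = self.outdir / "drip_metaprofile.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["column", "mean", "sem"],
                [
                    [i, float(m), float(s)]
                    for i, (m, s) in enumerate(zip(prof.column_means, prof.column_sem))
                ],
            )
        self._emit("drip_metaprofile", path)

        heat = pr.tts_heatmap(
            {"drip": ratio, "prpa": ctl["prpa"], "gh2ax": self.tracks["shTop1"]["gh2ax"]},
            self.genes,
            self.quintiles,
            window=self.cfg.analysis.flank,
            sort_track="drip",
        )
        for name, mat in heat.matrices.items():
            path = self.outdir / f"heatmap_{name}.tsv"
            if not self._skip(path):
                with open(path, "w") as fh:
                    fh.write("gene_id\t" + "\t".join(
                        f"bin{i}" for i in range(mat.shape[1])) + "\n")
                    for gid, row in zip(heat.gene_ids, mat):
                        fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
            self._emit(f"heatmap_{name}", path)
        self.summary.append(
            ("heatmap_quintile_blocks", ",".join(map(str, heat.quintile_blocks)))
        )
        log.info("profile stage in %.1fs", time.monotonic() - t0)

    # -- stage: conflicts ---------------------------------------------
    def stage_conflicts(self):
        t0 = time.monotonic()
        ap = self.cfg.analysis
        ctl = self.tracks["control"]
        drip_ratio = tr.ip_over_input(ctl["drip_ip"], ctl["drip_input"])
        self.pairs = cf.classify_gene_pairs(self.genes)
        path = self.outdir / "gene_pairs.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["upstream", "downstream", "relation", "gap"],
                [[p.upstream_id, p.downstream_id, p.relation, p.gap] for p in self.pairs],
            )
        self._emit("gene_pairs", path)

        strat = cf.signal_by_gap(
            self.pairs, drip_ratio, self.genes, ap, seed=self.cfg.seed
        )
        rows = []
        for name, s in (("gap_lt_threshold", strat.below), ("gap_ge_threshold", strat.at_or_above)):
            if s is None:
                rows.append([name, 0, float("nan"), float("nan"), float("nan")])
            else:
                rows.append([name, s.n, s.mean, s.ci_low, s.ci_high])
                self.summary.append((f"drip_tts_{name}_mean", _fmt(s.mean)))
        path = self.outdir / "converging_gap_strata.tsv"
        if not self._skip(path):
            _write_tsv(path, ["stratum", "n", "mean", "ci_low", "ci_high"], rows)
        self._emit("converging_gap_strata", path)

        expr_rows = cf.signal_by_expression(self.genes, ctl["prpa"], self.quintiles, ap)
        path = self.outdir / "prpa_by_expression.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["quintile", "n", "mean", "sem"],
                [[r.quintile, r.n, r.mean, r.sem] for r in expr_rows],
            )
        self._emit("prpa_by_expression", path)

        cells = cf.ho_cd_enrichment(
            self.active, self.rfd, ctl["prpa"], ap, self.cfg.conflict
        )
        path = self.outdir / "ho_cd_enrichment.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["anchor", "orientation", "n", "mean", "sem"],
                [[c.anchor, c.orientation, c.n, c.mean, c.sem] for c in cells],
            )
        self._emit("ho_cd_enrichment", path)
        for c in cells:
            if c.orientation in ("HO", "CD"):
                self.summary.append(
                    (f"prpa_{c.anchor}_{c.orientation}_mean", _fmt(c.mean))
                )

        curve = cf.signal_vs_origin_distance(self.active, self.zones, ctl["prpa"], params=ap)
        path = self.outdir / "prpa_vs_origin_distance.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["dist_lo", "dist_hi", "n", "mean", "sem"],
                [list(b) for b in curve.bins],
            )
        self._emit("prpa_vs_origin_distance", path)
        self.summary.append(("origin_distance_excluded_genes", str(curve.excluded)))
        log.info("conflict stage in %.1fs", time.monotonic() - t0)

    # -- stage: dsb ----------------------------------------------------
    def stage_dsb(self):
        t0 = time.monotonic()
        ap = self.cfg.analysis
        ranking = dsbmod.rank_tts_dsb(self.tracks["shTop1"]["ibless"], self.active, ap)
        scores_ctl = pr.window_scores(
            self.tracks["control"]["ibless"].rpm(), self.active, "TTS", ap.tts_half_width
        )
        features = {
            g: (scores_ctl[g], ranking.scores[g]) for g in ranking.scores
        }
        self.dsb_classes = dsbmod.cluster_dsb_genes(features)
        path = self.outdir / "dsb_classification.tsv"
        if not self._skip(path):
            _write_tsv(
                path,
                ["gene_id", "label", "control_score", "shtop1_score", "top_fraction"],
                [
                    [
                        g,
                        self.dsb_classes.labels[g],
                        features[g][0],
                        features[g][1],
                        int(g in ranking.top_set),
                    ]
                    for g in sorted(features)
                ],
            )
        self._emit("dsb_classification", path)
        n_pos = len(self.dsb_classes.positives())
        self.summary.append(("dsb_positive_n", str(n_pos)))

        orientations = dsbmod.pair_orientation_labels(self.pairs)
        comp = dsbmod.orientation_composition(self.dsb_classes, orientations)
        for grp in ("DSB+", "DSB-"):
            for orient in ("HO", "CD"):
                self.summary.append(
                    (
                        f"{grp}_{orient}_pct".replace("+", "pos").replace("-", "neg"),
                        _fmt(comp.table[grp][orient]),
                    )
                )
        self.summary.append(("dsb_orientation_ztest_p", _fmt(comp.p_value)))

        ctl = self.tracks["control"]
        comparisons = dsbmod.group_signal_profiles(
            self.dsb_classes,
            {"drip": ctl["drip_ip"], "prpa": ctl["prpa"]},
            self.active,
            ap,
        )
        for name, c in comparisons.items():
            self.summary.append((f"dsb_group_{name}_ranksum_p", _fmt(c.p_value)))
        log.info("dsb stage in %.1fs (%d DSB+)", time.monotonic() - t0, n_pos)

    # -- driver --------------------------------------------------------
    def run(self) -> Path:
        self.load_inputs()
        self.stage_rfd()
        self.stage_peaks()
        self.stage_annotation()
        self.stage_profiles()
        self.stage_conflicts()
        self.stage_dsb()
        summary_path = self.outdir / "summary.tsv"
        with open(summary_path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in self.summary:
                fh.write(f"{k}\t{v}\n")
        self._emit("summary", summary_path)
        manifest_path = self.outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return summary_path


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Run the full analysis; returns the path to the summary report."""
    run = PipelineRun(config, resume=resume)
    return run.run()
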