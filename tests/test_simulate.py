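import json

import numpy as np
import pytest
from scipy import stats

from trcpipe.core import GeneRecord, GenomeLayout, Interval, anchor_of
from trcpipe.simulate import (
    SimConfig,
    SimTruth,
    simulate_genome,
    simulate_okseq,
    simulate_rfd_field,
    simulate_tracks,
    write_dataset,
)


def make_truth_with_rfd(rfd_values, seed=0, bin_size=1000, okseq_depth=500.0):
    """Minimal SimTruth carrying a hand-specified RFD field."""
    n = len(rfd_values)
    layout = GenomeLayout.from_dict({"chr1": n * bin_size})
    config = SimConfig(
        seed=seed, chrom_lengths=(n * bin_size,), bin_size=bin_size, okseq_depth=okseq_depth
    )
    return SimTruth(
        config=config,
        layout=layout,
        genes=[],
        origin_positions={"chr1": np.array([], dtype=np.int64)},
        origin_efficiencies={"chr1": np.array([])},
        rfd_true={"chr1": np.asarray(rfd_values, dtype=float)},
        s_true={},
        orientation_true={},
        dsb_positive=[],
        drip_bumps=[],
        prpa_bumps=[],
        converging_boosted=[],
        gh2ax_domains=[],
        ibless_sites=[],
    )


class TestRFDField:
    def test_single_certain_origin_gives_step(self):
        rng = np.random.default_rng(0)
        field = simulate_rfd_field(
            np.array([50_000]), np.array([1.0]), 100, 1000, 50, rng
        )
        assert np.all(field[:50] == -1.0)
        assert np.all(field[50:] == 1.0)

    def test_no_origins_gives_zero(self):
        rng = np.random.default_rng(0)
        assert np.all(simulate_rfd_field(np.array([]), np.array([]), 10, 1000, 10, rng) == 0)

    def test_range(self):
        rng = np.random.default_rng(1)
        field = simulate_rfd_field(
            np.array([10_000, 40_000, 80_000]),
            np.array([0.3, 0.6, 0.9]),
            100,
            1000,
            100,
            rng,
        )
        assert np.all(field >= -1.0) and np.all(field <= 1.0)


class TestSimulateGenome:
    def test_determinism(self):
        cfg = SimConfig(seed=11, n_genes=300, chrom_lengths=(8_000_000,))
        _, genes_a, truth_a = simulate_genome(cfg)
        _, genes_b, truth_b = simulate_genome(cfg)
        assert genes_a == genes_b
        assert np.array_equal(truth_a.rfd_true["chr1"], truth_b.rfd_true["chr1"])
        assert truth_a.dsb_positive == truth_b.dsb_positive
        assert truth_a.drip_bumps == truth_b.drip_bumps
        assert np.array_equal(
            truth_a.origin_positions["chr1"], truth_b.origin_positions["chr1"]
        )

    def test_different_seed_differs(self):
        a = simulate_genome(SimConfig(seed=1, n_genes=200, chrom_lengths=(6_000_000,)))
        b = simulate_genome(SimConfig(seed=2, n_genes=200, chrom_lengths=(6_000_000,)))
        assert a[1] != b[1]

    def test_genes_non_overlapping_and_sorted(self, sim_bundle):
        genes = sim_bundle["genes"]
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(SimConfig(n_genes=2_000, chrom_lengths=(1_000_000,)))

    def test_ho_fraction_positive(self, sim_bundle):
        truth = sim_bundle["truth"]
        ho = sum(1 for o in truth.orientation_true.values() if o["TTS"] == "HO")
        assert 0 < ho < len(truth.orientation_true)

    def test_converging_fraction_near_target(self, sim_bundle):
        genes = sim_bundle["genes"]
        conv = sum(
            1
            for a, b in zip(genes, genes[1:])
            if a.strand == "+" and b.strand == "-"
        )
        assert abs(conv / (len(genes) - 1) - 0.30) < 0.05

    def test_dsb_labels_subset_of_active(self, sim_bundle):
        truth = sim_bundle["truth"]
        assert set(truth.dsb_positive) <= set(truth.active_gene_ids())
        expected = round(0.25 * len(truth.active_gene_ids()))
        assert len(truth.dsb_positive) == expected

    def test_dsb_enriched_for_head_on(self, sim_bundle):
        truth = sim_bundle["truth"]
        dsb = set(truth.dsb_positive)
        ho_in_dsb = np.mean(
            [truth.orientation_true[g]["TTS"] == "HO" for g in dsb]
        )
        ho_overall = np.mean(
            [truth.orientation_true[g]["TTS"] == "HO" for g in truth.active_gene_ids()]
        )
        assert ho_in_dsb > ho_overall

    def test_origin_min_separation(self, sim_bundle):
        pos = sim_bundle["truth"].origin_positions["chr1"]
        assert np.all(np.diff(pos) >= sim_bundle["config"].origin_min_separation)

    def test_multi_chromosome(self):
        cfg = SimConfig(seed=3, n_genes=200, chrom_lengths=(5_000_000, 3_000_000))
        layout, genes, truth = simulate_genome(cfg)
        assert layout.names == ("chr1", "chr2")
        assert {g.chrom for g in genes} == {"chr1", "chr2"}


class TestSimulateOkseq:
    def test_pure_rightward_bin_has_no_watson(self):
        truth = make_truth_with_rfd([1.0] * 50, okseq_depth=200.0)
        counts = simulate_okseq(truth)
        assert np.all(counts.watson["chr1"] == 0)
        assert counts.crick["chr1"].sum() > 0

    def test_zero_depth_all_zero(self):
        truth = make_truth_with_rfd([0.5] * 20)
        counts = simulate_okseq(truth, depth=0.0)
        assert counts.watson["chr1"].sum() == 0
        assert counts.crick["chr1"].sum() == 0

    def test_balanced_bin_near_half(self):
        # binomial tail: at depth 1000 and RFD 0, crick/total is within
        # [0.45, 0.55] with probability >= 99.8% per bin
        truth = make_truth_with_rfd([0.0] * 200, seed=4, okseq_depth=1000.0)
        counts = simulate_okseq(truth)
        total = counts.watson["chr1"] + counts.crick["chr1"]
        frac = counts.crick["chr1"] / total
        assert np.mean((frac >= 0.45) & (frac <= 0.55)) >= 0.97

    def test_estimator_converges_to_truth(self):
        rng_field = np.random.default_rng(9)
        field = np.clip(rng_field.uniform(-1, 1, 300), -1, 1)
        truth = make_truth_with_rfd(field, seed=8, okseq_depth=500.0)
        counts = simulate_okseq(truth)
        w, c = counts.watson["chr1"].astype(float), counts.crick["chr1"].astype(float)
        est = (c - w) / (c + w)
        assert np.mean(np.abs(est - field)) < 0.05

    def test_determinism(self):
        truth = make_truth_with_rfd([0.2] * 30, seed=5)
        a, b = simulate_okseq(truth), simulate_okseq(truth)
        assert np.array_equal(a.watson["chr1"], b.watson["chr1"])
        assert np.array_equal(a.crick["chr1"], b.crick["chr1"])


class TestSimulateTracks:
    def test_zero_expression_gene_has_no_bump(self, sim_bundle):
        truth = sim_bundle["truth"]
        inactive = {g.gene_id for g in truth.genes if g.expression_rpkm == 0}
        assert not any(b.gene_id in inactive for b in truth.drip_bumps)
        assert not any(b.gene_id in inactive for b in truth.prpa_bumps)

    def test_control_break_tracks_background_only(self, sim_bundle):
        cfg = sim_bundle["config"]
        control = sim_bundle["control"]
        # Poisson background: all values must stay below an extreme quantile
        for name, bg in (("ibless", cfg.ibless_background), ("gh2ax", cfg.gh2ax_background)):
            vals = control[name].values["chr1"]
            bound = stats.poisson.ppf(1 - 1e-9, bg)
            assert vals.max() <= bound, name

    def test_shtop1_plants_break_signal(self, sim_bundle):
        cfg = sim_bundle["config"]
        sh = sim_bundle["shTop1"]
        truth = sim_bundle["truth"]
        iv = truth.ibless_sites[0]
        b0, b1 = iv.start // cfg.bin_size, (iv.end - 1) // cfg.bin_size
        inside = sh["ibless"].values[iv.chrom][b0 : b1 + 1].mean()
        assert inside > 10 * cfg.ibless_background

    def test_bump_centers_on_anchors(self, sim_bundle):
        truth = sim_bundle["truth"]
        by_id = {g.gene_id: g for g in truth.genes}
        for b in truth.drip_bumps[:200]:
            anchor = anchor_of(by_id[b.gene_id], b.anchor_kind)
            assert abs(b.center - anchor.position) <= truth.config.bin_size

    def test_prpa_bumps_only_at_head_on_tts(self, sim_bundle):
        truth = sim_bundle["truth"]
        for b in truth.prpa_bumps:
            assert b.anchor_kind == "TTS"
            assert truth.s_true[b.gene_id]["TTS"] < 0

    def test_determinism(self, sim_bundle):
        truth, cfg = sim_bundle["truth"], sim_bundle["config"]
        again = simulate_tracks(truth, cfg.replace(condition="control"))
        for name, track in sim_bundle["control"].items():
            assert np.array_equal(track.values["chr1"], again[name].values["chr1"])

    def test_no_planted_signal_outside_declared_intervals(self):
        # mask all declared footprints; what remains must look like background
        cfg = SimConfig(seed=6, n_genes=300, chrom_lengths=(8_000_000,))
        _, _, truth = simulate_genome(cfg)
        tracks = simulate_tracks(truth, cfg.replace(condition="shTop1"))
        bs = cfg.bin_size
        n = truth.layout.n_bins("chr1", bs)
        keep = np.ones(n, dtype=bool)
        for b in truth.drip_bumps:
            keep[max(0, (b.interval.start - 2000) // bs) : (b.interval.end + 2000) // bs + 1] = False
        vals = tracks["drip_ip"].values["chr1"][keep]
        bound = stats.poisson.ppf(1 - 1e-8, cfg.drip_background)
        assert np.quantile(vals, 0.999) <= bound


class TestWriteDataset:
    def test_manifest_and_truth_json(self, tmp_path):
        cfg = SimConfig(seed=2, n_genes=50, chrom_lengths=(2_000_000,))
        _, _, truth = simulate_genome(cfg)
        manifest = write_dataset(truth, tmp_path / "ds")
        for path in manifest.values():
            assert (tmp_path / "ds").exists()
        with open(manifest["truth"]) as fh:
            doc = json.load(fh)
        assert doc["config"]["seed"] == 2
        assert len(doc["rfd_true"]["chr1"]) == 2_000
        assert set(doc["dsb_positive"]) == set(truth.dsb_positive)
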