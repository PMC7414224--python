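import math

import numpy as np
import pytest
from scipy import stats

from trcpipe.core import GeneRecord, GenomeLayout, Interval, overlap_query
from trcpipe.enrichment import (
    CATEGORIES,
    Peak,
    PeakCallConfig,
    annotate_peaks,
    broad_domain_width,
    call_peaks,
    gene_peak_overlap,
    reproducible_peaks,
)

from .conftest import make_track


def poisson_upper_tail_oracle(x, lam, terms=400):
    """Independent Poisson tail P(X >= x) by direct series summation."""
    # sum pmf from x upward in log space
    total = 0.0
    for k in range(x, x + terms):
        log_pmf = -lam + k * math.log(lam) - math.lgamma(k + 1)
        total += math.exp(log_pmf)
    return total


class TestPoissonCalling:
    def test_extreme_bin_significant(self, small_layout):
        # one bin of 50 against flat input of 5
        ip_vals = np.full(100, 5.0)
        ip_vals[40] = 50.0
        ip_vals[41] = 45.0
        ip = make_track(small_layout, {"chr1": ip_vals})
        inp = make_track(small_layout, {"chr1": np.full(100, 5.0)})
        oracle_p = poisson_upper_tail_oracle(50, 5.0)
        assert oracle_p < 1e-15
        peaks = call_peaks(ip, inp, PeakCallConfig())
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 40_000 < peaks[0].interval.end
        assert peaks[0].summit == 40_500
        assert peaks[0].q_value < 1e-10

    def test_bh_q_monotone_and_above_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        q = stats.false_discovery_control(p, method="bh")
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_all_zero_tracks_give_empty(self, small_layout):
        zero = make_track(small_layout, {"chr1": np.zeros(100)})
        assert call_peaks(zero, zero) == []

    def test_zero_input_nonzero_ip_rejected(self, small_layout):
        ip = make_track(small_layout, {"chr1": np.full(100, 5.0)})
        zero = make_track(small_layout, {"chr1": np.zeros(100)})
        with pytest.raises(ValueError):
            call_peaks(ip, zero)

    def test_null_tracks_rarely_give_peaks(self):
        layout = GenomeLayout.from_dict({"chr1": 20_000_000})
        zero_count = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ip = make_track(layout, {"chr1": rng.poisson(5.0, 20_000).astype(float)})
            inp = make_track(layout, {"chr1": rng.poisson(5.0, 20_000).astype(float)})
            zero_count += len(call_peaks(ip, inp)) == 0
        assert zero_count >= 4

    def test_min_width_drops_single_bins(self, small_layout):
        ip_vals = np.full(100, 5.0)
        ip_vals[10] = 80.0  # isolated single-bin spike
        ip = make_track(small_layout, {"chr1": ip_vals})
        inp = make_track(small_layout, {"chr1": np.full(100, 5.0)})
        peaks = call_peaks(ip, inp, PeakCallConfig(min_width=2))
        assert peaks == []
        peaks1 = call_peaks(ip, inp, PeakCallConfig(min_width=1))
        assert len(peaks1) == 1

    def test_recall_on_planted_bumps(self, sim_bundle):
        cfg = sim_bundle["config"]
        tracks = sim_bundle["control"]
        peaks = call_peaks(tracks["drip_ip"], tracks["drip_input"])
        strong = [
            b for b in sim_bundle["truth"].drip_bumps
            if b.amplitude >= 3 * cfg.drip_background
        ]
        hits = overlap_query([b.interval for b in strong], [p.interval for p in peaks])
        recall = len({qi for qi, _ in hits}) / len(strong)
        assert recall >= 0.9
        all_bumps = [b.interval for b in sim_bundle["truth"].drip_bumps]
        matched = overlap_query([p.interval for p in peaks], all_bumps)
        unmatched_frac = 1 - len({qi for qi, _ in matched}) / len(peaks)
        assert unmatched_frac <= 0.1


def peak(chrom, start, end, q=0.01):
    return Peak(Interval(chrom, start, end), (start + end) // 2, 2.0, q)


class TestReproduciblePeaks:
    def test_identical_replicates(self):
        reps = [peak("chr1", 0, 1000), peak("chr1", 5000, 7000)]
        consensus = reproducible_peaks([reps, list(reps)])
        assert [p.interval for p in consensus] == [p.interval for p in reps]

    def test_disjoint_replicates_empty(self):
        a = [peak("chr1", 0, 1000)]
        b = [peak("chr1", 5000, 6000)]
        assert reproducible_peaks([a, b]) == []

    def test_jittered_replicates_all_retained(self):
        rng = np.random.default_rng(1)
        a = [peak("chr1", s, s + 2000) for s in range(5_000, 55_000, 5_000)]
        jitter = rng.integers(-400, 400, len(a))  # < 25% of width
        b = [
            peak("chr1", p.interval.start + int(d), p.interval.end + int(d))
            for p, d in zip(a, jitter)
        ]
        consensus = reproducible_peaks([a, b])
        assert len(consensus) == len(a)
        for c, pa, pb in zip(consensus, a, b):
            assert c.interval.start == max(pa.interval.start, pb.interval.start)
            assert c.interval.end == min(pa.interval.end, pb.interval.end)

    def test_replicate_count_limits(self):
        a = [peak("chr1", 0, 1000)]
        with pytest.raises(ValueError):
            reproducible_peaks([a])
        with pytest.raises(ValueError):
            reproducible_peaks([a] * 6)
        assert len(reproducible_peaks([a] * 5)) == 1


class TestAnnotatePeaks:
    @pytest.fixture
    def layout(self):
        return GenomeLayout.from_dict({"chr1": 200_000})

    @pytest.fixture
    def genes(self):
        return [GeneRecord("g1", Interval("chr1", 50_000, 70_000), "+", 1.0)]

    def test_summit_upstream_of_tss(self, layout, genes):
        peaks = [peak("chr1", 48_500, 49_500)]  # summit 49_000, 1 kb upstream
        fractions, cats, baseline = annotate_peaks(peaks, genes, layout=layout)
        assert cats == ["TSS_region"]
        assert fractions["TSS_region"] == 1.0

    def test_summit_past_tts(self, layout, genes):
        peaks = [peak("chr1", 71_500, 72_500)]  # summit 72_000, 2 kb past TTS
        _, cats, _ = annotate_peaks(peaks, genes, layout=layout)
        assert cats == ["TTS_region"]

    def test_gene_body(self, layout, genes):
        peaks = [peak("chr1", 59_500, 60_500)]
        _, cats, _ = annotate_peaks(peaks, genes, layout=layout)
        assert cats == ["gene_body"]

    def test_gene_desert_and_fractions_sum(self, layout, genes):
        peaks = [
            peak("chr1", 150_000, 151_000),
            peak("chr1", 48_500, 49_500),
        ]
        fractions, cats, baseline = annotate_peaks(peaks, genes, layout=layout)
        assert cats[0] == "intergenic"
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert sum(baseline.values()) == pytest.approx(1.0)
        assert baseline["intergenic"] > 0.5  # mostly gene desert

    def test_minus_strand_regions(self, layout):
        genes = [GeneRecord("g1", Interval("chr1", 50_000, 70_000), "-", 1.0)]
        # 1 kb beyond the right end = upstream of the minus-strand TSS
        _, cats, _ = annotate_peaks([peak("chr1", 70_500, 71_500)], genes, layout=layout)
        assert cats == ["TSS_region"]
        _, cats, _ = annotate_peaks([peak("chr1", 47_500, 48_500)], genes, layout=layout)
        assert cats == ["TTS_region"]


class TestGenePeakOverlap:
    def test_half_positive(self):
        genes = [
            GeneRecord(f"g{i}", Interval("chr1", i * 10_000, i * 10_000 + 5_000), "+")
            for i in range(4)
        ]
        peaks = [peak("chr1", 1_000, 2_000), peak("chr1", 11_000, 12_000)]
        labels, _ = gene_peak_overlap(genes, {"a": peaks})
        assert labels["a"] == {"g0", "g1"}

    def test_subset_percentages(self):
        genes = [
            GeneRecord(f"g{i}", Interval("chr1", i * 10_000, i * 10_000 + 5_000), "+")
            for i in range(4)
        ]
        peaks_a = [peak("chr1", 1_000, 2_000)]
        peaks_b = [peak("chr1", 1_000, 2_000), peak("chr1", 11_000, 12_000)]
        labels, pct = gene_peak_overlap(genes, {"a": peaks_a, "b": peaks_b})
        assert labels["a"] <= labels["b"]
        assert pct[("a", "b")] == 100.0
        assert pct[("b", "a")] == 50.0

    def test_jaccard_with_planted_active_genes(self, sim_bundle):
        tracks = sim_bundle["control"]
        peaks = call_peaks(tracks["drip_ip"], tracks["drip_input"])
        labels, _ = gene_peak_overlap(sim_bundle["genes"], {"drip": peaks})
        active = set(sim_bundle["truth"].active_gene_ids())
        pos = labels["drip"]
        jaccard = len(pos & active) / len(pos | active)
        assert jaccard >= 0.85


class TestBroadDomainWidth:
    def test_single_run(self, small_layout):
        vals = np.zeros(100)
        vals[10:40] = 5.0
        track = make_track(small_layout, {"chr1": vals})
        assert broad_domain_width(track, 1.0, merge_gap=0) == [30_000]

    def test_two_runs_beyond_merge_gap(self, small_layout):
        vals = np.zeros(100)
        vals[10:20] = 5.0
        vals[30:45] = 5.0
        track = make_track(small_layout, {"chr1": vals})
        assert broad_domain_width(track, 1.0, merge_gap=2_000) == [10_000, 15_000]

    def test_merge_across_small_gap(self, small_layout):
        vals = np.zeros(100)
        vals[10:20] = 5.0
        vals[21:30] = 5.0
        track = make_track(small_layout, {"chr1": vals})
        assert broad_domain_width(track, 1.0, merge_gap=1_000) == [20_000]

    def test_gh2ax_width_recovery_sparse(self):
        from trcpipe.simulate import SimConfig, simulate_genome, simulate_tracks

        cfg = SimConfig(seed=3, dsb_fraction=0.05)
        _, _, truth = simulate_genome(cfg)
        sh = simulate_tracks(truth, cfg.replace(condition="shTop1"))
        mean = sh["gh2ax"].total() / sh["gh2ax"].n_bins_total()
        widths = broad_domain_width(sh["gh2ax"].scaled(1 / mean), 2.0, merge_gap=2_000)
        assert widths
        median = float(np.median(widths))
        assert abs(median - cfg.gh2ax_domain_width) <= 0.2 * cfg.gh2ax_domain_width
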