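# trcpipe

Analysis pipeline for transcription–replication conflicts on binned
genomic tracks: replication fork direction (RFD) from stranded
Okazaki-fragment counts, initiation-zone detection, head-on (HO) vs
codirectional (CD) orientation calls at gene anchors, Poisson
local-background peak calling with BH q-values, TSS/TTS metaprofiles and
quintile-stratified heatmaps, gene-pair geometry statistics, and
DSB-positive gene classification from break-end sequencing signal — plus
a fully seeded synthetic multi-omics generator with planted ground truth
so the whole pipeline runs and is validated without any external data.

## Layout

| module | contents |
| --- | --- |
| `trcpipe.core` | genome layout, intervals, gene records, TSS/TTS anchors, overlap engine, BED/chrom-sizes I/O |
| `trcpipe.tracks` | binned `SignalTrack`, bedGraph I/O, RPKM, IP/input normalization, active-gene filter, expression quintiles |
| `trcpipe.replication` | RFD = (C − W)/(C + W), initiation zones, HO/CD orientation, downstream-origin distance |
| `trcpipe.enrichment` | Poisson local-λ peak caller, replicate reproducibility filter, peak annotation, gene/peak overlap, broad-domain widths |
| `trcpipe.profiles` | scaled-gene and anchor-window metaprofiles with SEM, window quantification, sorted TTS heatmaps |
| `trcpipe.conflicts` | converging/codirectional/divergent pair classification, gap/expression/orientation/origin-distance stratified statistics |
| `trcpipe.dsb` | TTS break-signal ranking, hierarchical DSB+/DSB− clustering, rank-sum comparisons, orientation composition |
| `trcpipe.simulate` | seeded genome/origin/track generator with planted truth (`SimTruth`) |
| `trcpipe.pipeline` / `trcpipe.cli` | orchestration, config, manifest, summary report |

## CLI

```sh
# generate a synthetic dataset (both conditions + truth.json)
trcpipe simulate --outdir data --seed 1

# RFD + initiation zones from stranded Okazaki bin counts
trcpipe rfd --okseq data/okseq.tsv --chrom-sizes data/chrom.sizes --outdir rfd_out

# peak calling from IP/input bedGraphs
trcpipe callpeaks --ip data/drip_ip.control.bedgraph \
    --input data/drip_input.control.bedgraph \
    --chrom-sizes data/chrom.sizes --out peaks.bed

# full pipeline (simulate mode); writes tables, summary.tsv, manifest.json
trcpipe all --outdir run1 --seed 1
# or with a YAML config (see PipelineConfig for the keys)
trcpipe all --config config.yaml --resume
```

A minimal config:

```yaml
outdir: run1
seed: 1
simulate: {}            # or an `inputs:` block with file paths
analysis:
  converging_gap_threshold: 5000
  tts_half_width: 2000
  flank: 10000
  top_fraction: 0.25
peaks:
  q_threshold: 0.05
```

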