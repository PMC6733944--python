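# pol3prox

Occupancy profiling and feature-proximity statistics for RNA polymerase
III-transcribed genes.

## The problem

tRNA genes are short (~100 bp), pol III-transcribed, and often sit in
intergenic space close to pol II gene ends, replication origins and TAD
boundaries. Asking where a chromatin factor sits on these genes — and
whether the genes themselves cluster near genomic landmarks — needs a
small set of careful operations:

- **Strand-aware metagene profiles.** Given near-base-pair positional tag
  counts (ChIP-exo style, forward/reverse channels summed), the average
  occupancy at each gene-oriented offset `k ∈ [−flank, +flank]` around the
  TSS across a gene set, with minus-strand genes read right-to-left. A
  confound filter removes tRNAs that have pol II gene ends within a window
  on both (or either) side, and an ORF-density profile counts same-strand
  ORF ends in 100 bp windows around the tRNA body.
- **Feature-proximity enrichment.** Points (tRNA TSSs, ORF TSSs as
  control, or per-position tag weights) are aggregated into signed-distance
  bins `[−max_dist, +max_dist)` around each replication origin or TAD
  boundary. Curves are per-bin means across features, normalized by the
  total point count. Significance is a two-tailed pooled-variance Student's
  t-test contrasting the per-feature means of feature-proximal bins against
  feature-distal bins:

      t = (x̄_prox − x̄_dist) / √(s_p² (1/n + 1/n)),  df = 2n − 2

  with proximal/distal windows of ±0.5 kb vs ±2.5 kb for TAD boundaries
  and ±1.5 kb vs ±5 kb for origins.
- **The qPCR fold enrichment method.** With amplification efficiency `E`
  and `ΔCt_s = Ct_s(gene) − Ct_s(TelVIR)` for sample kinds IP, mock and
  input (TelVIR is the subtelomeric control region):

      FE = E^−(ΔCt_IP − ΔCt_input) / E^−(ΔCt_mock − ΔCt_input)

- **Count-table comparison.** Counts-per-million normalization of tRNA
  abundance tables with log2(+pseudocount) values and per-gene fold
  changes, plus band-intensity normalization for blots.
- **A simulator with planted truth.** Synthetic multi-chromosome genomes
  with a tunable fraction of tRNAs co-localized to features, tag tracks
  with Poisson background and sharp per-gene peaks at a configurable TSS
  offset (default −10 bp), Ct tables that invert exactly to known fold
  enrichments, and multinomial count tables — so every pipeline stage is
  testable end to end without any external download.

## Worked example

```python
from pol3prox import (SimulationConfig, simulate_genome, simulate_tag_track,
                      compute_profile, run_proximity_analysis)

config = SimulationConfig(seed=7, colocalization_fraction=0.5,
                          colocalization_dist=500,
                          colocalization_feature="tad_boundaries")
sim = simulate_genome(config)
track = simulate_tag_track(sim, config)

profile = compute_profile(track, sim.trnas, flank=300)
print(profile.peak_offset)          # -10

report = run_proximity_analysis(sim.trnas,
                                [sim.feature_sets["tad_boundaries"],
                                 sim.feature_sets["origins"]],
                                orfs=sim.orfs)
for key, res in sorted(report.tests.items()):
    print(key, f"t={res.t_statistic:.3f} p={res.p_value:.3g}")
```

prints

```
('origins', 'orf_tss') t=1.101 p=0.277
('origins', 'trna_tss') t=-0.370 p=0.713
('tad_boundaries', 'orf_tss') t=-1.952 p=0.0546
('tad_boundaries', 'trna_tss') t=9.088 p=7.29e-14
```

Half of the 150 tRNAs were planted within 500 bp of a TAD boundary, and
only that combination is called enriched (p ≈ 7e-14); the uniformly
placed ORF control and the untargeted origins stay flat. The metagene
profile recovers the planted −10 bp peak exactly. More narrative runs
live in `examples/` (one script per capability), and a thin CLI covers
the same stages from a shell:

```sh
pol3prox simulate --config sim.yaml --out fixtures/
pol3prox metagene --track fixtures/tags.tab --genes fixtures/trna.bed \
    --chrom-sizes fixtures/chrom.sizes --flank 300 --out profile/
pol3prox proximity --genes fixtures/trna.bed --control-genes fixtures/orf.bed \
    --features fixtures/tad_boundaries.bed --chrom-sizes fixtures/chrom.sizes \
    --out report/
```

## Layout

- `src/pol3prox/annotations.py` — genomes, gene records, point features,
  BED/table IO, distance and proximity-subset operations
- `src/pol3prox/track_io.py` — tag tables, bedGraph, Ct tables, count tables
- `src/pol3prox/metagene.py` — profiles, heatmap matrices, confound filter,
  ORF density, windowed means, Pearson r
- `src/pol3prox/proximity.py` — distance binning, curve normalization,
  proximal/distal t-test, end-to-end report
- `src/pol3prox/quantify.py` — fold enrichment method, condition ratios,
  band ratios, count normalization
- `src/pol3prox/simulate.py` — the planted-truth generator
- `src/pol3prox/cli.py` — the `pol3prox` command
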