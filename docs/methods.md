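# Methods

## Coordinate model

Internal coordinates are 0-based half-open everywhere. A gene's TSS is
`start` on the plus strand and `end − 1` on the minus strand; the TTS is
symmetric. BED files are read and written untranslated; tab-delimited
annotation tables are documented as 1-based inclusive and shifted on
read. Point features (replication origins, TAD boundaries) are
unstranded; interval-shaped sources are collapsed to the floor of the
mean of their endpoints before storage, the least-assuming reduction of
an interval to a reference point.

Two orientation conventions coexist deliberately. Metagene profiles, ORF
density and windowed means are **gene-oriented**: offsets follow the
direction of transcription, so minus-strand genes are read right-to-left
and "upstream" always means upstream of the TSS. Proximity analysis is
**genome-oriented**: features are unstranded, distances are
`point − feature` in chromosome coordinates, and the enrichment curves
aggregate both directions without flipping.

"Within d" is closed (|distance| ≤ d) wherever a proximity subset is
taken, and is measured from the TSS by default (an `edge` mode measures
from the nearer gene boundary instead; which anchor published gene
counts used is generally not recoverable from figure legends, so both
are exposed and the TSS is the documented default).

## Metagene profiling

`compute_profile` averages the collapsed (forward + reverse) tag count
at each gene-oriented offset in `[−flank, +flank]` (default flank
300 bp; offset 0 is the TSS base itself, so a window has `2·flank + 1`
positions). Genes whose window would cross a chromosome end are excluded
and logged — profile rows must have equal length — whereas the
single-gene `mean_window_occupancy` truncates at the bounds instead,
because a lone mean does not need row alignment. Profiles average raw
tag counts by default; per-million depth normalization is a flag, since
averaged deposited tracks may be either and the choice only rescales the
curve.

The pol II confound filter removes a tRNA when a pol II gene boundary
coordinate lies within `window` bp (default 300) of its gene body on
both sides (`both_sides`, the default) or on at least one side
(`either_side`). Both modes exist because one-sided proximity is the
stricter reading and the intended one is not decidable from prose; the
default removes only doubly-flanked genes, and `both_sides` output is
always a superset of `either_side` output.

ORF density assigns each (tRNA, ORF) pair to the window containing the
ORF's proximal boundary coordinate — point assignment, not interval
overlap — in gene-oriented 100 bp windows out to 1 kb, optionally
restricted to same-strand ORFs. Window totals are therefore conserved:
their sum equals the number of pairs whose proximal end lies within the
span.

Heatmap matrices pool flank regions at a fixed bin size and rescale the
gene body into a fixed number of bins by mean pooling; bodies shorter
than the bin count are linearly interpolated (logged). Row ordering
(descending row sum) and any color scaling are presentation defaults and
carry no analytical weight.

## Proximity enrichment and the proximal/distal test

`relative_bin_counts` adds each point's weight to the signed-distance
bin of every feature within `max_dist` on its chromosome (no
nearest-feature assignment — a point near two features counts for both,
which makes total mass checkable by conservation). Bins are half-open
`[lo, hi)`, tile `[−max_dist, +max_dist)`, and distance 0 falls in the
first non-negative bin. TSS signals use 1 kb bins; tag tracks use 100 bp
bins, with per-position collapsed tag counts as weights. Curves are
per-bin means across features, then divided by the total point count of
the signal (e.g. the tRNA and ORF TSS totals) to put curves from
differently sized point sets on one scale; a pooled mode (summing across
features before normalizing) exists as an alternative reading, but
column-mean-then-normalize is the default.

The test contrasts, per feature, the mean of bins overlapping
`[−h, +h)` (proximal) against the mean of the bin pair at ±`d` (distal),
with (h, d) = (0.5 kb, 2.5 kb) for TAD boundaries and (1.5 kb, 5 kb) for
origins — a narrow contrast where enrichment is narrow, a broad one
where it is broad. The distal pair is selected by nearest bin center
with ties resolved outward: identical to "the bin containing ±d"
whenever d is interior to a bin, and, unlike the containing-bin rule,
mirror-symmetric when d lands exactly on a bin edge (so reflecting the
genome provably leaves t and p unchanged). A `beyond` mode widens distal
to all bins at least d out.

The two per-feature vectors go into a two-tailed unpaired Student's
t-test with pooled variance (n = feature count on each side; Welch is
not the default because the pooled form is the convention this analysis
follows). Degenerate inputs are defined: two constant equal vectors give
t = 0, p = 1; zero pooled variance with unequal means raises rather than
fabricating an infinite statistic. An alternative `bin_means` mode tests
cross-feature bin means (n = bin count); it is exposed but not default —
features are the defensible sampling unit.

Calibration and power of this test are measured, not assumed: under
uniform tRNA placement the rejection rate at α = 0.05 over 1,000
simulated genomes stays within ±2 points of nominal, and a planted 50%
co-localization within 500 bp is detected at p < 0.01 in ≥ 90% of
replicates (both recomputed by the test suite and the acceptance
script). The per-feature bin counts are small Poisson-like values, so
nominal coverage relies on the two groups sharing a distribution under
the null — which they do by construction — rather than on normality.

## qPCR fold enrichment

`ΔCt_s = Ct_s(gene) − Ct_s(TelVIR)` for s ∈ {IP, mock, input};
`FE = E^−(ΔCt_IP − ΔCt_input) / E^−(ΔCt_mock − ΔCt_input)`. The
efficiency E defaults to 2.0 (perfect doubling) with an override, since
reaction efficiencies are rarely reported alongside Ct tables. Mock
normalization is a division on the fold scale (the standard
exponentiated-ΔΔCt reading of "normalized against mock") and is applied
per replicate, then replicates are aggregated as an arithmetic mean with
min/max scatter (SD available). Two algebraic identities pin the
implementation down and are asserted over random tables: adding a
constant to every Ct of one sample kind leaves FE unchanged, and one
fewer IP cycle for the gene exactly doubles it. Note the input terms
cancel algebraically in the ratio; they are retained in the formula (and
required in the table) because the two normalization steps are the
method's definition, and the table invariant catches incomplete runs.
Changes with p > 0.05 are flagged non-significant in tabular output.

Count tables are normalized per-million per column with a pseudocount of
1 before log2 — a deliberately plain library-size normalization standing
in for pipeline-specific processing that count depositions do not
document; it preserves within-sample rank order and is stated as such,
not inferred intent.

## The simulator

The generator emulates the study conditions at desk scale: 4 chromosomes
of 400 kb, 150 tRNA genes of 70–120 bp, 600 ORFs of 500–2,000 bp
(≈ 47% ORF coverage), 25 origins and 40 TAD boundaries placed uniformly.
The tRNA density is higher than a real small eukaryotic genome's so that
1 kb bins around a few dozen features see usable counts; the geometry
(short genes, intergenic placement, non-overlap) is what matters for the
operations under test. Placement is rejection sampling against occupied
intervals; a genome too full to place a gene raises rather than
overlapping silently.

`colocalization_fraction` f plants exactly `round(f · n_trna)` tRNA TSSs
within `colocalization_dist` (default 500 bp) of a target feature
(uniform over ± the distance around a uniformly chosen feature). When
f > 0 the remaining tRNAs are rejection-sampled to stay farther away, so
the planted count is exact; **f = 0 means fully uniform placement** —
some TSSs will land near features by chance, which is precisely the
clean null the calibration experiments need. The two regimes differ
because "exactly zero near features" is not a null, it is depletion.

Tag tracks are Poisson background (0.01 tags/bp) plus, per tRNA, a
Poisson(50)-sized bundle of tags at gene-oriented offsets drawn from
Normal(−10, 2) around the TSS, rounded to integer positions and split
evenly between forward and reverse channels. The peak sd of 2 bp makes
the peak single-base-resolvable, matching the near-base-pair resolution
exonuclease trimming produces; a broad peak (sd ≳ 10 bp) would make
per-bp argmax recovery a coin toss at realistic depths because adjacent
offsets differ by far less than Poisson noise.

Ct tables are constructed so the fold enrichment method inverts them
exactly at zero noise (gene IP Ct offset by −log_E(fold) from a fixed
baseline; input and mock flat), then perturbed by independent
Normal(0, 0.2)-cycle noise. Count tables are multinomial draws at fixed
library sizes from per-sample relative abundance vectors. A single
global seed feeds a per-component seed sequence, so the genome, track,
Ct and count generators are independently reproducible.

## Problem sizes

The default test and acceptance workloads use the sizes above; the
calibration study runs 1,000 genomes without ORFs (the null statistic
only needs tRNAs and features), power uses 100 replicates, peak recovery
50 tracks, and qPCR recovery 200 simulations of 6 replicates — enough
for the Monte-Carlo error on each reported rate to sit well inside its
stated band.

## What the synthetic data does not show

The generator plants ideal structure: uniform feature placement, a
single Gaussian peak shape, independent Poisson background, noise-free
strand balance, and Ct noise that is i.i.d. normal. Real tracks have
mappability holes, copy-number structure, correlated background,
antibody-specific peak shapes and replication-timing gradients; real
qPCR noise is heteroscedastic. Passing tests therefore demonstrate that
the operations compute what they claim on data with known truth — not
that any biological dataset satisfies these assumptions. Analyses of
real depositions should treat the confound filter and the ORF control
curve as the first sanity checks, exactly as the synthetic end-to-end
run does.

## Known limitations

- No BAM/FASTQ ingestion; the pipeline starts from processed positional
  counts, and no read-level simulation is provided.
- No profile smoothing, no nucleosome calling, no whole-genome
  permutation framework for overlap testing (the permutation null
  appears only as a test oracle for the t-based contrast).
- tRNA introns are ignored; gene bodies are plain intervals.
- The heatmap operation computes matrices only; plotting aesthetics are
  out of scope.
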