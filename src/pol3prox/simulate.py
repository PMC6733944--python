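"""Synthetic-data generator with known planted parameters.

Produces multi-chromosome genomes carrying tRNA genes, ORFs, replication
origins and TAD boundaries (with a tunable planted co-localization
fraction), ChIP-exo-style tag tracks with Poisson background plus sharp
per-gene peaks at a configurable TSS offset (default -10 bp), qPCR Ct
tables consistent with known true fold enrichments, and multinomial
count tables with known abundance ratios.  Every generator is a pure
function of its configuration (which includes the seed), so each
pipeline stage can be tested against planted truth without downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotations import FeatureSet, GeneRecord, Genome
from .track_io import TELVIR, CountTable, CtTable, TagTrack

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


# component indices for the per-component seed sequence
_COMPONENTS = {"genome": 0, "track": 1, "ct": 2, "counts": 3}


def _rng(seed: int, component: str) -> np.random.Generator:
    """Per-component generator so components regenerate independently."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _COMPONENTS[component]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Planted parameters for all synthetic artifacts.

    The genome is a desk-scale stand-in for a small eukaryotic genome:
    a few hundred-kb chromosomes with dense tRNA placement so binned
    statistics see usable counts.  ``colocalization_fraction`` is the
    share of tRNAs planted within ``colocalization_dist`` of a feature
    (0 means fully uniform placement); ``colocalization_feature`` names
    the target feature set, or None for the union of all sets.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 400_000
    n_trna: int = 150
    n_orf: int = 600
    n_origins: int = 25
    n_tad_boundaries: int = 40
    colocalization_fraction: float = 0.0
    colocalization_dist: int = 500
    colocalization_feature: str | None = None
    trna_length: tuple[int, int] = (70, 120)
    orf_length: tuple[int, int] = (500, 2000)
    peak_offset: int = -10
    peak_sigma: float = 2.0
    peak_amplitude_mean: float = 50.0
    background_rate: float = 0.01
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    true_fold: dict[str, float] = field(default_factory=lambda: {"gene_A": 4.0, "gene_B": 1.0})
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {"WT": 500_000, "mutant": 500_000}
    )
    true_abundances: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.colocalization_fraction <= 1.0:
            raise SimulationError("colocalization_fraction must be in [0, 1]")
        for name in ("chrom_length", "colocalization_dist"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        for name in ("peak_sigma", "peak_amplitude_mean", "background_rate", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for name in ("n_chroms", "n_trna", "n_orf", "n_origins", "n_tad_boundaries"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


@dataclass
class SimulatedGenome:
    """Genome + annotations + features + the planted truth record."""

    genome: Genome
    trnas: list[GeneRecord]
    orfs: list[GeneRecord]
    feature_sets: dict[str, FeatureSet]
    colocalized_trna_ids: list[str]


def _place_gene(
    rng: np.random.Generator,
    genome: Genome,
    occupied: dict[str, list[tuple[int, int]]],
    length: int,
    tss_sampler,
    max_tries: int = 2000,
) -> tuple[str, int, int, str]:
    """Rejection-sample a non-overlapping placement; tss_sampler yields
    (chrom, tss, strand) proposals."""
    for _ in range(max_tries):
        chrom, tss, strand = tss_sampler(rng)
        clen = genome.length(chrom)
        start = tss if strand == "+" else tss - length + 1
        end = start + length
        if start < 0 or end > clen:
            continue
        if any(s < end and start < e for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((start, end))
        return chrom, start, end, strand
    raise SimulationError(
        "genome too small to place requested genes without overlap"
    )


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate a genome with planted tRNA/feature co-localization.

    Exactly ``round(colocalization_fraction * n_trna)`` tRNA TSSs are
    placed within ``colocalization_dist`` of a target feature; when the
    fraction is positive the remaining tRNAs are kept farther away so the
    planted count is exact, while fraction 0 means fully uniform
    placement (a clean null for calibration).
    """
    rng = _rng(config.seed, "genome")
    genome = Genome(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    chrom_names = genome.chrom_names

    def uniform_point(r: np.random.Generator) -> tuple[str, int]:
        c = chrom_names[r.integers(len(chrom_names))]
        return c, int(r.integers(genome.length(c)))

    feature_sets: dict[str, FeatureSet] = {}
    for name, count in (
        ("origins", config.n_origins),
        ("tad_boundaries", config.n_tad_boundaries),
    ):
        pairs = [uniform_point(rng) for _ in range(count)]
        feature_sets[name] = FeatureSet.from_pairs(name, pairs)

    if config.colocalization_feature is not None:
        if config.colocalization_feature not in feature_sets:
            raise SimulationError(
                f"unknown colocalization_feature {config.colocalization_feature!r}"
            )
        targets = list(feature_sets[config.colocalization_feature].iter_points())
    else:
        targets = [p for fs in feature_sets.values() for p in fs.iter_points()]
    target_by_chrom = {
        c: np.array([p for cc, p in targets if cc == c], dtype=np.int64)
        for c in chrom_names
    }

    def min_target_dist(chrom: str, pos: int) -> float:
        arr = target_by_chrom.get(chrom)
        if arr is None or arr.size == 0:
            return np.inf
        return float(np.min(np.abs(arr - pos)))

    n_coloc = int(round(config.colocalization_fraction * config.n_trna))
    if n_coloc > 0 and not targets:
        raise SimulationError("cannot plant co-localization without features")

    occupied: dict[str, list[tuple[int, int]]] = {}
    trnas: list[GeneRecord] = []
    coloc_ids: list[str] = []
    lo, hi = config.trna_length

    def coloc_sampler(r: np.random.Generator):
        chrom, fpos = targets[r.integers(len(targets))]
        tss = int(fpos + r.integers(-config.colocalization_dist, config.colocalization_dist + 1))
        return chrom, tss, "+-"[r.integers(2)]

    def distal_sampler(r: np.random.Generator):
        for _ in range(1000):
            chrom, pos = uniform_point(r)
            if (
                config.colocalization_fraction == 0.0
                or min_target_dist(chrom, pos) > config.colocalization_dist
            ):
                return chrom, pos, "+-"[r.integers(2)]
        raise SimulationError("could not place tRNA away from features")

    for i in range(config.n_trna):
        length = int(rng.integers(lo, hi + 1))
        sampler = coloc_sampler if i < n_coloc else distal_sampler
        # re-propose until the planted-side constraint holds post-placement
        for _ in range(2000):
            chrom, start, end, strand = _place_gene(rng, genome, occupied, length, sampler)
            tss = start if strand == "+" else end - 1
            d = min_target_dist(chrom, tss)
            ok = (
                d <= config.colocalization_dist
                if i < n_coloc
                else (config.colocalization_fraction == 0.0 or d > config.colocalization_dist)
            )
            if ok:
                break
            occupied[chrom].remove((start, end))
        else:
            raise SimulationError("could not satisfy co-localization constraint")
        gid = f"tRNA_{i + 1:04d}"
        trnas.append(GeneRecord(gid, chrom, start, end, strand, "tRNA"))
        if i < n_coloc:
            coloc_ids.append(gid)

    orfs: list[GeneRecord] = []
    olo, ohi = config.orf_length

    def orf_sampler(r: np.random.Generator):
        chrom, pos = uniform_point(r)
        return chrom, pos, "+-"[r.integers(2)]

    for i in range(config.n_orf):
        length = int(rng.integers(olo, ohi + 1))
        chrom, start, end, strand = _place_gene(rng, genome, occupied, length, orf_sampler)
        orfs.append(GeneRecord(f"ORF_{i + 1:04d}", chrom, start, end, strand, "ORF"))

    return SimulatedGenome(genome, trnas, orfs, feature_sets, coloc_ids)


def simulate_tag_track(
    sim: SimulatedGenome, config: SimulationConfig
) -> TagTrack:
    """Poisson background plus a sharp planted peak per tRNA gene.

    Per tRNA, a Poisson(peak_amplitude_mean) number of tags is placed at
    gene-oriented offsets drawn from Normal(peak_offset, peak_sigma)
    around the TSS and rounded to integer positions; each tag lands in
    the forward or reverse channel with equal probability.  Background is
    Poisson(background_rate) per position genome-wide.
    """
    rng = _rng(config.seed, "track")
    genome = sim.genome
    fwd: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rev: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    per_chrom_positions: dict[str, list[np.ndarray]] = {c: [] for c in genome.chrom_names}

    if config.background_rate > 0:
        for chrom in genome.chrom_names:
            counts = rng.poisson(config.background_rate, genome.length(chrom))
            nz = np.flatnonzero(counts)
            per_chrom_positions[chrom].append(np.repeat(nz, counts[nz]))

    for gene in sim.trnas:
        n_tags = int(rng.poisson(config.peak_amplitude_mean))
        if n_tags == 0:
            continue
        offsets = np.rint(rng.normal(config.peak_offset, config.peak_sigma, n_tags))
        sign = 1 if gene.strand == "+" else -1
        pos = gene.tss + sign * offsets.astype(np.int64)
        pos = pos[(pos >= 0) & (pos < genome.length(gene.chrom))]
        per_chrom_positions[gene.chrom].append(pos)

    for chrom, chunks in per_chrom_positions.items():
        if not chunks:
            continue
        tags = np.concatenate(chunks)
        if tags.size == 0:
            continue
        pos, counts = np.unique(tags, return_counts=True)
        f = rng.binomial(counts, 0.5)
        r = counts - f
        fwd[chrom] = (pos, f.astype(float))
        rev[chrom] = (pos, r.astype(float))
    return TagTrack(genome, fwd, rev)


# base cycle-threshold levels the noise-free Ct construction hangs off;
# arbitrary but realistic mid-range values that cancel in the fold formula
_BASE_CT = {"input": 20.0, "mock": 27.0, "IP": 27.0}


def simulate_ct(config: SimulationConfig, efficiency: float = 2.0) -> CtTable:
    """Ct table whose noise-free fold enrichment equals ``true_fold`` exactly.

    TelVIR and gene Cts are set so the TelVIR/input double normalization
    yields the planted fold at zero noise; Normal(0, ct_noise_sd) cycles
    are then added independently to every measurement.
    """
    rng = _rng(config.seed, "ct")
    rows = []
    condition = "WT"
    for rep in range(1, config.n_replicates + 1):
        for kind, base in _BASE_CT.items():
            rows.append((kind, condition, TELVIR, rep, base))
        for gene, fold in config.true_fold.items():
            if fold <= 0:
                raise SimulationError(f"true fold for {gene!r} must be > 0")
            for kind, base in _BASE_CT.items():
                ct = base
                if kind == "IP":
                    ct = base - np.log(fold) / np.log(efficiency)
                rows.append((kind, condition, gene, rep, ct))
    df = pd.DataFrame(
        rows, columns=["sample_kind", "condition", "amplicon", "replicate", "ct"]
    )
    if config.ct_noise_sd > 0:
        df["ct"] = df["ct"] + rng.normal(0.0, config.ct_noise_sd, len(df))
    return CtTable(df)


def simulate_counts(config: SimulationConfig) -> CountTable:
    """Multinomial count table with known per-sample abundance ratios.

    ``true_abundances`` maps sample -> {row_id: relative abundance}; when
    None, a shared 8-row geometric abundance ladder is used for every
    sample so replicate structure is trivially comparable.
    """
    rng = _rng(config.seed, "counts")
    abundances = config.true_abundances
    if abundances is None:
        ladder = {f"tRNA_{i + 1:04d}": 2.0**i for i in range(8)}
        abundances = {sample: ladder for sample in config.library_sizes}
    rows = sorted({r for m in abundances.values() for r in m})
    data = {}
    for sample, size in config.library_sizes.items():
        weights = np.array([abundances[sample].get(r, 0.0) for r in rows])
        if weights.sum() <= 0:
            raise SimulationError(f"sample {sample!r} has no positive abundances")
        data[sample] = rng.multinomial(int(size), weights / weights.sum())
    return CountTable(pd.DataFrame(data, index=rows))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same configuration, different seed."""
    return replace(config, seed=int(seed))
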