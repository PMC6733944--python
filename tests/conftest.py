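import numpy as np
import pytest

from pol3prox.annotations import FeatureSet, GeneRecord, Genome
from pol3prox.track_io import TagTrack


@pytest.fixture
def tiny_genome() -> Genome:
    return Genome({"chrI": 40, "chrII": 50})


@pytest.fixture
def small_genome() -> Genome:
    return Genome({"chrI": 100_000, "chrII": 80_000})


def make_track(genome: Genome, per_chrom: dict) -> TagTrack:
    """Build a track from {chrom: {pos: (fwd, rev)}} dicts."""
    fwd = {}
    rev = {}
    for chrom, d in per_chrom.items():
        pos = np.array(sorted(d), dtype=np.int64)
        fwd[chrom] = (pos, np.array([d[p][0] for p in pos], dtype=float))
        rev[chrom] = (pos, np.array([d[p][1] for p in pos], dtype=float))
    return TagTrack(genome, fwd, rev)


def constant_track(genome: Genome, value: float) -> TagTrack:
    fwd = {
        c: (np.arange(genome.length(c), dtype=np.int64),
            np.full(genome.length(c), value, dtype=float))
        for c in genome.chrom_names
    }
    return TagTrack(genome, fwd, {})


def random_genes(rng, genome, n, min_len=70, max_len=120, gene_class="tRNA", prefix="g"):
    genes = []
    for i in range(n):
        chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome.length(chrom) - length))
        strand = "+-"[rng.integers(2)]
        genes.append(GeneRecord(f"{prefix}{i}", chrom, start, start + length, strand, gene_class))
    return genes


def random_features(rng, genome, n, name="features"):
    pairs = []
    for _ in range(n):
        chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        pairs.append((chrom, int(rng.integers(genome.length(chrom)))))
    return FeatureSet.from_pairs(name, pairs)


def reflect_gene(gene: GeneRecord, length: int) -> GeneRecord:
    """Mirror a gene through pos -> L - 1 - pos (strand flipped)."""
    return GeneRecord(
        gene.gene_id,
        gene.chrom,
        length - gene.end,
        length - gene.start,
        "-" if gene.strand == "+" else "+",
        gene.gene_class,
    )


def reflect_track(track: TagTrack) -> TagTrack:
    genome = track.genome
    fwd = {}
    for chrom in track.chroms():
        pos, cnt = track.collapsed(chrom)
        length = genome.length(chrom)
        fwd[chrom] = ((length - 1 - pos)[::-1], cnt[::-1])
    return TagTrack(genome, fwd, {})
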