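"""Genomic coordinate model and gene/feature containers.

Everything downstream (metagene profiling, proximity enrichment, the
simulator) consumes the types defined here.  Internal coordinates are
0-based half-open throughout; readers for 1-based tab tables shift on
input.  Point features (replication origins, TAD boundaries) are
unstranded; interval-shaped sources are collapsed to midpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_CLASSES = ("tRNA", "ORF", "other_pol3")


class AnnotationError(ValueError):
    """Structurally invalid annotation input."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome name -> length (bp) container.

    Lengths must be positive and names unique; every record elsewhere must
    reference a chromosome present here.
    """

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise AnnotationError("genome has no chromosomes")
        for name, length in self.chrom_lengths.items():
            if int(length) <= 0:
                raise AnnotationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval: 0-based half-open [start, end) with strand.

    ``gene_class`` distinguishes pol III-transcribed genes (tRNA,
    other_pol3) from pol II-transcribed ORFs.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "other_pol3"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(
                f"gene {self.gene_id!r}: gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (symmetric to :attr:`tss`)."""
        return self.end - 1 if self.strand == "+" else self.start

    def validate_against(self, genome: Genome) -> None:
        if self.end > genome.length(self.chrom):
            raise AnnotationError(
                f"gene {self.gene_id!r} extends past end of {self.chrom} "
                f"({self.end} > {genome.length(self.chrom)})"
            )


def tss(gene: GeneRecord) -> int:
    """TSS position of a gene (strand-aware, see :class:`GeneRecord`)."""
    return gene.tss


def tts(gene: GeneRecord) -> int:
    return gene.tts


def signed_distance(point: int, feature: int) -> int:
    """Signed genomic offset ``point - feature``.

    Negative means the point lies left of the feature in genome
    coordinates; features are unstranded so no strand flip applies.
    Callers are responsible for only comparing same-chromosome positions.
    """
    return int(point) - int(feature)


@dataclass
class FeatureSet:
    """Named set of unstranded point features, e.g. origins or TAD boundaries.

    ``points`` maps chromosome -> sorted numpy array of positions.
    """

    name: str
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {
            chrom: np.sort(np.asarray(pos, dtype=np.int64))
            for chrom, pos in self.points.items()
        }

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, int]]) -> "FeatureSet":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in pairs:
            by_chrom.setdefault(chrom, []).append(int(pos))
        return cls(name, {c: np.array(p, dtype=np.int64) for c, p in by_chrom.items()})

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "FeatureSet":
        """Collapse intervals to integer midpoints (floor of endpoint mean)."""
        return cls.from_pairs(name, ((c, (s + e) // 2) for c, s, e in intervals))

    def validate_against(self, genome: Genome) -> None:
        for chrom, pos in self.points.items():
            length = genome.length(chrom)
            if pos.size and (pos.min() < 0 or pos.max() >= length):
                raise AnnotationError(
                    f"feature set {self.name!r}: position out of bounds on {chrom}"
                )

    def __len__(self) -> int:
        return sum(p.size for p in self.points.values())

    def iter_points(self) -> Iterable[tuple[str, int]]:
        for chrom, pos in self.points.items():
            for p in pos:
                yield chrom, int(p)


def genes_within(
    features: FeatureSet,
    genes: Sequence[GeneRecord],
    max_dist: int,
    mode: str = "tss",
) -> list[GeneRecord]:
    """Genes whose TSS (or nearest gene edge) lies within ``max_dist`` of a feature.

    "Within" is closed (|distance| <= max_dist).  Each gene appears at most
    once regardless of how many features it is near.  ``mode='edge'``
    measures from the nearer of the two gene boundary coordinates instead
    of the TSS.
    """
    if max_dist < 0:
        raise AnnotationError(f"max_dist must be >= 0, got {max_dist}")
    if mode not in ("tss", "edge"):
        raise AnnotationError(f"mode must be 'tss' or 'edge', got {mode!r}")
    kept: list[GeneRecord] = []
    for gene in genes:
        pos = features.points.get(gene.chrom)
        if pos is None or pos.size == 0:
            continue
        if mode == "tss":
            dmin = np.min(np.abs(pos - gene.tss))
        else:
            dmin = min(
                np.min(np.abs(pos - gene.start)),
                np.min(np.abs(pos - (gene.end - 1))),
            )
        if dmin <= max_dist:
            kept.append(gene)
    return kept


# ---------------------------------------------------------------------------
# File interfaces: BED6, tab-delimited annotation tables, chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> Genome:
    """Two-column (name, length) whitespace/tab file -> :class:`Genome`."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"])
    if df["chrom"].duplicated().any():
        dupes = df.loc[df["chrom"].duplicated(), "chrom"].tolist()
        raise AnnotationError(f"duplicate chromosome names: {dupes}")
    return Genome({str(r.chrom): int(r.length) for r in df.itertuples()})


def read_bed6(path, gene_class: str = "other_pol3") -> list[GeneRecord]:
    """BED6 (0-based half-open) -> gene records; name column becomes gene_id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneRecord(str(r.name), str(r.chrom), int(r.start), int(r.end), str(r.strand), gene_class)
        for r in df.itertuples()
    ]


def write_bed6(genes: Sequence[GeneRecord], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_table(path) -> list[GeneRecord]:
    """Headered tab table (gene_id, chrom, start, end, strand, class), 1-based
    inclusive coordinates; shifted to internal 0-based half-open on read."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "start", "end", "strand", "class"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
    df = df.rename(columns={"class": "gene_class"})
    return [
        GeneRecord(
            str(r.gene_id),
            str(r.chrom),
            int(r.start) - 1,
            int(r.end),
            str(r.strand),
            str(r.gene_class),
        )
        for r in df.itertuples()
    ]


def read_feature_bed(path, name: str) -> FeatureSet:
    """BED intervals -> point features (interval midpoints)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    return FeatureSet.from_intervals(
        name, ((str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples())
    )
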