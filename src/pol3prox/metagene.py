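"""Anchor-relative occupancy profiling around pol III-transcribed genes.

Strand-aware metagene averages (the per-offset mean of collapsed tag
counts across a gene set aligned at the TSS or TTS), heatmap matrices
with a rescaled gene body, the pol II gene-end confound filter, ORF
density profiles around tRNA gene bodies, and windowed mean occupancy
for gene-by-gene correlation analyses.

Upstream/downstream are gene-oriented throughout this module: offsets on
minus-strand genes read right-to-left along the genome, so offset -10
always means 10 bp upstream of the TSS in the direction of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import GeneRecord
from .stats import pearson_r  # noqa: F401  (module surface: correlation lives here)
from .track_io import TagTrack

logger = logging.getLogger(__name__)


class MetageneError(ValueError):
    pass


@dataclass
class OccupancyProfile:
    """Mean tag count per gene-oriented offset around an anchor.

    ``offsets`` are bp relative positions (negative = upstream of the
    anchor in gene orientation); ``values`` are means across the
    ``n_regions`` genes actually used.  The optional ``per_gene_matrix``
    keeps the underlying rows (genes x offsets).
    """

    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    n_regions: int
    gene_ids: list[str]
    per_gene_matrix: np.ndarray | None = None
    excluded: list[str] | None = None

    def __post_init__(self) -> None:
        if self.offsets.size != self.values.size:
            raise MetageneError("offsets and values must align")
        if np.any(np.diff(self.offsets) <= 0):
            raise MetageneError("offsets must be strictly increasing")
        if self.n_regions < 1:
            raise MetageneError("profile needs at least one gene")

    @property
    def peak_offset(self) -> int:
        """Offset of the profile maximum (first maximum on ties)."""
        return int(self.offsets[int(np.argmax(self.values))])


def _anchor_window(
    track: TagTrack, gene: GeneRecord, lo: int, hi: int, anchor: str = "TSS"
) -> np.ndarray | None:
    """Collapsed counts over gene-oriented offsets [lo, hi] from the anchor.

    Returns None when the genomic window exceeds chromosome bounds.
    """
    length = track.genome.length(gene.chrom)
    pos = gene.tss if anchor == "TSS" else gene.tts
    if gene.strand == "+":
        g0, g1 = pos + lo, pos + hi
    else:
        g0, g1 = pos - hi, pos - lo
    if g0 < 0 or g1 >= length:
        return None
    window = track.dense_window(gene.chrom, g0, g1 + 1)
    return window if gene.strand == "+" else window[::-1]


def compute_profile(
    track: TagTrack,
    genes: Sequence[GeneRecord],
    flank: int = 300,
    anchor: str = "TSS",
    keep_matrix: bool = False,
    per_million: bool = False,
) -> OccupancyProfile:
    """Average occupancy over [-flank, +flank] around the TSS (or TTS).

    Genes whose window would run past a chromosome end are excluded (and
    logged) so every row has equal length.  ``per_million`` rescales the
    track to tags-per-million before averaging.
    """
    if not genes:
        raise MetageneError("empty gene set")
    if flank < 1:
        raise MetageneError(f"flank must be >= 1, got {flank}")
    if anchor not in ("TSS", "TTS"):
        raise MetageneError(f"anchor must be TSS or TTS, got {anchor!r}")
    scale = 1e6 / track.total_tags if per_million else 1.0
    rows, used, excluded = [], [], []
    for gene in genes:
        window = _anchor_window(track, gene, -flank, flank, anchor)
        if window is None:
            excluded.append(gene.gene_id)
            continue
        rows.append(window * scale)
        used.append(gene.gene_id)
    if excluded:
        logger.info("compute_profile: excluded %d genes with out-of-bounds windows",
                    len(excluded))
    if not rows:
        raise MetageneError("all genes excluded: every window out of bounds")
    matrix = np.vstack(rows)
    return OccupancyProfile(
        anchor=anchor,
        offsets=np.arange(-flank, flank + 1),
        values=matrix.mean(axis=0),
        n_regions=len(rows),
        gene_ids=used,
        per_gene_matrix=matrix if keep_matrix else None,
        excluded=excluded,
    )


def filter_flanked_genes(
    trnas: Sequence[GeneRecord],
    pol2_genes: Sequence[GeneRecord],
    window: int = 300,
    mode: str = "both_sides",
) -> list[GeneRecord]:
    """Drop tRNA genes confounded by nearby pol II-transcribed gene ends.

    A pol II gene "end" is either of its boundary coordinates.  In
    ``both_sides`` mode a tRNA is removed iff some end lies within
    ``window`` bp on the upstream side AND another within ``window`` bp on
    the downstream side of its gene body; ``either_side`` removes on
    one-sided proximity.  Returns the retained tRNAs.
    """
    if mode not in ("both_sides", "either_side"):
        raise MetageneError(f"mode must be both_sides or either_side, got {mode!r}")
    if window < 0:
        raise MetageneError("window must be >= 0")
    ends_by_chrom: dict[str, list[int]] = {}
    for g in pol2_genes:
        ends_by_chrom.setdefault(g.chrom, []).extend((g.start, g.end))
    ends_arr = {c: np.array(sorted(v)) for c, v in ends_by_chrom.items()}
    kept = []
    for t in trnas:
        ends = ends_arr.get(t.chrom)
        if ends is None:
            kept.append(t)
            continue
        left = np.any((ends <= t.start) & (t.start - ends <= window))
        right = np.any((ends >= t.end) & (ends - t.end <= window))
        hit = (left and right) if mode == "both_sides" else (left or right)
        if not hit:
            kept.append(t)
    return kept


def orf_density(
    trnas: Sequence[GeneRecord],
    orfs: Sequence[GeneRecord],
    step: int = 100,
    span: int = 1000,
    same_strand: bool = True,
    assign: str = "proximal_end",
) -> dict[str, np.ndarray]:
    """Count ORFs in fixed windows around tRNA gene bodies.

    For every gene-oriented window ``[k*step, (k+1)*step)`` up/downstream
    of the tRNA body edges, counts ORFs whose proximal boundary coordinate
    falls in that window (``assign='proximal_end'``, the default) or whose
    interval overlaps the window (``assign='overlap'``; an ORF may then hit
    several windows), summed over tRNAs.  With ``same_strand`` only ORFs
    on the tRNA's strand are counted.  Returns ``{"upstream": ...,
    "downstream": ...}`` arrays of length ``span // step``; upstream index
    0 is the window nearest the gene.
    """
    if span % step != 0:
        raise MetageneError("span must be a multiple of step")
    if assign not in ("proximal_end", "overlap"):
        raise MetageneError(f"assign must be proximal_end or overlap, got {assign!r}")
    nbins = span // step
    up = np.zeros(nbins, dtype=np.int64)
    down = np.zeros(nbins, dtype=np.int64)
    for t in trnas:
        for o in orfs:
            if o.chrom != t.chrom:
                continue
            if same_strand and o.strand != t.strand:
                continue
            if assign == "proximal_end":
                side, dist = _proximal_end_offset(t, o)
                if side is None or dist >= span:
                    continue
                idx = dist // step
                # genome-left/right mapped to gene-oriented up/down via strand
                if t.strand == "+":
                    (up if side == "left" else down)[idx] += 1
                else:
                    (down if side == "left" else up)[idx] += 1
            else:
                for k in range(nbins):
                    left = (t.start - (k + 1) * step, t.start - k * step)
                    right = (t.end + k * step, t.end + (k + 1) * step)
                    for side, (w0, w1) in (("left", left), ("right", right)):
                        if o.start < w1 and w0 < o.end:
                            gene_side = side if t.strand == "+" else (
                                "right" if side == "left" else "left"
                            )
                            (up if gene_side == "left" else down)[k] += 1
    return {"upstream": up, "downstream": down}


def _proximal_end_offset(trna: GeneRecord, orf: GeneRecord):
    """(side, distance) of the ORF boundary coordinate nearest the tRNA body.

    side is 'left'/'right' of the body in genome orientation; None when the
    proximal end lies inside the body.
    """
    cands = []
    for p in (orf.start, orf.end):
        if p < trna.start:
            cands.append(("left", trna.start - p))
        elif p >= trna.end:
            cands.append(("right", p - trna.end))
        else:
            cands.append((None, 0))
    return min(cands, key=lambda c: c[1])


@dataclass
class HeatmapMatrix:
    """Per-gene binned occupancy rows: upstream flank, scaled body, downstream flank."""

    gene_ids: list[str]
    values: np.ndarray
    flank: int
    body_bins: int
    bin_size: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.bin_size

    def column_blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nf = self.n_flank_bins
        return (
            self.values[:, :nf],
            self.values[:, nf : nf + self.body_bins],
            self.values[:, nf + self.body_bins :],
        )


def heatmap_matrix(
    track: TagTrack,
    genes: Sequence[GeneRecord],
    flank: int = 1000,
    body_bins: int = 50,
    bin_size: int = 10,
    sort_rows: bool = True,
) -> HeatmapMatrix:
    """Per-gene occupancy rows with fixed flank bins and a rescaled body.

    Flank regions up/downstream of the gene body (gene-oriented) are
    mean-pooled at ``bin_size`` bp; the body is rescaled into
    ``body_bins`` bins by mean pooling, or linear interpolation when the
    gene is shorter than ``body_bins`` (logged).  Rows are ordered by
    descending row sum by default (presentation only).
    """
    if not genes:
        raise MetageneError("empty gene set")
    if flank % bin_size != 0:
        raise MetageneError("flank must be a multiple of bin_size")
    rows, ids = [], []
    n_interp = 0
    for gene in genes:
        length = track.genome.length(gene.chrom)
        g0, g1 = gene.start - flank, gene.end + flank
        if g0 < 0 or g1 > length:
            logger.info("heatmap_matrix: excluding %s (window out of bounds)", gene.gene_id)
            continue
        dense = track.dense_window(gene.chrom, g0, g1)
        if gene.strand == "-":
            dense = dense[::-1]
        up = dense[:flank].reshape(-1, bin_size).mean(axis=1)
        body = dense[flank : flank + (gene.end - gene.start)]
        down = dense[flank + (gene.end - gene.start) :].reshape(-1, bin_size).mean(axis=1)
        if body.size < body_bins:
            n_interp += 1
            body_binned = np.interp(
                np.linspace(0, body.size - 1, body_bins), np.arange(body.size), body
            )
        else:
            edges = np.linspace(0, body.size, body_bins + 1).astype(int)
            body_binned = np.array(
                [body[edges[i] : edges[i + 1]].mean() for i in range(body_bins)]
            )
        rows.append(np.concatenate([up, body_binned, down]))
        ids.append(gene.gene_id)
    if n_interp:
        logger.info("heatmap_matrix: %d genes shorter than body_bins, interpolated", n_interp)
    if not rows:
        raise MetageneError("all genes excluded: every window out of bounds")
    values = np.vstack(rows)
    if sort_rows:
        order = np.argsort(-values.sum(axis=1), kind="stable")
        values = values[order]
        ids = [ids[i] for i in order]
    return HeatmapMatrix(ids, values, flank, body_bins, bin_size)


def mean_window_occupancy(
    track: TagTrack,
    gene: GeneRecord,
    rel_start: int,
    rel_end: int,
) -> float:
    """Mean collapsed count over gene-oriented TSS offsets [rel_start, rel_end].

    The window is inclusive at both ends; parts falling outside the
    chromosome are truncated (logged) rather than excluding the gene.
    """
    if rel_start >= rel_end:
        raise MetageneError("rel_start must be < rel_end")
    length = track.genome.length(gene.chrom)
    anchor = gene.tss
    if gene.strand == "+":
        g0, g1 = anchor + rel_start, anchor + rel_end
    else:
        g0, g1 = anchor - rel_end, anchor - rel_start
    t0, t1 = max(g0, 0), min(g1, length - 1)
    if (t0, t1) != (g0, g1):
        logger.info("mean_window_occupancy: window truncated to chromosome bounds for %s",
                    gene.gene_id)
    if t0 > t1:
        raise MetageneError("window lies entirely outside the chromosome")
    window = track.dense_window(gene.chrom, t0, t1 + 1)
    return float(window.mean())
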