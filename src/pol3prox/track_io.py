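"""Positional signal and assay-table IO.

Covers the formats the analyses touch: processed per-position tag tables
with forward/reverse channels (ChIP-exo style depositions), bedGraph,
qPCR cycle-threshold tables and tRNA abundance count matrices.  Readers
validate and reject rather than silently repair; every writer produces a
file its paired reader accepts losslessly.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotations import Genome

logger = logging.getLogger(__name__)

TELVIR = "TelVIR"
SAMPLE_KINDS = ("IP", "mock", "input")


class TrackIOError(ValueError):
    """Structurally invalid signal or table input."""


def _sorted_channel(positions, counts) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(positions, dtype=np.int64)
    cnt = np.asarray(counts, dtype=np.float64)
    order = np.argsort(pos, kind="stable")
    pos, cnt = pos[order], cnt[order]
    # merge duplicate positions by summation
    if pos.size:
        uniq, inverse = np.unique(pos, return_inverse=True)
        if uniq.size != pos.size:
            summed = np.zeros(uniq.size)
            np.add.at(summed, inverse, cnt)
            pos, cnt = uniq, summed
    keep = cnt != 0
    return pos[keep], cnt[keep]


@dataclass
class TagTrack:
    """Sparse per-chromosome positional counts with forward/reverse channels.

    ``forward``/``reverse`` map chromosome -> (sorted positions, counts).
    The collapsed channel (forward + reverse) is derived on demand and
    cached; ``total_tags`` is the sum of the collapsed channel.
    """

    genome: Genome
    forward: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    reverse: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for channel in (self.forward, self.reverse):
            for chrom in list(channel):
                pos, cnt = _sorted_channel(*channel[chrom])
                if np.any(cnt < 0):
                    raise TrackIOError(f"negative tag count on {chrom}")
                length = self.genome.length(chrom)
                if pos.size and (pos[0] < 0 or pos[-1] >= length):
                    raise TrackIOError(f"tag position out of bounds on {chrom}")
                channel[chrom] = (pos, cnt)
        self._collapsed_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- channel access -----------------------------------------------------
    def collapsed(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (positions, forward+reverse counts) for one chromosome."""
        if chrom not in self._collapsed_cache:
            fp, fc = self.forward.get(chrom, (np.empty(0, np.int64), np.empty(0)))
            rp, rc = self.reverse.get(chrom, (np.empty(0, np.int64), np.empty(0)))
            self._collapsed_cache[chrom] = _sorted_channel(
                np.concatenate([fp, rp]), np.concatenate([fc, rc])
            )
        return self._collapsed_cache[chrom]

    def chroms(self) -> list[str]:
        return [c for c in self.genome.chrom_names if c in self.forward or c in self.reverse]

    @property
    def total_tags(self) -> float:
        return float(sum(self.collapsed(c)[1].sum() for c in self.chroms()))

    def dense_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense collapsed counts over genomic [start, end); zeros where no tags."""
        pos, cnt = self.collapsed(chrom)
        out = np.zeros(end - start)
        lo, hi = np.searchsorted(pos, [start, end])
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    # -- construction -------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        genome: Genome,
        records: Iterable[tuple[str, int, float, float]],
    ) -> "TagTrack":
        """Build from (chrom, position, forward, reverse) rows, summing duplicates."""
        fwd: dict[str, list] = {}
        rev: dict[str, list] = {}
        for chrom, pos, f, r in records:
            fwd.setdefault(chrom, []).append((pos, f))
            rev.setdefault(chrom, []).append((pos, r))
        return cls(
            genome,
            {c: tuple(zip(*v)) if v else ((), ()) for c, v in fwd.items()},
            {c: tuple(zip(*v)) if v else ((), ()) for c, v in rev.items()},
        )


def collapse_tags(track: TagTrack) -> TagTrack:
    """Sum forward and reverse channels into a single authoritative channel.

    The result carries the summed counts in its forward channel with an
    empty reverse channel, so its collapsed channel equals the input's.
    """
    return TagTrack(
        track.genome,
        {c: track.collapsed(c) for c in track.chroms()},
        {},
    )


# ---------------------------------------------------------------------------
# Tag table IO
# ---------------------------------------------------------------------------

_TAG_COLUMNS = ("chrom", "position", "forward", "reverse")


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    """Read a headered table, auto-detecting tab vs comma."""
    with open(path) as fh:
        head = fh.readline()
        body = head + fh.read()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(io.StringIO(body), sep=sep, **kwargs)


def read_tag_table(
    path,
    genome: Genome,
    one_based: bool = True,
    columns: dict[str, str] | None = None,
) -> TagTrack:
    """Read a processed tag table (chrom, position, forward, reverse counts).

    Positions are treated as 1-based by default (the common dialect of
    deposited processed files) and shifted to internal 0-based;
    ``one_based=False`` switches the dialect.  ``columns`` maps the
    canonical names to the file's actual column headers.  Duplicate
    (chrom, position) rows are summed.  Malformed rows and unknown
    chromosomes are rejected with the offending line / name.
    """
    colmap = {c: c for c in _TAG_COLUMNS}
    if columns:
        colmap.update(columns)
    df = _read_delimited(path, dtype={colmap["chrom"]: str})
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise TrackIOError(f"tag table missing columns: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    for col in ("position", "forward", "reverse"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise TrackIOError(f"malformed {col!r} value at line {line}")
        df[col] = numeric
    unknown = sorted(set(df["chrom"]) - set(genome.chrom_names))
    if unknown:
        raise TrackIOError(f"unknown chromosomes in tag table: {unknown}")
    shift = 1 if one_based else 0
    df["position"] = df["position"].astype(np.int64) - shift
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["position"].to_numpy()
        if pos.size and (pos.min() < 0 or pos.max() >= genome.length(str(chrom))):
            raise TrackIOError(f"tag position out of bounds on {chrom}")
    if df["chrom"].duplicated().any() and df.duplicated(["chrom", "position"]).any():
        logger.info("duplicate (chrom, position) rows summed in %s", path)
    fwd = {
        str(c): (s["position"].to_numpy(), s["forward"].to_numpy())
        for c, s in df.groupby("chrom", sort=False)
    }
    rev = {
        str(c): (s["position"].to_numpy(), s["reverse"].to_numpy())
        for c, s in df.groupby("chrom", sort=False)
    }
    return TagTrack(genome, fwd, rev)


def write_tag_table(track: TagTrack, path, one_based: bool = True) -> None:
    """Write forward/reverse channels as a headered tab table (inverse of read)."""
    shift = 1 if one_based else 0
    rows = []
    for chrom in track.chroms():
        fp, fc = track.forward.get(chrom, (np.empty(0, np.int64), np.empty(0)))
        rp, rc = track.reverse.get(chrom, (np.empty(0, np.int64), np.empty(0)))
        pos = np.union1d(fp, rp)
        f = np.zeros(pos.size)
        r = np.zeros(pos.size)
        f[np.searchsorted(pos, fp)] = fc
        r[np.searchsorted(pos, rp)] = rc
        for p, fv, rv in zip(pos, f, r):
            rows.append((chrom, int(p) + shift, fv, rv))
    pd.DataFrame(rows, columns=list(_TAG_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

BEDGRAPH_HEADER = "track type=bedGraph"


def write_bedgraph(track: TagTrack, path) -> None:
    """Write the collapsed channel as bedGraph (0-based half-open runs).

    Adjacent equal-valued positions are merged into one record; zero
    positions are omitted, per bedGraph sparse convention.
    """
    with open(path, "w") as fh:
        fh.write(BEDGRAPH_HEADER + "\n")
        for chrom in track.chroms():
            pos, cnt = track.collapsed(chrom)
            i = 0
            while i < pos.size:
                j = i
                while (
                    j + 1 < pos.size
                    and pos[j + 1] == pos[j] + 1
                    and cnt[j + 1] == cnt[i]
                ):
                    j += 1
                fh.write(f"{chrom}\t{pos[i]}\t{pos[j] + 1}\t{cnt[i]:g}\n")
                i = j + 1


def read_bedgraph(path, genome: Genome) -> TagTrack:
    """Read bedGraph into a single-channel track (values in forward)."""
    per_chrom: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TrackIOError(f"malformed bedGraph line {lineno}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in genome:
                raise TrackIOError(f"unknown chromosome {chrom!r} at line {lineno}")
            pos_list, cnt_list = per_chrom.setdefault(chrom, ([], []))
            pos_list.extend(range(start, end))
            cnt_list.extend([value] * (end - start))
    return TagTrack(genome, {c: (p, v) for c, (p, v) in per_chrom.items()}, {})


# ---------------------------------------------------------------------------
# Ct tables and count tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """qPCR cycle-threshold measurements.

    One row per (sample_kind, condition, amplicon, replicate); every
    (sample_kind, condition, replicate) combination must include a TelVIR
    control amplicon, the subtelomeric background reference.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_kind", "condition", "amplicon", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise TrackIOError(f"Ct table missing columns: {sorted(missing)}")
        df = self.data
        bad_kind = set(df["sample_kind"]) - set(SAMPLE_KINDS)
        if bad_kind:
            raise TrackIOError(f"unknown sample_kind values: {sorted(bad_kind)}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
            raise TrackIOError("Ct values must be finite and > 0")
        groups = df.groupby(["sample_kind", "condition", "replicate"])
        for key, sub in groups:
            if not (sub["amplicon"] == TELVIR).any():
                raise TrackIOError(
                    f"missing {TELVIR} control row for (sample_kind, condition, "
                    f"replicate) = {key}"
                )

    def ct(self, sample_kind: str, condition: str, amplicon: str, replicate) -> float:
        df = self.data
        sel = df[
            (df["sample_kind"] == sample_kind)
            & (df["condition"] == condition)
            & (df["amplicon"] == amplicon)
            & (df["replicate"] == replicate)
        ]
        if sel.empty:
            raise TrackIOError(
                f"no Ct for sample_kind={sample_kind!r}, condition={condition!r}, "
                f"amplicon={amplicon!r}, replicate={replicate!r}"
            )
        return float(sel["ct"].mean())

    def genes(self) -> list[str]:
        return sorted(set(self.data["amplicon"]) - {TELVIR})

    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))

    def replicates(self, condition: str) -> list:
        sub = self.data[self.data["condition"] == condition]
        return sorted(set(sub["replicate"]))


def read_ct_table(path) -> CtTable:
    return CtTable(_read_delimited(path))


def write_ct_table(table: CtTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


@dataclass
class CountTable:
    """Raw abundance counts: rows are tRNA identifiers, columns are samples."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TrackIOError("count table must be numeric")
        if (arr < 0).any():
            raise TrackIOError("count table has negative entries")
        if not np.allclose(arr, np.round(arr)):
            raise TrackIOError("count table entries must be integers")
        self.counts = self.counts.astype(np.int64)

    def require_positive_totals(self) -> None:
        sums = self.counts.sum(axis=0)
        zero = sums[sums <= 0].index.tolist()
        if zero:
            raise TrackIOError(f"zero-sum count columns cannot be normalized: {zero}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def read_count_table(path) -> CountTable:
    df = _read_delimited(path, index_col=0)
    return CountTable(df)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t")
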