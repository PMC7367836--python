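"""Genomic coordinate plumbing and text-format I/O.

Defines the shared interval data model (:class:`GenomicInterval`,
:class:`GenomeTable`, :class:`BinnedTrack`, :class:`GeneRecord`) and
readers/writers for the small set of plain-text formats the pipeline
touches: two-column chrom-sizes, 4-column bedGraph, BED3/6/12, minimal
GTF (gene/transcript features with a ``gene_id`` attribute) and TSV with
a header line.

All coordinates are 0-based half-open (BED convention) internally;
1-based GTF input is converted at the parsing boundary.  Strand is
retained where the format carries it but replication-timing analyses
ignore it (replication is strand-agnostic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}

# fixed float format used by every writer so that rerunning a pipeline with
# the same config is byte-identical
FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test (shared chromosome, >=1 shared bp)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeTable(Mapping[str, int]):
    """Ordered map of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Sequence[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for name, length in items:
            if not name:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self._sizes: dict[str, int] = dict(items)

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeTable":
        """Read a two-column (name, length) chrom-sizes file."""
        items: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns")
                try:
                    items.append((parts[0], int(parts[1])))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
        return cls(items)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeTable) and self._sizes == other._sizes

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self[chrom] / bin_size)

    def validate_interval(self, iv: GenomicInterval) -> None:
        """Reject intervals on unknown chromosomes or beyond the end."""
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval end {iv.end} beyond length of {iv.chrom} ({self._sizes[iv.chrom]})"
            )

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())


@dataclass
class BinnedTrack:
    """A per-chromosome numeric signal in fixed-width non-overlapping bins.

    One value per bin (the last bin may be truncated at the chromosome
    end); masked bins carry ``NaN``.  Vector length per chromosome is
    ``ceil(length / bin_size)``.
    """

    genome: GenomeTable
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom in self.genome:
            n = self.genome.n_bins(chrom, self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.full(n, np.nan)
            else:
                v = np.asarray(self.values[chrom], dtype=float)
                if v.shape != (n,):
                    raise ValueError(
                        f"{chrom}: expected {n} bins, got {v.shape}"
                    )
                self.values[chrom] = v

    @classmethod
    def allocate(cls, genome: GenomeTable, bin_size: int, fill: float = np.nan) -> "BinnedTrack":
        return cls(
            genome,
            bin_size,
            {c: np.full(genome.n_bins(c, bin_size), float(fill)) for c in genome},
        )

    def mask(self, chrom: str) -> np.ndarray:
        """Boolean array, True where the bin carries no value."""
        return np.isnan(self.values[chrom])

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.genome, self.bin_size, {c: v.copy() for c, v in self.values.items()}
        )

    def flat(self) -> np.ndarray:
        """All values concatenated in genome order (masked bins as NaN)."""
        return np.concatenate([self.values[c] for c in self.genome])

    def set_flat(self, flat: np.ndarray) -> None:
        off = 0
        for chrom in self.genome:
            n = len(self.values[chrom])
            self.values[chrom] = np.asarray(flat[off : off + n], dtype=float)
            off += n
        if off != len(flat):
            raise ValueError("flat vector length mismatch")

    def compatible_with(self, other: "BinnedTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size

    def bin_centers(self, chrom: str) -> np.ndarray:
        n = len(self.values[chrom])
        centers = np.arange(n) * self.bin_size + self.bin_size / 2
        return np.minimum(centers, self.genome[chrom])


@dataclass(frozen=True)
class GeneRecord:
    """A gene span (transcript isoforms collapsed to the union span)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# bedGraph


def _parse_bedgraph_rows(path: str | Path) -> pd.DataFrame:
    """Parse a 4-column bedGraph, reporting the line number on failure."""
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        if df.isna().any().any():
            raise FormatError("missing fields")
        return df
    except (ValueError, FormatError):
        pass  # fall through to the diagnostic line-by-line parse
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record {s!r}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_bedgraph(path: str | Path, genome: GenomeTable, bin_size: int) -> BinnedTrack:
    """Read a 4-column bedGraph into fixed-width bins.

    Record values are averaged into bins weighted by the number of bp the
    record covers within each bin; uncovered sub-bin stretches contribute
    neither value nor weight, and entirely uncovered bins are masked.
    Records may be unsorted and may abut or leave gaps, but overlapping
    records simply stack their weights.
    """
    df = _parse_bedgraph_rows(path)
    track = BinnedTrack.allocate(genome, bin_size)
    if df.empty:
        return track
    for chrom_name in pd.unique(df["chrom"]):
        if chrom_name not in genome:
            raise ValueError(f"bedGraph record on unknown chromosome {chrom_name!r}")
    for chrom_name, sub in df.groupby("chrom", sort=False):
        clen = genome[chrom_name]
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        value = sub["value"].to_numpy()
        if (start < 0).any() or (start >= end).any():
            raise FormatError(f"invalid interval on {chrom_name}")
        if (end > clen).any():
            raise ValueError(
                f"bedGraph interval beyond chromosome length on {chrom_name}"
            )
        n = genome.n_bins(chrom_name, bin_size)
        wsum = np.zeros(n)
        vsum = np.zeros(n)
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        single = b0 == b1
        if single.any():
            w = (end[single] - start[single]).astype(float)
            np.add.at(wsum, b0[single], w)
            np.add.at(vsum, b0[single], w * value[single])
        for s, e, v, lo, hi in zip(
            start[~single], end[~single], value[~single], b0[~single], b1[~single]
        ):
            for b in range(lo, hi + 1):
                seg = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
                wsum[b] += seg
                vsum[b] += seg * v
        out = np.full(n, np.nan)
        covered = wsum > 0
        out[covered] = vsum[covered] / wsum[covered]
        track.values[chrom_name] = out
    return track


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write one bedGraph line per unmasked bin (deterministic formatting)."""
    with open(path, "w") as fh:
        for chrom in track.genome:
            v = track.values[chrom]
            clen = track.genome[chrom]
            for i in np.flatnonzero(~np.isnan(v)):
                s = int(i) * track.bin_size
                e = min(s + track.bin_size, clen)
                fh.write(f"{chrom}\t{s}\t{e}\t{FLOAT_FMT % v[i]}\n")


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | Path, format: str = "bed12") -> list[GeneRecord]:
    """Read a gene annotation as one :class:`GeneRecord` per gene.

    ``bed12``: one record per gene; duplicate gene IDs (column 4) are an
    error.  ``gtf-minimal``: ``gene``/``transcript`` features carrying a
    ``gene_id`` attribute; records sharing a gene_id are collapsed to
    their union span.  Gene length is end − start; strand is preserved.
    """
    if format == "bed12":
        genes = _read_genes_bed12(path)
    elif format == "gtf-minimal":
        genes = _read_genes_gtf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not genes:
        logger.warning("empty gene annotation: %s", path)
    return genes


def _read_genes_bed12(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED12 needs >= 6 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if parts[5] in VALID_STRANDS else "."
            if end <= start:
                raise FormatError(f"{path}:{lineno}: zero-length gene {name!r}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {name!r}")
            seen.add(name)
            genes.append(GeneRecord(name, chrom, start, end, strand))
    return genes


_GENE_ID_KEY = "gene_id"


def _gtf_gene_id(attributes: str) -> str | None:
    # minimal attribute grammar: key "value"; pairs split on ';'
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(_GENE_ID_KEY):
            val = chunk[len(_GENE_ID_KEY):].strip()
            return val.strip('"').strip()
    return None


def _read_genes_gtf(path: str | Path) -> list[GeneRecord]:
    spans: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.rstrip("\n")
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("gene", "transcript"):
                continue
            gid = _gtf_gene_id(attrs)
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start = int(start1) - 1  # GTF is 1-based inclusive
            end = int(end1)
            if end <= start:
                raise FormatError(f"{path}:{lineno}: zero-length gene {gid!r}")
            if strand not in VALID_STRANDS:
                strand = "."
            if gid in spans:
                rec = spans[gid]
                if rec[0] != chrom:
                    raise FormatError(
                        f"{path}:{lineno}: gene {gid!r} spans multiple chromosomes"
                    )
                rec[1] = min(rec[1], start)
                rec[2] = max(rec[2], end)
            else:
                spans[gid] = [chrom, start, end, strand]
                order.append(gid)
    return [GeneRecord(g, *spans[g]) for g in order]


def genes_to_frame(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "length": [g.length for g in genes],
        }
    )


# ---------------------------------------------------------------------------
# interval tables


def write_interval_table(
    records: pd.DataFrame, path: str | Path, format: str = "tsv"
) -> None:
    """Write an interval table as BED (sorted, headerless) or TSV (header).

    ``records`` must carry ``chrom``/``start``/``end`` columns; for BED
    output optional ``name``, ``score`` and ``strand`` columns are used
    and the rows are sorted by (chrom, start).  Floats are written with a
    fixed format so identical inputs give byte-identical files.
    """
    df = records.copy()
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"interval table missing column {col!r}")
    if format == "bed":
        df = df.sort_values(["chrom", "start", "end"], kind="stable")
        cols = [df["chrom"], df["start"].astype(int), df["end"].astype(int)]
        if "name" in df.columns or "score" in df.columns or "strand" in df.columns:
            cols.append(df.get("name", pd.Series(["."] * len(df), index=df.index)))
        if "score" in df.columns or "strand" in df.columns:
            score = df.get("score", pd.Series([0] * len(df), index=df.index))
            cols.append(score)
        if "strand" in df.columns:
            cols.append(df["strand"])
        out = pd.concat(cols, axis=1)
        out.to_csv(path, sep="\t", header=False, index=False, float_format=FLOAT_FMT)
    elif format == "tsv":
        df.to_csv(path, sep="\t", header=True, index=False, float_format=FLOAT_FMT)
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/6(+); extra columns (e.g. narrowPeak) are ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            row = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
            }
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                try:
                    row["score"] = float(parts[4])
                except ValueError:
                    row["score"] = np.nan
            if len(parts) > 5 and parts[5] in VALID_STRANDS:
                row["strand"] = parts[5]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.dropna(axis=1, how="all") if rows else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    ivs = list(intervals)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "strand": [iv.strand for iv in ivs],
        }
    )
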