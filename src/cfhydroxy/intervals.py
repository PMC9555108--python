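"""Genomic interval primitives and BED plumbing.

Everything downstream (hMR universes, fragment counting, feature
annotation) runs on half-open 0-based intervals, the BED convention.
``IntervalSet`` is a thin, always-sorted columnar container (a pandas
DataFrame underneath) so that sweep operations can work on per-chromosome
numpy arrays instead of Python objects; at cfDNA scale a sample holds
hundreds of thousands of fragments.

Coordinate convention: ``[start, end)`` with ``0 <= start < end``.
Chromosome names are compared by exact string match — no "chr" prefix
harmonisation, so input mismatches surface as empty overlaps rather than
being silently papered over.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "SampleSheetEntry",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bed12",
    "write_bed12",
    "read_sample_sheet",
    "write_sample_sheet",
    "merge_intervals",
    "overlap_count",
    "feature_fraction",
    "total_genome_size",
]

_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Malformed BED input; message names the offending line number."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_COLUMNS = ["chrom", "start", "end", "name", "strand"]


class IntervalSet:
    """An ordered collection of intervals, sorted by (chrom, start, end).

    Construction accepts a DataFrame with at least ``chrom``/``start``/``end``
    columns, or any iterable of :class:`GenomicInterval` / ``(chrom, start,
    end[, name[, strand]])`` tuples.  The set is validated and sorted once at
    construction; all sweep operations rely on that order.
    """

    def __init__(self, data=None, label: str = ""):
        if data is None:
            df = pd.DataFrame(columns=_COLUMNS)
        elif isinstance(data, pd.DataFrame):
            df = data.copy()
        else:
            rows = []
            for item in data:
                if isinstance(item, GenomicInterval):
                    rows.append((item.chrom, item.start, item.end, "", item.strand))
                else:
                    t = tuple(item)
                    chrom, start, end = t[0], t[1], t[2]
                    name = t[3] if len(t) > 3 else ""
                    strand = t[4] if len(t) > 4 else "."
                    rows.append((chrom, start, end, name, strand))
            df = pd.DataFrame(rows, columns=_COLUMNS)
        for col, default in (("name", ""), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_COLUMNS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df):
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                r = df.iloc[i]
                raise ValueError(
                    f"invalid interval {r.chrom}:[{r.start},{r.end}): "
                    "require 0 <= start < end"
                )
            unknown = ~df["strand"].isin(_STRANDS)
            if unknown.any():
                raise ValueError("invalid strand value in interval set")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        self.label = label

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self.df.iloc[i]
        return GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    def __repr__(self) -> str:
        lab = f" label={self.label!r}" if self.label else ""
        return f"<IntervalSet n={len(self)}{lab}>"

    # -- helpers ------------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` arrays, in sorted order."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            out[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    @property
    def total_bases(self) -> int:
        """Sum of raw interval lengths (overlaps counted multiply)."""
        return int((self.df["end"] - self.df["start"]).sum())

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def merge(self, min_gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, min_gap=min_gap)


# ---------------------------------------------------------------------------
# BED I/O

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`.

    Columns 4 (name) and 6 (strand) are kept when present; anything else is
    ignored.  Track/browser/comment lines are skipped.  Malformed lines raise
    :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}:{lineno}: invalid coordinates [{start},{end}); "
                    "require 0 <= start < end"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            rows.append((fields[0], start, end, name, strand))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return IntervalSet(df, label=label if label is not None else path.stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write as BED; 3 columns, or 6 when any name/strand carries information.

    Round trip through :func:`read_bed` reproduces the set exactly.
    """
    df = iset.df
    rich = bool(len(df)) and bool(
        (df["name"].astype(str) != "").any() or (df["strand"] != ".").any()
    )
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if rich:
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name or '.'}\t0\t{row.strand}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# Gene models (BED12)


@dataclass(frozen=True)
class GeneModel:
    """A transcript span with exon structure, 0-based half-open."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs >= 1 exon")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Parse BED12 gene models; blockStarts are relative to chromStart."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"{path}:{lineno}: expected 12 BED12 fields")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed BED12 line") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise BedParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            genes.append(GeneModel(chrom, strand, start, end, exons, name))
    return genes


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    group: str
    replicate: int
    fragments_path: str = ""
    peaks_path: str = ""

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")


_SHEET_COLUMNS = ["sample_id", "group", "replicate", "fragments_path", "peaks_path"]


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    """Read a TSV sample sheet; (group, replicate) pairs must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SHEET_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    entries = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.group, int(row.replicate))
        if key in seen:
            raise ValueError(f"sample sheet {path}: duplicate (group, replicate) {key}")
        seen.add(key)
        entries.append(
            SampleSheetEntry(
                sample_id=row.sample_id,
                group=row.group,
                replicate=int(row.replicate),
                fragments_path=getattr(row, "fragments_path", "") or "",
                peaks_path=getattr(row, "peaks_path", "") or "",
            )
        )
    return entries


def write_sample_sheet(entries: Sequence[SampleSheetEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.sample_id, e.group, e.replicate, e.fragments_path, e.peaks_path)
            for e in entries
        ],
        columns=_SHEET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(iset: IntervalSet, min_gap: int = 0) -> IntervalSet:
    """Union-merge intervals; neighbours closer than ``min_gap`` also merge.

    Two intervals merge iff they overlap, touch (book-ended, gap == 0), or
    the gap between them is strictly less than ``min_gap``.  With
    ``min_gap=0`` this is the familiar ``bedtools merge`` default.  The
    operation is idempotent.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if len(iset) == 0:
        return IntervalSet(label=iset.label)
    rows = []
    for chrom, (starts, ends) in iset.per_chrom().items():
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            gap = int(s) - cur_e
            if gap <= 0 or gap < min_gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return IntervalSet(rows, label=iset.label)


def overlap_count(
    query: IntervalSet, subject: IntervalSet, min_overlap_bp: int = 1
) -> np.ndarray:
    """Number of subject intervals overlapping each query by >= min_overlap_bp.

    A subject interval may be counted by several queries (bedtools-multicov
    semantics).  The default 1-bp threshold uses an O((n+m) log m) searchsorted
    sweep per chromosome; larger thresholds fall back to an interval tree.
    Returns counts aligned with the (sorted) order of ``query``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    counts = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return counts
    sub = subject.per_chrom()
    offset = 0
    for chrom, grp in query.df.groupby("chrom", sort=True):
        n = len(grp)
        if chrom in sub:
            qs = grp["start"].to_numpy()
            qe = grp["end"].to_numpy()
            ss, se = sub[chrom]
            if min_overlap_bp == 1:
                starts_sorted = ss  # already sorted
                ends_sorted = np.sort(se)
                a = np.searchsorted(starts_sorted, qe, side="left")
                b = np.searchsorted(ends_sorted, qs, side="right")
                counts[offset : offset + n] = a - b
            else:
                from intervaltree import IntervalTree

                # attach unique payloads: duplicate intervals must all count
                tree = IntervalTree.from_tuples(
                    zip(ss.tolist(), se.tolist(), range(len(ss)))
                )
                for i, (q0, q1) in enumerate(zip(qs, qe)):
                    c = 0
                    for iv in tree.overlap(int(q0), int(q1)):
                        if min(q1, iv.end) - max(q0, iv.begin) >= min_overlap_bp:
                            c += 1
                    counts[offset + i] = c
        offset += n
    return counts


def total_genome_size(genome: Mapping[str, int] | Iterable[tuple[str, int]]) -> int:
    if isinstance(genome, Mapping):
        return int(sum(genome.values()))
    return int(sum(length for _, length in genome))


def feature_fraction(
    features: IntervalSet,
    genome_size: int | Mapping[str, int] | Iterable[tuple[str, int]],
) -> float:
    """Fraction of the genome covered by the (merged) feature set.

    ``genome_size`` may be a total base count or a chrom->length mapping; with
    a mapping, features exceeding their chromosome bound raise.
    """
    if isinstance(genome_size, (int, np.integer)):
        total = int(genome_size)
        bounds: Mapping[str, int] | None = None
    else:
        bounds = dict(genome_size) if not isinstance(genome_size, Mapping) else genome_size
        total = total_genome_size(bounds)
    if total <= 0:
        raise ValueError("genome_size must be > 0")
    if len(features) == 0:
        return 0.0
    if bounds is not None:
        for chrom, (starts, ends) in features.per_chrom().items():
            if chrom not in bounds:
                raise ValueError(f"feature chromosome {chrom!r} not in genome")
            if ends.max() > bounds[chrom]:
                raise ValueError(f"feature exceeds bounds of {chrom!r}")
    merged = merge_intervals(features)
    covered = merged.total_bases
    if bounds is None and covered > total:
        raise ValueError("features exceed genome bounds")
    return covered / total
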