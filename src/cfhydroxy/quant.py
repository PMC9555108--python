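"""Region universes, fragment counting, RPKM, replicate merging.

Builds the two region definitions the analysis runs on — the merged hMR
universe derived from per-replicate peak calls, and fixed 1-kb genome
tiles — then fills a regions x samples fragment-count matrix
(bedtools-multicov semantics: a fragment overlapping k regions counts in
all k), normalizes it to RPKM, and collapses replicates into group-level
signals by summing raw counts and library sizes.  Summation preserves
the Poisson additivity the downstream differential test relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    IntervalSet,
    SampleSheetEntry,
    merge_intervals,
    overlap_count,
    read_bed,
)

__all__ = [
    "RegionUniverse",
    "CountMatrix",
    "NormalizedMatrix",
    "GroupMatrix",
    "high_confidence_hmrs",
    "merged_hmr_universe",
    "tile_genome",
    "count_matrix",
    "rpkm",
    "merge_replicates",
]


@dataclass
class RegionUniverse:
    """A non-overlapping, sorted set of regions plus its provenance."""

    regions: IntervalSet
    definition: str  # consensus_hmr | merged_hmr | tiles_1kb
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.definition not in ("consensus_hmr", "merged_hmr", "tiles_1kb"):
            raise ValueError(f"unknown universe definition {self.definition!r}")
        df = self.regions.df
        for _, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise ValueError("universe regions must be non-overlapping")

    def __len__(self) -> int:
        return len(self.regions)

    def region_ids(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in self.regions.df[["chrom", "start", "end"]].itertuples(
                index=False
            )
        ]

    def lengths(self) -> np.ndarray:
        return self.regions.lengths()


@dataclass
class CountMatrix:
    """Regions x samples fragment counts with per-sample library sizes.

    Library size counts every fragment of the sample, including those
    outside the universe; column sums are therefore <= library sizes.
    """

    universe: RegionUniverse
    samples: list[SampleSheetEntry]
    counts: np.ndarray  # (R, S) int
    library_sizes: np.ndarray  # (S,) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.counts.shape != (len(self.universe), len(self.samples)):
            raise ValueError("counts shape does not match universe x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integral")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        df = self.universe.regions.df[["chrom", "start", "end"]].copy()
        df.insert(0, "region_id", self.region_ids())
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.counts[:, j]
        return df

    def region_ids(self) -> list[str]:
        return self.universe.region_ids()


@dataclass
class NormalizedMatrix:
    """RPKM values: count / ((region_kb) * (library_size / 1e6))."""

    universe: RegionUniverse
    samples: list[SampleSheetEntry]
    values: np.ndarray  # (R, S) float

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        df = self.universe.regions.df[["chrom", "start", "end"]].copy()
        df.insert(0, "region_id", self.universe.region_ids())
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.values[:, j]
        return df


@dataclass
class GroupMatrix:
    """Group-collapsed counts, library sizes and RPKM."""

    universe: RegionUniverse
    groups: list[str]
    group_counts: np.ndarray  # (R, G) int, summed over replicates
    group_library_sizes: np.ndarray  # (G,) int
    group_norm: np.ndarray  # (R, G) float, RPKM on the summed quantities

    def __post_init__(self) -> None:
        if self.group_counts.shape != (len(self.universe), len(self.groups)):
            raise ValueError("group_counts shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = self.universe.regions.df[["chrom", "start", "end"]].copy()
        df.insert(0, "region_id", self.universe.region_ids())
        for j, g in enumerate(self.groups):
            df[f"count_{g}"] = self.group_counts[:, j]
            df[f"rpkm_{g}"] = self.group_norm[:, j]
        return df


# ---------------------------------------------------------------------------
# Universe construction


def high_confidence_hmrs(
    peak_sets: Sequence[IntervalSet],
    min_replicates: int = 2,
    mode: str = "basewise",
) -> IntervalSet:
    """Sub-regions supported by peaks in >= ``min_replicates`` replicates.

    "Present in at least two biological replicates" is resolved base-wise:
    a base belongs to the consensus iff it is covered by peaks of at least
    ``min_replicates`` distinct replicates.  Base-wise presence is
    deterministic for partial overlaps, where peak-wise presence is not.
    ``mode="peakwise"`` instead keeps whole union peaks touched (>= 1 bp)
    by enough replicates.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    if len(peak_sets) < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} replicate peak sets, got {len(peak_sets)}"
        )
    merged = [merge_intervals(s) for s in peak_sets]  # one vote per replicate per base
    if mode == "peakwise":
        union = merge_intervals(IntervalSet(pd.concat([m.df for m in merged])))
        support = np.zeros(len(union), dtype=int)
        for m in merged:
            support += (overlap_count(union, m) > 0).astype(int)
        keep = support >= min_replicates
        return IntervalSet(
            union.df.loc[keep, ["chrom", "start", "end"]], label="consensus"
        )
    if mode != "basewise":
        raise ValueError("mode must be 'basewise' or 'peakwise'")

    chroms = sorted({c for m in merged for c in m.chroms})
    rows = []
    for chrom in chroms:
        pos_events = []
        for m in merged:
            per = m.per_chrom()
            if chrom in per:
                starts, ends = per[chrom]
                pos_events.append(np.column_stack([starts, np.ones_like(starts)]))
                pos_events.append(np.column_stack([ends, -np.ones_like(ends)]))
        ev = np.concatenate(pos_events)
        # sort by position; at equal positions apply ends before starts so a
        # replicate ending where another starts does not double-support
        order = np.lexsort((ev[:, 1], ev[:, 0]))
        ev = ev[order]
        depth = 0
        run_start = None
        i = 0
        n = len(ev)
        while i < n:
            pos = ev[i, 0]
            while i < n and ev[i, 0] == pos:
                depth += ev[i, 1]
                i += 1
            if depth >= min_replicates and run_start is None:
                run_start = int(pos)
            elif depth < min_replicates and run_start is not None:
                rows.append((chrom, run_start, int(pos)))
                run_start = None
    return IntervalSet(rows, label="consensus")


def merged_hmr_universe(
    hmr_sets: Sequence[IntervalSet], min_gap: int = 0
) -> RegionUniverse:
    """Union-merge hMR sets from all groups/samples into the total universe."""
    if not hmr_sets:
        raise ValueError("need >= 1 hMR set")
    frames = [s.df for s in hmr_sets if len(s)]
    combined = (
        IntervalSet(pd.concat(frames, ignore_index=True)) if frames else IntervalSet()
    )
    merged = merge_intervals(combined, min_gap=min_gap)
    return RegionUniverse(
        IntervalSet(merged.df[["chrom", "start", "end"]], label="merged_hmr"),
        "merged_hmr",
        {"n_inputs": len(hmr_sets), "min_gap": min_gap},
    )


def tile_genome(
    genome: Mapping[str, int] | Sequence[tuple[str, int]], bin_size: int = 1000
) -> RegionUniverse:
    """Half-open fixed tiles; the last tile truncates at the chromosome end."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    items = genome.items() if isinstance(genome, Mapping) else genome
    rows = []
    for chrom, size in items:
        size = int(size)
        edges = np.arange(0, size, bin_size, dtype=np.int64)
        for s in edges:
            rows.append((chrom, int(s), int(min(s + bin_size, size))))
    return RegionUniverse(
        IntervalSet(rows, label="tiles_1kb"), "tiles_1kb", {"bin_size": bin_size}
    )


# ---------------------------------------------------------------------------
# Counting and normalization


def count_matrix(
    universe: RegionUniverse,
    samples: Sequence[SampleSheetEntry],
    fragments: Mapping[str, IntervalSet] | None = None,
    min_overlap_bp: int = 1,
    base_dir: str | Path | None = None,
) -> CountMatrix:
    """Fragment counts per region per sample (multicov semantics).

    Fragments come either from the in-memory ``fragments`` mapping
    (sample_id -> IntervalSet) or from each entry's ``fragments_path``.
    A fragment spanning several regions is counted in each.  Library size
    is the sample's total fragment count, in or out of the universe.
    """
    cols, libs = [], []
    for entry in samples:
        if fragments is not None and entry.sample_id in fragments:
            frags = fragments[entry.sample_id]
        else:
            path = Path(entry.fragments_path)
            if base_dir is not None and not path.is_absolute():
                path = Path(base_dir) / path
            if not entry.fragments_path or not path.exists():
                raise FileNotFoundError(
                    f"fragment file missing for sample {entry.sample_id!r}: "
                    f"{entry.fragments_path!r}"
                )
            frags = read_bed(path, label=entry.sample_id)
        if len(frags) == 0:
            warnings.warn(f"sample {entry.sample_id!r} has zero fragments")
        cols.append(overlap_count(universe.regions, frags, min_overlap_bp=min_overlap_bp))
        libs.append(len(frags))
    counts = (
        np.column_stack(cols)
        if cols
        else np.zeros((len(universe), 0), dtype=np.int64)
    )
    return CountMatrix(universe, list(samples), counts, np.array(libs, dtype=np.int64))


def rpkm(counts: CountMatrix) -> NormalizedMatrix:
    """Reads per kilobase of region per million mapped fragments."""
    if (counts.library_sizes <= 0).any():
        bad = [
            s.sample_id
            for s, l in zip(counts.samples, counts.library_sizes)
            if l <= 0
        ]
        raise ValueError(f"zero library size for samples {bad}")
    kb = counts.universe.lengths() / 1_000.0
    per_million = counts.library_sizes / 1e6
    values = counts.counts / (kb[:, None] * per_million[None, :])
    return NormalizedMatrix(counts.universe, counts.samples, values)


def merge_replicates(
    counts: CountMatrix, groups: Mapping[str, str] | None = None
) -> GroupMatrix:
    """Collapse replicates into groups by summing counts and library sizes.

    ``groups`` maps sample_id -> group; defaults to each entry's own group
    field.  Group RPKM is computed on the summed quantities.
    """
    if groups is None:
        groups = {s.sample_id: s.group for s in counts.samples}
    for s in counts.samples:
        if s.sample_id not in groups:
            raise ValueError(f"sample {s.sample_id!r} has no group assignment")
    group_names = sorted(set(groups[s.sample_id] for s in counts.samples))
    gidx = {g: j for j, g in enumerate(group_names)}
    R = len(counts.universe)
    gc = np.zeros((R, len(group_names)), dtype=np.int64)
    gl = np.zeros(len(group_names), dtype=np.int64)
    for j, s in enumerate(counts.samples):
        g = gidx[groups[s.sample_id]]
        gc[:, g] += counts.counts[:, j]
        gl[g] += counts.library_sizes[j]
    if (gl <= 0).any():
        raise ValueError("a group has zero total library size")
    kb = counts.universe.lengths() / 1_000.0
    gn = gc / (kb[:, None] * (gl / 1e6)[None, :])
    return GroupMatrix(counts.universe, group_names, gc, gl, gn)
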