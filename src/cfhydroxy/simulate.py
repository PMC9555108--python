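"""Synthetic multi-group cfDNA 5hmC datasets with known ground truth.

The generator emulates the observable outputs of a 5hmC enrichment
(hmC-CATCH-style) cfDNA study: a toy genome with non-overlapping gene
models and derived feature classes, a landscape of 5hmC-enriched regions
(hMRs) biased toward gene bodies, per-sample fragment sets with Poisson
counts and nucleosomal fragment lengths, C-to-T conversion tallies per
read, and 5hmC spike-in controls.  Group-specific differential regions
are planted with known direction and fold change so that every
downstream statistic can be scored against ground truth.

Default study design: six groups — five DLBCL primary sites (lymph node,
gastric, intestinal, testicular, CNS) and a healthy-control group — with
three replicates each, the smallest group size of the emulated cohort.

All randomness flows from ``SimConfig.seed`` through named per-stage
substreams, so any stage is reproducible in isolation and the full
fixture bundle is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    SampleSheetEntry,
    overlap_count,
    write_bed,
    write_bed12,
    write_sample_sheet,
)

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "SimTruth",
    "ConversionRecord",
    "SimulatedDataset",
    "rng_for",
    "simulate_annotation",
    "simulate_hmr_landscape",
    "simulate_sample",
    "simulate_spikeins",
    "simulate_count_matrix",
    "simulate_dataset",
    "write_fixture_bundle",
]

DEFAULT_GROUPS = (
    "LN-DLBCL",
    "PG-DLBCL",
    "PI-DLBCL",
    "PT-DLBCL",
    "PCNS-DLBCL",
    "Healthy",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Counts are Poisson by default (the distributional assumption of the
    downstream test); ``overdispersion`` > 0 gamma-mixes the per-region
    rates to stress-test robustness.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 20_000_000),
        ("chr3", 20_000_000),
    )
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 3
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    promoter_bp: int = 2_000
    tts_bp: int = 2_000
    n_hmrs: int = 10_000
    hmr_length_range: tuple[int, int] = (500, 1_500)
    gene_body_weight: float = 0.7
    baseline_mean_count: float = 50.0
    region_intensity_sigma: float = 0.5
    n_planted_per_group: int = 200
    planted_fold_change: float = 4.0
    planted_direction_mix: float = 0.5
    overdispersion: float = 0.0
    library_factor_range: tuple[float, float] = (0.8, 1.25)
    background_fraction: float = 0.1
    fragment_length_modes: tuple[tuple[float, float, float], ...] = ((167.0, 10.0, 1.0),)
    min_fragment_length: int = 30
    cytosines_per_read_mean: float = 10.0
    hmc_sites_per_read: int = 2
    conversion_rate_5hmc: float = 0.97
    false_conversion_rate: float = 0.005
    spikein_n_reads: int = 1_000
    spikein_sites_per_read: int = 10
    spikein_modified_fraction: float = 0.9
    spikein_input_modified_fraction: float = 0.5
    peak_call_min_count: int = 10

    def __post_init__(self) -> None:
        names = list(self.group_names)
        if len(set(names)) != len(names):
            raise ValueError("group_names must be unique")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        if self.n_planted_per_group * len(names) > self.n_hmrs:
            raise ValueError("n_planted_per_group exceeds n_hmrs / n_groups")
        for name, p in (
            ("planted_direction_mix", self.planted_direction_mix),
            ("conversion_rate_5hmc", self.conversion_rate_5hmc),
            ("false_conversion_rate", self.false_conversion_rate),
            ("background_fraction", self.background_fraction),
            ("spikein_modified_fraction", self.spikein_modified_fraction),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.spikein_input_modified_fraction < 1.0):
            raise ValueError("spikein_input_modified_fraction must be in (0, 1)")
        if self.planted_fold_change < 1.0:
            raise ValueError("planted_fold_change must be >= 1")
        for name, v in (
            ("n_genes", self.n_genes),
            ("n_hmrs", self.n_hmrs),
            ("spikein_n_reads", self.spikein_n_reads),
            ("n_planted_per_group", self.n_planted_per_group),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def genome_map(self) -> dict[str, int]:
        return {c: int(l) for c, l in self.genome}

    @property
    def genome_size(self) -> int:
        return sum(self.genome_map.values())

    def sample_id(self, group: str, replicate: int) -> str:
        return f"{group}_rep{replicate}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["group_names"] = list(self.group_names)
        d["gene_length_range"] = list(self.gene_length_range)
        d["hmr_length_range"] = list(self.hmr_length_range)
        d["library_factor_range"] = list(self.library_factor_range)
        d["fragment_length_modes"] = [list(m) for m in self.fragment_length_modes]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("gene_length_range", "hmr_length_range", "library_factor_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "genome" in d:
            d["genome"] = tuple((str(c), int(l)) for c, l in d["genome"])
        if "group_names" in d:
            d["group_names"] = tuple(d["group_names"])
        if "fragment_length_modes" in d:
            d["fragment_length_modes"] = tuple(tuple(m) for m in d["fragment_length_modes"])
        return cls(**d)


def rng_for(seed: int, *tags) -> np.random.Generator:
    """A named substream of the top-level seed.

    Stage substreams are independent of the order in which stages run: the
    spawn key is a CRC32 of the tag tuple, not a sequential counter.
    """
    key = zlib.crc32("/".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Truth containers


@dataclass(frozen=True)
class PlantedEffect:
    region: GenomicInterval
    group: str
    direction: str  # "gain" | "loss"
    fold_change: float

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be gain or loss")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")


@dataclass
class SimTruth:
    """Planted differential regions plus per-region baseline intensities."""

    planted: list[PlantedEffect]
    baseline_intensity: np.ndarray  # expected fragments/region/sample, pre library factor

    def __post_init__(self) -> None:
        seen = set()
        for p in self.planted:
            key = (p.region.chrom, p.region.start, p.region.end, p.group)
            if key in seen:
                raise ValueError("at most one planted effect per (region, group)")
            seen.add(key)

    def effect_matrix(self, universe: IntervalSet, groups: Sequence[str]) -> np.ndarray:
        """Multiplicative (region x group) effect: fc for gain, 1/fc for loss."""
        gidx = {g: j for j, g in enumerate(groups)}
        ridx = {
            (c, int(s), int(e)): i
            for i, (c, s, e) in enumerate(
                universe.df[["chrom", "start", "end"]].itertuples(index=False)
            )
        }
        eff = np.ones((len(universe), len(groups)))
        for p in self.planted:
            i = ridx[(p.region.chrom, p.region.start, p.region.end)]
            j = gidx[p.group]
            eff[i, j] = p.fold_change if p.direction == "gain" else 1.0 / p.fold_change
        return eff

    def planted_keys(self) -> set[tuple[str, int, int, str, str]]:
        return {
            (p.region.chrom, p.region.start, p.region.end, p.group, p.direction)
            for p in self.planted
        }

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted": [
                {
                    "chrom": p.region.chrom,
                    "start": p.region.start,
                    "end": p.region.end,
                    "group": p.group,
                    "direction": p.direction,
                    "fold_change": p.fold_change,
                }
                for p in self.planted
            ],
            "baseline_intensity": [float(x) for x in self.baseline_intensity],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            obj = json.load(fh)
        planted = [
            PlantedEffect(
                GenomicInterval(d["chrom"], d["start"], d["end"]),
                d["group"],
                d["direction"],
                d["fold_change"],
            )
            for d in obj["planted"]
        ]
        return cls(planted, np.asarray(obj["baseline_intensity"], dtype=float))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimTruth):
            return NotImplemented
        return (
            set(self.planted) == set(other.planted)
            and np.allclose(self.baseline_intensity, other.baseline_intensity)
        )


@dataclass(frozen=True)
class ConversionRecord:
    """Per-read cytosine conversion tally (the C-to-T 5hmC readout)."""

    read_id: str
    n_cytosines: int
    n_converted: int
    is_spikein: bool = False
    spikein_true_sites: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_converted <= self.n_cytosines):
            raise ValueError("require 0 <= n_converted <= n_cytosines")
        if self.spikein_true_sites < 0:
            raise ValueError("spikein_true_sites must be >= 0")


CONVERSION_COLUMNS = [
    "read_id",
    "n_cytosines",
    "n_converted",
    "is_spikein",
    "spikein_true_sites",
]


def conversion_frame(records) -> pd.DataFrame:
    """Build a conversion table from ConversionRecord objects or tuples."""
    rows = []
    for r in records:
        if isinstance(r, ConversionRecord):
            rows.append(
                (r.read_id, r.n_cytosines, r.n_converted, r.is_spikein, r.spikein_true_sites)
            )
        else:
            rows.append(tuple(r))
    return pd.DataFrame(rows, columns=CONVERSION_COLUMNS)


# ---------------------------------------------------------------------------
# Annotation


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_len: int, lengths: np.ndarray, margin: int
) -> np.ndarray:
    """Start positions for blocks of given lengths, separated by >= margin.

    Deterministic single pass: the free space left after reserving all blocks
    and margins is split into random gaps (Dirichlet), so placement never
    needs rejection retries.
    """
    k = len(lengths)
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    reserved = int(lengths.sum()) + margin * (k + 1)
    free = chrom_len - reserved
    if free < 0:
        raise ValueError(
            "genome too small for requested placement; increase chromosome sizes"
        )
    gaps = rng.dirichlet(np.ones(k + 1)) * free
    gaps = np.floor(gaps).astype(np.int64)
    starts = np.zeros(k, dtype=np.int64)
    pos = margin
    for i in range(k):
        pos += int(gaps[i])
        starts[i] = pos
        pos += int(lengths[i]) + margin
    return starts


def simulate_annotation(
    config: SimConfig,
) -> tuple[list[GeneModel], dict[str, IntervalSet]]:
    """Toy gene models plus derived, mutually disjoint feature classes.

    Genes are spaced at least ``promoter_bp + tts_bp`` apart (plus a small
    buffer) so promoter/exon/intron/TTS/intergenic genuinely partition the
    genome — the analytic expected fractions used by enrichment scoring are
    then exact.
    """
    rng = rng_for(config.seed, "annotation")
    genome = config.genome_map
    chroms = list(genome)
    margin = config.promoter_bp + config.tts_bp + 500

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    # round-robin genes over chromosomes proportionally to length
    weights = np.array([genome[c] for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=config.n_genes, p=weights / weights.sum())

    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        lens_c = lengths[assignment == ci]
        starts = _place_nonoverlapping(rng, genome[chrom], lens_c, margin)
        for s, L in zip(starts, lens_c):
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 9))
            # 2*n_exons - 2 internal breakpoints; segments alternate exon/intron,
            # first and last segments exonic
            inner = np.sort(rng.choice(np.arange(1, L), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate(([0], inner, [L]))
            exons = tuple(
                (int(s + bounds[i]), int(s + bounds[i + 1]))
                for i in range(0, 2 * n_exons - 1, 2)
            )
            genes.append(
                GeneModel(chrom, strand, int(s), int(s + L), exons, f"gene{gi:04d}")
            )
            gi += 1
    genes.sort(key=lambda g: (g.chrom, g.tx_start))

    features = derive_feature_classes(genes, genome, config.promoter_bp, config.tts_bp)
    return genes, features


def derive_feature_classes(
    genes: Sequence[GeneModel],
    genome: Mapping[str, int],
    promoter_bp: int,
    tts_bp: int,
) -> dict[str, IntervalSet]:
    """Promoter / exon / intron / TTS windows and the intergenic complement."""
    prom, tts, exon, intron = [], [], [], []
    for g in genes:
        if g.strand == "+":
            p = (g.chrom, max(0, g.tx_start - promoter_bp), g.tx_start)
            t = (g.chrom, g.tx_end, min(genome[g.chrom], g.tx_end + tts_bp))
        else:
            p = (g.chrom, g.tx_end, min(genome[g.chrom], g.tx_end + promoter_bp))
            t = (g.chrom, max(0, g.tx_start - tts_bp), g.tx_start)
        if p[1] < p[2]:
            prom.append(p)
        if t[1] < t[2]:
            tts.append(t)
        exon.extend((g.chrom, s, e) for s, e in g.exons)
        intron.extend((g.chrom, s, e) for s, e in g.introns())

    covered = IntervalSet(prom + tts + exon + intron).merge()
    inter = []
    per = covered.per_chrom()
    for chrom, size in genome.items():
        if chrom in per:
            starts, ends = per[chrom]
            prev = 0
            for s, e in zip(starts, ends):
                if prev < s:
                    inter.append((chrom, prev, int(s)))
                prev = int(e)
            if prev < size:
                inter.append((chrom, prev, size))
        else:
            inter.append((chrom, 0, size))

    return {
        "promoter": IntervalSet(prom, label="promoter"),
        "exon": IntervalSet(exon, label="exon"),
        "intron": IntervalSet(intron, label="intron"),
        "tts": IntervalSet(tts, label="tts"),
        "intergenic": IntervalSet(inter, label="intergenic"),
    }


# ---------------------------------------------------------------------------
# hMR landscape


def simulate_hmr_landscape(
    config: SimConfig, annotation: tuple[list[GeneModel], dict[str, IntervalSet]]
) -> tuple[IntervalSet, SimTruth]:
    """Non-overlapping hMR universe, gene-body biased, with planted effects.

    With probability ``gene_body_weight`` a region midpoint is drawn inside a
    gene body, otherwise uniformly on the genome; candidates that would
    overlap an accepted region are redrawn (bounded rounds).
    """
    rng = rng_for(config.seed, "landscape")
    genes, _features = annotation
    genome = config.genome_map
    chroms = list(genome)
    chrom_sizes = np.array([genome[c] for c in chroms], dtype=np.int64)
    chrom_offsets = np.concatenate(([0], np.cumsum(chrom_sizes)))
    gsize = int(chrom_sizes.sum())

    gene_chrom = np.array([chroms.index(g.chrom) for g in genes], dtype=np.int64) if genes else np.zeros(0, np.int64)
    gene_start = np.array([g.tx_start for g in genes], dtype=np.int64)
    gene_len = np.array([g.length for g in genes], dtype=np.int64)
    gene_cum = np.concatenate(([0], np.cumsum(gene_len)))
    total_gene = int(gene_cum[-1])

    lo, hi = config.hmr_length_range
    accepted: list[tuple[int, int, int]] = []  # (chrom_idx, start, end), genome-linear kept separately
    occupied_s: list[int] = []  # linear coordinates of accepted, kept sorted per round
    occupied_e: list[int] = []

    need = config.n_hmrs
    for _round in range(200):
        if need <= 0:
            break
        m = max(need * 2, 64)
        lens = rng.integers(lo, hi + 1, size=m)
        use_gene = (rng.random(m) < config.gene_body_weight) & (total_gene > 0)
        mids = np.empty(m, dtype=np.int64)
        # gene-body draws: uniform over concatenated gene bases
        ng = int(use_gene.sum())
        if ng:
            u = rng.integers(0, total_gene, size=ng)
            gi = np.searchsorted(gene_cum, u, side="right") - 1
            within = u - gene_cum[gi]
            mids[use_gene] = (
                chrom_offsets[gene_chrom[gi]] + gene_start[gi] + within
            )
        nu = m - ng
        if nu:
            mids[~use_gene] = rng.integers(0, gsize, size=nu)
        starts = mids - lens // 2
        ends = starts + lens
        # keep inside one chromosome
        ci = np.searchsorted(chrom_offsets, mids, side="right") - 1
        ok = (starts >= chrom_offsets[ci]) & (ends <= chrom_offsets[ci + 1])
        starts, ends, ci = starts[ok], ends[ok], ci[ok]
        # drop overlaps with accepted set
        if occupied_s:
            os_arr = np.array(occupied_s)
            oe_arr = np.array(occupied_e)
            order = np.argsort(os_arr)
            os_arr, oe_arr = os_arr[order], oe_arr[order]
            oe_sorted = np.sort(oe_arr)
            a = np.searchsorted(os_arr, ends, side="left")
            b = np.searchsorted(oe_sorted, starts, side="right")
            ok = (a - b) == 0
            starts, ends, ci = starts[ok], ends[ok], ci[ok]
        # drop overlaps within the batch (greedy by start)
        order = np.argsort(starts, kind="mergesort")
        keep_idx = []
        last_end = -1
        for idx in order:
            if starts[idx] >= last_end:
                keep_idx.append(idx)
                last_end = ends[idx]
        keep_idx = np.array(keep_idx[:need], dtype=np.int64)
        for idx in keep_idx:
            accepted.append((int(ci[idx]), int(starts[idx]), int(ends[idx])))
            occupied_s.append(int(starts[idx]))
            occupied_e.append(int(ends[idx]))
        need = config.n_hmrs - len(accepted)
    if need > 0:
        raise ValueError(
            "could not place requested hMRs without overlap; enlarge the genome"
        )

    rows = [
        (chroms[c], int(s - chrom_offsets[c]), int(e - chrom_offsets[c]))
        for c, s, e in accepted
    ]
    universe = IntervalSet(rows, label="simulated_hmrs")

    # planted effects: disjoint region sets per group, round-robin over a
    # single permutation so no region carries two effects
    n_eff = config.n_planted_per_group * config.n_groups
    perm = rng.permutation(len(universe))[:n_eff]
    planted = []
    regions = [universe[int(i)] for i in perm]
    for j, group in enumerate(config.group_names):
        for r in regions[
            j * config.n_planted_per_group : (j + 1) * config.n_planted_per_group
        ]:
            direction = "gain" if rng.random() < config.planted_direction_mix else "loss"
            planted.append(
                PlantedEffect(
                    GenomicInterval(r.chrom, r.start, r.end),
                    group,
                    direction,
                    config.planted_fold_change,
                )
            )

    intensity = config.baseline_mean_count * np.exp(
        rng.normal(0.0, config.region_intensity_sigma, size=len(universe))
        - 0.5 * config.region_intensity_sigma**2
    )
    return universe, SimTruth(planted, intensity)


# ---------------------------------------------------------------------------
# Samples


def _library_factor(config: SimConfig, group: str, replicate: int) -> float:
    rng = rng_for(config.seed, "libfactor", group, replicate)
    lo, hi = config.library_factor_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_fragment_lengths(
    rng: np.random.Generator, config: SimConfig, n: int
) -> np.ndarray:
    modes = np.asarray(config.fragment_length_modes, dtype=float)
    w = modes[:, 2] / modes[:, 2].sum()
    which = rng.choice(len(modes), size=n, p=w)
    lens = rng.normal(modes[which, 0], modes[which, 1])
    return np.maximum(np.rint(lens).astype(np.int64), config.min_fragment_length)


def simulate_sample(
    config: SimConfig,
    universe: IntervalSet,
    truth: SimTruth,
    group: str,
    replicate: int,
    with_conversions: bool = True,
) -> tuple[IntervalSet, pd.DataFrame]:
    """Fragments and per-read conversion tallies for one sample.

    Per-region fragment counts are Poisson with mean
    ``baseline_intensity * group_effect * library_factor``; fragment
    midpoints are uniform within the region, lengths follow the configured
    nucleosomal mixture.  A ``background_fraction`` of the library is
    genome-wide uniform.  Reads inside hMRs convert at their 5hmC sites with
    rate ``conversion_rate_5hmc``; all other cytosines convert at the false
    rate.
    """
    if group not in config.group_names:
        raise ValueError(f"unknown group {group!r}")
    rng = rng_for(config.seed, "sample", group, replicate)
    lib = _library_factor(config, group, replicate)
    genome = config.genome_map
    chroms = list(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=np.int64)

    eff = truth.effect_matrix(universe, config.group_names)[
        :, list(config.group_names).index(group)
    ]
    mean = truth.baseline_intensity[: len(universe)] * eff * lib
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mean = mean * rng.gamma(shape, 1.0 / shape, size=len(mean))
    counts = rng.poisson(mean)

    starts_u = universe.df["start"].to_numpy()
    lens_u = universe.df["end"].to_numpy() - starts_u
    chrom_u = universe.df["chrom"].to_numpy()

    ridx = np.repeat(np.arange(len(universe)), counts)
    mids = starts_u[ridx] + (rng.random(len(ridx)) * lens_u[ridx]).astype(np.int64)
    frag_chrom = chrom_u[ridx]
    in_region = np.ones(len(ridx), dtype=bool)

    # genome-wide background
    total_mean = float(mean.sum())
    bf = config.background_fraction
    n_bg = rng.poisson(total_mean * bf / (1.0 - bf)) if bf > 0 and total_mean > 0 else 0
    if n_bg:
        bci = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
        bpos = (rng.random(n_bg) * sizes[bci]).astype(np.int64)
        frag_chrom = np.concatenate([frag_chrom, np.array(chroms, dtype=object)[bci]])
        mids = np.concatenate([mids, bpos])
        in_region = np.concatenate([in_region, np.zeros(n_bg, dtype=bool)])

    n = len(mids)
    lens = _draw_fragment_lengths(rng, config, n)
    fs = np.maximum(mids - lens // 2, 0)
    fe = fs + lens
    size_of = np.array([genome[c] for c in frag_chrom], dtype=np.int64)
    fe = np.minimum(fe, size_of)
    fs = np.minimum(fs, fe - 1)  # keep non-empty after clipping

    sample = config.sample_id(group, replicate)
    read_ids = np.array([f"{sample}:frag{i:07d}" for i in range(n)], dtype=object)
    fragments = IntervalSet(
        pd.DataFrame(
            {"chrom": frag_chrom, "start": fs, "end": fe, "name": read_ids, "strand": "."}
        ),
        label=sample,
    )

    if not with_conversions:
        return fragments, pd.DataFrame(columns=CONVERSION_COLUMNS)

    sites = np.where(in_region, config.hmc_sites_per_read, 0)
    extra = rng.poisson(
        max(config.cytosines_per_read_mean - config.hmc_sites_per_read, 0.0), size=n
    )
    n_cyt = sites + extra
    conv_true = rng.binomial(sites, config.conversion_rate_5hmc)
    conv_false = rng.binomial(n_cyt - sites, config.false_conversion_rate)
    conversions = pd.DataFrame(
        {
            "read_id": read_ids,
            "n_cytosines": n_cyt,
            "n_converted": conv_true + conv_false,
            "is_spikein": False,
            "spikein_true_sites": 0,
        }
    )
    return fragments, conversions


def simulate_spikeins(config: SimConfig) -> pd.DataFrame:
    """Spike-in control reads after enrichment.

    A ``spikein_modified_fraction`` of reads carry known 5hmC sites that
    convert at the true rate; the unmodified remainder converts at the false
    rate only.
    """
    rng = rng_for(config.seed, "spikeins")
    n = config.spikein_n_reads
    if n == 0:
        return pd.DataFrame(columns=CONVERSION_COLUMNS)
    n_mod = int(round(config.spikein_modified_fraction * n))
    sites = config.spikein_sites_per_read
    conv_mod = rng.binomial(sites, config.conversion_rate_5hmc, size=n_mod)
    conv_unmod = rng.binomial(sites, config.false_conversion_rate, size=n - n_mod)
    return pd.DataFrame(
        {
            "read_id": [f"spikein{i:05d}" for i in range(n)],
            "n_cytosines": sites,
            "n_converted": np.concatenate([conv_mod, conv_unmod]),
            "is_spikein": True,
            "spikein_true_sites": np.concatenate(
                [np.full(n_mod, sites), np.zeros(n - n_mod, dtype=int)]
            ),
        }
    )


# ---------------------------------------------------------------------------
# Count-level shortcut and full dataset


def simulate_count_matrix(
    config: SimConfig,
    universe: IntervalSet | None = None,
    truth: SimTruth | None = None,
):
    """Per-sample region counts drawn directly at the count level.

    Skips fragment materialisation; used where only the counting model
    matters (calibration and power studies).  Returns a
    :class:`cfhydroxy.quant.CountMatrix` whose library sizes include the
    background the fragment path would have added.
    """
    from .quant import CountMatrix, RegionUniverse

    if universe is None or truth is None:
        annotation = simulate_annotation(config)
        universe, truth = simulate_hmr_landscape(config, annotation)
    eff = truth.effect_matrix(universe, config.group_names)
    samples = []
    cols = []
    libs = []
    for group in config.group_names:
        j = list(config.group_names).index(group)
        for rep in range(1, config.replicates_per_group + 1):
            rng = rng_for(config.seed, "countmat", group, rep)
            lib = _library_factor(config, group, rep)
            mean = truth.baseline_intensity[: len(universe)] * eff[:, j] * lib
            if config.overdispersion > 0:
                shape = 1.0 / config.overdispersion
                mean = mean * rng.gamma(shape, 1.0 / shape, size=len(mean))
            c = rng.poisson(mean)
            cols.append(c)
            bf = config.background_fraction
            bg = float(mean.sum()) * bf / (1.0 - bf) if bf > 0 else 0.0
            libs.append(int(c.sum() + round(bg)))
            samples.append(
                SampleSheetEntry(config.sample_id(group, rep), group, rep)
            )
    counts = np.column_stack(cols)
    ru = RegionUniverse(universe, "merged_hmr", {"source": "simulate_count_matrix"})
    return CountMatrix(ru, samples, counts, np.array(libs, dtype=np.int64))


@dataclass
class SimulatedDataset:
    """Everything one synthetic study produces, held in memory."""

    config: SimConfig
    genes: list[GeneModel]
    features: dict[str, IntervalSet]
    universe: IntervalSet
    truth: SimTruth
    samples: list[SampleSheetEntry]
    fragments: dict[str, IntervalSet]
    conversions: dict[str, pd.DataFrame]
    peaks: dict[str, IntervalSet]
    spikeins: pd.DataFrame


def _call_peaks(
    config: SimConfig, universe: IntervalSet, fragments: IntervalSet
) -> IntervalSet:
    """Stand-in for upstream peak calling: regions whose fragment count
    reaches ``peak_call_min_count`` in this sample."""
    counts = overlap_count(universe, fragments)
    keep = counts >= config.peak_call_min_count
    return IntervalSet(universe.df.loc[keep, ["chrom", "start", "end"]], label="peaks")


def simulate_dataset(config: SimConfig, with_conversions: bool = True) -> SimulatedDataset:
    """Run the full generator for every sample of the configured design."""
    annotation = simulate_annotation(config)
    genes, features = annotation
    universe, truth = simulate_hmr_landscape(config, annotation)
    samples, fragments, conversions, peaks = [], {}, {}, {}
    for group in config.group_names:
        for rep in range(1, config.replicates_per_group + 1):
            sid = config.sample_id(group, rep)
            frags, conv = simulate_sample(
                config, universe, truth, group, rep, with_conversions=with_conversions
            )
            fragments[sid] = frags
            conversions[sid] = conv
            peaks[sid] = _call_peaks(config, universe, frags)
            samples.append(SampleSheetEntry(sid, group, rep))
    return SimulatedDataset(
        config,
        genes,
        features,
        universe,
        truth,
        samples,
        fragments,
        conversions,
        peaks,
        simulate_spikeins(config),
    )


# ---------------------------------------------------------------------------
# Fixture bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(
    config: SimConfig, out_dir: str | Path, dataset: SimulatedDataset | None = None
) -> dict:
    """Write the complete synthetic study to disk; returns the manifest.

    Layout: genome table, BED12 genes, per-class feature BEDs, per-sample
    fragment/peak BEDs and conversion TSVs, spike-in TSV, sample sheet,
    truth JSON, config YAML, and a manifest with SHA-256 checksums.
    Identical configs produce byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = dataset if dataset is not None else simulate_dataset(config)

    written: list[Path] = []

    def emit(relpath: str, writer) -> Path:
        p = out / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        writer(p)
        written.append(p)
        return p

    emit(
        "genome.tsv",
        lambda p: pd.DataFrame(config.genome, columns=["chrom", "length"]).to_csv(
            p, sep="\t", index=False
        ),
    )
    emit("genes.bed12", lambda p: write_bed12(ds.genes, p))
    for cls, iset in sorted(ds.features.items()):
        emit(f"features/{cls}.bed", lambda p, s=iset: write_bed(s, p))
    emit("hmr_universe.bed", lambda p: write_bed(ds.universe, p))

    entries = []
    for e in ds.samples:
        sid = e.sample_id
        emit(f"samples/{sid}.fragments.bed", lambda p, s=ds.fragments[sid]: write_bed(s, p))
        emit(f"samples/{sid}.peaks.bed", lambda p, s=ds.peaks[sid]: write_bed(s, p))
        emit(
            f"samples/{sid}.conversions.tsv",
            lambda p, d=ds.conversions[sid]: d.to_csv(p, sep="\t", index=False),
        )
        # paths are bundle-relative so bundles are portable and byte-stable
        entries.append(
            SampleSheetEntry(
                sid,
                e.group,
                e.replicate,
                f"samples/{sid}.fragments.bed",
                f"samples/{sid}.peaks.bed",
            )
        )
    emit("spikeins.tsv", lambda p: ds.spikeins.to_csv(p, sep="\t", index=False))
    emit("sample_sheet.tsv", lambda p: write_sample_sheet(entries, p))
    emit("truth.json", lambda p: ds.truth.to_json(p))
    emit(
        "config.yaml",
        lambda p: p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True)),
    )

    manifest = {
        "n_samples": len(ds.samples),
        "n_hmrs": len(ds.universe),
        "files": [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in written
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
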