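"""Genomic-context characterisation of hMRs and 5hmC signal.

Four views of where the 5hmC signal sits, plus a separability statistic
for the differential-region matrix:

* class assignment of hMRs (promoter/exon/intron/TTS/intergenic pie),
* observed-vs-expected enrichment scores per class,
* metagene profiles (gene bodies rescaled to a fixed bin grid, flanks in
  fixed-width bins, minus-strand genes reversed so bin 0 is upstream of
  the TSS),
* profiles of mark coverage centred on region midpoints (histone-mark
  context of distal hMRs),
* silhouette-based group separability of per-sample log-RPKM vectors
  (any 2-D embedding such as t-SNE is presentation only; the statistic
  lives in the full-dimensional distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances, silhouette_score

from .intervals import GeneModel, IntervalSet, feature_fraction, merge_intervals

__all__ = [
    "DEFAULT_PRIORITY",
    "FeatureDistribution",
    "EnrichmentScores",
    "MetageneProfile",
    "CenteredProfile",
    "feature_distribution",
    "enrichment_scores",
    "metagene_profile",
    "centered_profile",
    "separability",
]

#: hMR-to-class priority when a midpoint could belong to several classes.
DEFAULT_PRIORITY = ("promoter", "exon", "intron", "tts", "intergenic")


@dataclass
class FeatureDistribution:
    table: pd.DataFrame  # columns: class, n_assigned, fraction

    def fraction(self, cls: str) -> float:
        row = self.table.loc[self.table["class"] == cls, "fraction"]
        return float(row.iloc[0]) if len(row) else 0.0


@dataclass
class EnrichmentScores:
    table: pd.DataFrame  # columns: class, observed, expected, score

    def score(self, cls: str) -> float:
        row = self.table.loc[self.table["class"] == cls, "score"]
        return float(row.iloc[0]) if len(row) else float("nan")


@dataclass
class MetageneProfile:
    values: np.ndarray  # length 2*n_flank_bins + n_body_bins
    n_body_bins: int
    n_flank_bins: int
    flank_bp: int
    n_genes_used: int
    group: str = ""

    def body(self) -> np.ndarray:
        return self.values[self.n_flank_bins : self.n_flank_bins + self.n_body_bins]

    def flanks(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.values[: self.n_flank_bins],
            self.values[self.n_flank_bins + self.n_body_bins :],
        )


@dataclass
class CenteredProfile:
    offsets: np.ndarray  # bin centres relative to region midpoint (bp)
    values: np.ndarray  # mean fraction of bin covered by marks
    half_window: int
    bin_size: int
    n_queries: int


# ---------------------------------------------------------------------------
# Membership helpers


def _membership_lookup(features: IntervalSet):
    """chrom -> (starts, ends) of the merged class, for midpoint tests."""
    return merge_intervals(features).per_chrom()


def _midpoints_in(per_chrom, chroms: np.ndarray, mids: np.ndarray) -> np.ndarray:
    out = np.zeros(len(mids), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in per_chrom:
            continue
        starts, ends = per_chrom[chrom]
        sel = chroms == chrom
        m = mids[sel]
        idx = np.searchsorted(starts, m, side="right") - 1
        ok = (idx >= 0) & (m < ends[np.clip(idx, 0, len(ends) - 1)])
        out[sel] = ok
    return out


def feature_distribution(
    hmrs: IntervalSet,
    features: Mapping[str, IntervalSet],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    fallback: str = "intergenic",
) -> FeatureDistribution:
    """Assign every hMR to exactly one class by midpoint and priority.

    An hMR belongs to the highest-priority class whose (merged) intervals
    contain its midpoint; anything left over falls back to ``fallback``.
    Fractions sum to 1 by construction.
    """
    for cls in features:
        if cls not in priority:
            raise ValueError(f"priority order does not cover class {cls!r}")
    n = len(hmrs)
    chroms = hmrs.df["chrom"].to_numpy()
    mids = ((hmrs.df["start"] + hmrs.df["end"]) // 2).to_numpy()
    assigned = np.full(n, "", dtype=object)
    for cls in priority:
        if cls not in features:
            continue
        free = assigned == ""
        if not free.any():
            break
        hit = _midpoints_in(_membership_lookup(features[cls]), chroms[free], mids[free])
        idx = np.flatnonzero(free)[hit]
        assigned[idx] = cls
    assigned[assigned == ""] = fallback
    rows = []
    for cls in priority:
        if cls not in features and cls != fallback:
            continue
        k = int((assigned == cls).sum())
        rows.append({"class": cls, "n_assigned": k, "fraction": k / n if n else 0.0})
    return FeatureDistribution(pd.DataFrame(rows))


def enrichment_scores(
    hmrs: IntervalSet,
    features: Mapping[str, IntervalSet],
    genome_size,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    epsilon: float = 0.5,
) -> EnrichmentScores:
    """Observed vs expected class counts, scored as log2 ratios.

    Expected counts come analytically from the genome fraction each class
    occupies (uniform-placement null); ``epsilon`` guards empty classes.
    Positive scores mean enrichment above a uniform placement.
    """
    dist = feature_distribution(hmrs, features, priority=priority)
    n = len(hmrs)
    rows = []
    for _, r in dist.table.iterrows():
        cls = r["class"]
        frac = feature_fraction(features[cls], genome_size)
        expected = n * frac
        observed = int(r["n_assigned"])
        if frac == 0.0 and observed > 0:
            warnings.warn(f"class {cls!r} has zero genome fraction but nonzero hMRs")
            score = float("inf")
        else:
            score = float(np.log2((observed + epsilon) / (expected + epsilon)))
        rows.append(
            {"class": cls, "observed": observed, "expected": expected, "score": score}
        )
    return EnrichmentScores(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Metagene and centred profiles


def metagene_profile(
    fragments: IntervalSet,
    genes: Sequence[GeneModel],
    n_body_bins: int = 100,
    flank_bp: int = 2000,
    n_flank_bins: int = 20,
    library_size: int | None = None,
    group: str = "",
) -> MetageneProfile:
    """Mean fragment density over a scaled gene-body grid with fixed flanks.

    Each gene body is rescaled to ``n_body_bins``; flanks use fixed-width
    bins.  Signal is fragment-midpoint density per bp, per million
    fragments, averaged over genes; minus-strand genes are reversed so the
    profile always reads TSS -> TTS.  Genes shorter than ``n_body_bins`` bp
    are skipped with a warning.
    """
    if not genes:
        raise ValueError("metagene_profile requires >= 1 gene")
    lib = library_size if library_size is not None else len(fragments)
    scale = 1e6 / lib if lib > 0 else 0.0
    mids_by_chrom = {}
    for chrom, (starts, ends) in fragments.per_chrom().items():
        mids_by_chrom[chrom] = np.sort((starts + ends) // 2)

    n_bins = 2 * n_flank_bins + n_body_bins
    acc = np.zeros(n_bins)
    used = 0
    skipped = 0
    flank_w = flank_bp / n_flank_bins
    for g in genes:
        if g.length < n_body_bins:
            skipped += 1
            continue
        up = np.linspace(g.tx_start - flank_bp, g.tx_start, n_flank_bins + 1)
        body = np.linspace(g.tx_start, g.tx_end, n_body_bins + 1)
        down = np.linspace(g.tx_end, g.tx_end + flank_bp, n_flank_bins + 1)
        edges = np.concatenate([up[:-1], body, down[1:]])
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            counts = np.zeros(n_bins)
        else:
            cum = np.searchsorted(mids, edges)
            counts = np.diff(cum).astype(float)
        widths = np.diff(edges)
        dens = counts / widths
        if g.strand == "-":
            dens = dens[::-1]
        acc += dens
        used += 1
    if used == 0:
        raise ValueError("no gene long enough for the requested body bins")
    if skipped:
        warnings.warn(f"skipped {skipped} genes shorter than n_body_bins bp")
    values = acc / used * scale
    return MetageneProfile(values, n_body_bins, n_flank_bins, flank_bp, used, group)


def _coverage_function(marks: IntervalSet):
    """Per-chromosome cumulative-coverage evaluator C(x) for merged marks."""
    merged = merge_intervals(marks).per_chrom()
    tables = {}
    for chrom, (starts, ends) in merged.items():
        lens = ends - starts
        cum_before = np.concatenate(([0], np.cumsum(lens)))
        tables[chrom] = (starts, ends, cum_before)

    def cov(chrom: str, x: np.ndarray) -> np.ndarray:
        """Covered bases in [-inf, x) for each x."""
        if chrom not in tables:
            return np.zeros(len(x))
        starts, ends, cum_before = tables[chrom]
        i = np.searchsorted(starts, x, side="right") - 1
        i_cl = np.clip(i, 0, len(starts) - 1)
        partial = np.clip(x - starts[i_cl], 0, ends[i_cl] - starts[i_cl])
        out = np.where(i >= 0, cum_before[i_cl] + partial, 0.0)
        return out

    return cov


def centered_profile(
    query: IntervalSet,
    marks: IntervalSet,
    half_window: int = 5000,
    bin_size: int = 100,
    tss_positions: IntervalSet | Mapping[str, np.ndarray] | None = None,
    distal_min_bp: int | None = None,
) -> CenteredProfile:
    """Mean mark coverage per bin around query-region midpoints.

    Each bin value is the fraction of its bases covered by the (merged)
    mark set, averaged over query regions; the grid is symmetric around the
    midpoint.  When ``tss_positions`` and ``distal_min_bp`` are given, only
    queries farther than that distance from every TSS are used ("distal"
    regions, default convention > 10 kb).
    """
    if len(query) == 0:
        raise ValueError("centered_profile requires a non-empty query set")
    qdf = query.df
    chroms = qdf["chrom"].to_numpy()
    mids = ((qdf["start"] + qdf["end"]) // 2).to_numpy()

    if tss_positions is not None and distal_min_bp is not None:
        if isinstance(tss_positions, IntervalSet):
            tss_map = {
                c: np.sort((s + e) // 2)
                for c, (s, e) in tss_positions.per_chrom().items()
            }
        else:
            tss_map = {c: np.sort(np.asarray(v)) for c, v in tss_positions.items()}
        keep = np.ones(len(mids), dtype=bool)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            tss = tss_map.get(chrom)
            if tss is None or len(tss) == 0:
                continue
            m = mids[sel]
            i = np.clip(np.searchsorted(tss, m), 1, len(tss) - 1)
            d = np.minimum(np.abs(m - tss[i - 1]), np.abs(m - tss[np.minimum(i, len(tss) - 1)]))
            keep[sel] = d > distal_min_bp
        chroms, mids = chroms[keep], mids[keep]
        if len(mids) == 0:
            raise ValueError("no query region passes the distal filter")

    edges_rel = np.arange(-half_window, half_window + bin_size, bin_size)
    n_bins = len(edges_rel) - 1
    cov = _coverage_function(marks)
    acc = np.zeros(n_bins)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        m = mids[sel]
        edges_abs = m[:, None] + edges_rel[None, :]
        c = cov(chrom, edges_abs.ravel()).reshape(edges_abs.shape)
        acc += (np.diff(c, axis=1) / bin_size).sum(axis=0)
    values = acc / len(mids)
    centres = (edges_rel[:-1] + edges_rel[1:]) / 2
    return CenteredProfile(centres, values, half_window, bin_size, len(mids))


# ---------------------------------------------------------------------------
# Separability


def separability(
    norm_values: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """Group separability of per-sample signal vectors.

    Rows of ``norm_values`` are regions (typically the significant
    psDhMRs), columns are samples.  Samples become log2(RPKM + 1) vectors;
    the statistic is the mean silhouette of the group labelling under
    Euclidean distance.  Returns (distance matrix, mean silhouette).
    """
    if isinstance(norm_values, pd.DataFrame):
        sample_ids = list(norm_values.columns)
        values = norm_values.to_numpy(dtype=float)
    else:
        values = np.asarray(norm_values, dtype=float)
        sample_ids = [f"sample{j}" for j in range(values.shape[1])]
    labels = list(labels)
    if values.shape[0] < 2:
        raise ValueError("separability needs >= 2 regions")
    if len(labels) != values.shape[1]:
        raise ValueError("one label per sample required")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    X = np.log2(values + 1.0).T  # samples x regions
    if np.allclose(X, X[0]):
        raise ValueError("degenerate (constant) matrix: silhouette undefined")
    D = pairwise_distances(X, metric="euclidean")
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    dist = pd.DataFrame(D, index=sample_ids, columns=sample_ids)
    return dist, sil
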