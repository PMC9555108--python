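"""One-tailed Poisson differential 5hmC regions (psDhMRs / DhMRs).

The statistic: for each region and each focal group, the group-summed
fragment count ``k`` is compared against a Poisson null whose mean is the
average of the other groups' counts rescaled to the focal group's library
size,

    lambda_g = mean over others o of ( k_o * L_g / L_o ),

with the upper tail P(X >= k) when k > lambda and the lower tail
P(X <= k) otherwise.  P-values are Bonferroni-adjusted over the full
(region x group) family; a region is called when the adjusted p falls
below alpha *and* the group-RPKM fold change is at least ``fc_min`` (gain)
or at most ``1/fc_min`` (loss).

The Poisson test runs on integer counts; RPKM enters only through the
fold change (a Poisson likelihood on RPKM values would be ill-defined).
``lambda`` is a plug-in estimate, so raw p-values are mildly
anti-conservative relative to a known-mean Poisson — the fold-change
threshold, not the p-value alone, is what keeps the caller honest; see
the methods note for the calibration analysis.

Organisation follows the fitted-model idiom: build a
:class:`PoissonDifferentialModel` from a :class:`~cfhydroxy.quant.GroupMatrix`
(or a count matrix plus sample sheet), call :meth:`fit` or
:meth:`fit_contrast`, and read estimates, p-values and tallies off the
returned :class:`PoissonDifferentialResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet
from .quant import CountMatrix, GroupMatrix, merge_replicates

__all__ = [
    "poisson_tail",
    "bonferroni",
    "PoissonDifferentialModel",
    "PoissonDifferentialResults",
    "psdhmr_test",
    "two_group_test",
    "summarize_calls",
    "PRESETS",
]

#: The two published threshold conventions for calling differential regions.
PRESETS = {
    "methods": {"alpha": 0.05, "fc_min": 2.0, "adjustment": "bonferroni"},
    "results": {"alpha": 0.01, "fc_min": 2.0, "adjustment": "none"},
}


def poisson_tail(k, lam, tail: str = "upper"):
    """Exact Poisson tail probability, stable to lambda ~ 1e6.

    upper: P(X >= k); lower: P(X <= k), for X ~ Poisson(lam).  Accepts
    scalars or arrays.  Evaluated through the survival function / CDF, so
    no explicit pmf summation is ever formed.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    if np.any(lam_arr < 0) or not np.all(np.isfinite(lam_arr)):
        raise ValueError("lambda must be finite and >= 0")
    if not np.issubdtype(k_arr.dtype, np.integer):
        if not np.all(k_arr == np.floor(k_arr)):
            raise ValueError("k must be integral")
        k_arr = k_arr.astype(np.int64)
    if tail == "upper":
        out = stats.poisson.sf(k_arr - 1, lam_arr)
    elif tail == "lower":
        out = stats.poisson.cdf(k_arr, lam_arr)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return float(out) if np.isscalar(k) and np.isscalar(lam) else out


def bonferroni(p_values, m: int | None = None):
    """Family-wise adjustment: p -> min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, p * m)


@dataclass
class PoissonDifferentialResults:
    """Estimates, p-values and calls from a fitted differential model.

    ``frame`` holds one row per (region, focal group): observed count,
    null mean, RPKM fold change, direction, raw and adjusted p, call flag.
    """

    model: "PoissonDifferentialModel"
    frame: pd.DataFrame
    params: dict

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    def significant(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["significant"]].copy()

    def significant_regions(self, group: str | None = None) -> IntervalSet:
        sig = self.significant()
        if group is not None:
            sig = sig.loc[sig["group"] == group]
        return IntervalSet(
            sig[["chrom", "start", "end"]].drop_duplicates(), label="significant"
        )

    def group_summary(self) -> pd.DataFrame:
        """Per-group gain/loss tallies and region uniqueness.

        A region is unique to a group when it is significant in exactly one
        group of this call set.
        """
        sig = self.significant()
        groups = self.params["groups"]
        rid_counts = sig.groupby("region_id")["group"].nunique()
        unique_rids = set(rid_counts.index[rid_counts == 1])
        rows = []
        for g in groups:
            sg = sig.loc[sig["group"] == g]
            rows.append(
                {
                    "group": g,
                    "n_gain": int((sg["direction"] == "gain").sum()),
                    "n_loss": int((sg["direction"] == "loss").sum()),
                    "n_significant": len(sg),
                    "n_unique_regions": int(
                        sg["region_id"].isin(unique_rids).sum()
                    ),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Poisson differential 5hmC regions",
            "=" * 50,
            f"universe:        {p['universe']} ({p['n_regions']} regions)",
            f"groups:          {', '.join(p['groups'])}",
            f"family size m:   {p['m']}",
            f"adjustment:      {p['adjustment']}   alpha: {p['alpha']}"
            f"   fold-change >= {p['fc_min']} or <= {1 / p['fc_min']:.3g}",
            f"significant:     {self.n_significant} of {len(self.frame)} tests",
            "",
            self.group_summary().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


class PoissonDifferentialModel:
    """Differential 5hmC model over a group-collapsed count matrix."""

    def __init__(self, group_matrix: GroupMatrix):
        if len(group_matrix.groups) < 2:
            raise ValueError("differential testing needs >= 2 groups")
        if not np.issubdtype(group_matrix.group_counts.dtype, np.integer):
            raise ValueError("group counts must be integral")
        self.group_matrix = group_matrix

    @classmethod
    def from_count_matrix(
        cls, counts: CountMatrix, groups: Mapping[str, str] | None = None
    ) -> "PoissonDifferentialModel":
        return cls(merge_replicates(counts, groups))

    # -- core ---------------------------------------------------------------
    @staticmethod
    def _test_core(
        counts: np.ndarray,
        libs: np.ndarray,
        norm: np.ndarray,
        pseudocount: float,
        tail: str,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised (R, G) lambda, fold change, direction and raw p."""
        R, G = counts.shape
        lam = np.empty((R, G))
        fc = np.empty((R, G))
        for g in range(G):
            others = [o for o in range(G) if o != g]
            rescaled = counts[:, others] * (libs[g] / libs[others])[None, :]
            lam[:, g] = rescaled.mean(axis=1)
            fc[:, g] = (norm[:, g] + pseudocount) / (
                norm[:, others].mean(axis=1) + pseudocount
            )
        k = counts
        upper_mask = k > lam
        p_up = stats.poisson.sf(k - 1, lam)
        p_lo = stats.poisson.cdf(k, lam)
        if tail == "auto":
            p = np.where(upper_mask, p_up, p_lo)
        elif tail == "two-sided":
            p = np.minimum(1.0, 2.0 * np.where(upper_mask, p_up, p_lo))
        else:
            raise ValueError("tail must be 'auto' or 'two-sided'")
        return lam, fc, upper_mask, p

    def _assemble(
        self,
        universe,
        groups: Sequence[str],
        counts: np.ndarray,
        lam: np.ndarray,
        fc: np.ndarray,
        upper_mask: np.ndarray,
        p: np.ndarray,
        alpha: float,
        fc_min: float,
        adjustment: str,
        family: str,
        pseudocount: float,
    ) -> PoissonDifferentialResults:
        R, G = counts.shape
        if adjustment == "bonferroni":
            m = R * G if family == "global" else R
            p_adj = np.minimum(1.0, p * m)
        elif adjustment == "none":
            m = R * G if family == "global" else R
            p_adj = p.copy()
        else:
            raise ValueError("adjustment must be 'bonferroni' or 'none'")
        significant = (p_adj < alpha) & ((fc >= fc_min) | (fc <= 1.0 / fc_min))
        region_df = universe.regions.df[["chrom", "start", "end"]]
        rids = universe.region_ids()
        frames = []
        for j, g in enumerate(groups):
            sub = region_df.copy()
            sub.insert(0, "region_id", rids)
            sub["group"] = g
            sub["count"] = counts[:, j]
            sub["lambda"] = lam[:, j]
            sub["fold_change"] = fc[:, j]
            sub["direction"] = np.where(upper_mask[:, j], "gain", "loss")
            sub["p_value"] = p[:, j]
            sub["p_adjusted"] = p_adj[:, j]
            sub["significant"] = significant[:, j]
            frames.append(sub)
        frame = pd.concat(frames, ignore_index=True)
        params = {
            "groups": list(groups),
            "alpha": alpha,
            "fc_min": fc_min,
            "adjustment": adjustment,
            "family": family,
            "m": int(m),
            "pseudocount": pseudocount,
            "universe": universe.definition,
            "n_regions": R,
        }
        return PoissonDifferentialResults(self, frame, params)

    # -- public fits --------------------------------------------------------
    def fit(
        self,
        alpha: float = 0.05,
        fc_min: float = 2.0,
        adjustment: str = "bonferroni",
        pseudocount: float = 0.5,
        family: str = "global",
        tail: str = "auto",
        preset: str | None = None,
    ) -> PoissonDifferentialResults:
        """Each group against the mean of the other groups.

        ``preset="methods"`` (Bonferroni p<0.05) or ``preset="results"``
        (raw p<0.01) override alpha/fc_min/adjustment with the two published
        threshold conventions.
        """
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}")
            cfg = PRESETS[preset]
            alpha, fc_min, adjustment = cfg["alpha"], cfg["fc_min"], cfg["adjustment"]
        if not (0.0 <= alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if fc_min < 1.0:
            raise ValueError("fc_min must be >= 1")
        gm = self.group_matrix
        lam, fc, upper, p = self._test_core(
            gm.group_counts, gm.group_library_sizes.astype(float), gm.group_norm,
            pseudocount, tail,
        )
        return self._assemble(
            gm.universe, gm.groups, gm.group_counts, lam, fc, upper, p,
            alpha, fc_min, adjustment, family, pseudocount,
        )

    def fit_contrast(
        self,
        focal: Sequence[str],
        other: Sequence[str] | None = None,
        name: str | None = None,
        alpha: float = 0.05,
        fc_min: float = 2.0,
        adjustment: str = "bonferroni",
        pseudocount: float = 0.5,
        tail: str = "auto",
        preset: str | None = None,
    ) -> PoissonDifferentialResults:
        """Pooled two-group comparison, e.g. IP vs non-IP primary sites.

        ``focal`` groups are summed into one focal pseudo-group and
        ``other`` (default: every remaining group) into the null side, then
        the same one-tailed Poisson machinery runs once per region.
        """
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}")
            cfg = PRESETS[preset]
            alpha, fc_min, adjustment = cfg["alpha"], cfg["fc_min"], cfg["adjustment"]
        gm = self.group_matrix
        focal = list(focal)
        other = (
            [g for g in gm.groups if g not in focal] if other is None else list(other)
        )
        if not focal or not other:
            raise ValueError("both contrast sides must be non-empty")
        overlap = set(focal) & set(other)
        if overlap:
            raise ValueError(f"contrast strata overlap: {sorted(overlap)}")
        for g in focal + other:
            if g not in gm.groups:
                raise ValueError(f"contrast names unknown group {g!r}")
        jf = [gm.groups.index(g) for g in focal]
        jo = [gm.groups.index(g) for g in other]
        counts = np.column_stack(
            [gm.group_counts[:, jf].sum(axis=1), gm.group_counts[:, jo].sum(axis=1)]
        )
        libs = np.array(
            [
                gm.group_library_sizes[jf].sum(),
                gm.group_library_sizes[jo].sum(),
            ],
            dtype=float,
        )
        kb = gm.universe.lengths() / 1_000.0
        norm = counts / (kb[:, None] * (libs / 1e6)[None, :])
        lam, fc, upper, p = self._test_core(counts, libs, norm, pseudocount, tail)
        label = name or ("+".join(focal) + "_vs_" + "+".join(other))
        res = self._assemble(
            gm.universe,
            [label, "rest"],
            counts, lam, fc, upper, p,
            alpha, fc_min, adjustment, "per_group", pseudocount,
        )
        # only the focal side of a pooled contrast is reported
        res.frame = res.frame.loc[res.frame["group"] == label].reset_index(drop=True)
        res.params["groups"] = [label]
        res.params["contrast"] = {"focal": focal, "other": other}
        return res

    def fit_strata(self, strata: Mapping[str, Sequence[str]], **kwargs) -> dict:
        """k-stratum contrasts: each named stratum against all the rest."""
        all_named: list[str] = []
        for gs in strata.values():
            for g in gs:
                if g in all_named:
                    raise ValueError(f"group {g!r} appears in two strata")
                all_named.append(g)
        out = {}
        for name, gs in strata.items():
            rest = [g for g in all_named if g not in gs]
            out[name] = self.fit_contrast(gs, rest, name=name, **kwargs)
        return out


# ---------------------------------------------------------------------------
# Functional surface


def psdhmr_test(
    groups: GroupMatrix,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    adjustment: str = "bonferroni",
    pseudocount: float = 0.5,
    **kwargs,
) -> PoissonDifferentialResults:
    """Primary-site differential regions: each group vs the others' mean."""
    return PoissonDifferentialModel(groups).fit(
        alpha=alpha, fc_min=fc_min, adjustment=adjustment, pseudocount=pseudocount,
        **kwargs,
    )


def two_group_test(
    groups: GroupMatrix,
    contrast: tuple[Sequence[str], Sequence[str]],
    alpha: float = 0.05,
    fc_min: float = 2.0,
    adjustment: str = "bonferroni",
    pseudocount: float = 0.5,
    **kwargs,
) -> PoissonDifferentialResults:
    """Pooled A-vs-B differential regions (clinical-feature DhMRs)."""
    focal, other = contrast
    return PoissonDifferentialModel(groups).fit_contrast(
        focal, other, alpha=alpha, fc_min=fc_min, adjustment=adjustment,
        pseudocount=pseudocount, **kwargs,
    )


def summarize_calls(results: PoissonDifferentialResults) -> pd.DataFrame:
    """Per-group gain/loss tallies and unique-region counts."""
    return results.group_summary()
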