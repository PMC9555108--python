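"""The one-tailed Poisson differential test and its Model/Results API."""

import numpy as np
import pandas as pd
import pytest

from cfhydroxy.diff import (
    PoissonDifferentialModel,
    bonferroni,
    poisson_tail,
    psdhmr_test,
    summarize_calls,
    two_group_test,
)
from cfhydroxy.intervals import IntervalSet, SampleSheetEntry
from cfhydroxy.quant import CountMatrix, GroupMatrix, RegionUniverse, merge_replicates
from cfhydroxy.simulate import SimConfig, simulate_count_matrix


def brute_force_poisson_upper(k, lam, tol=1e-15):
    """Independent oracle: explicit log-space pmf summation P(X >= k)."""
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    from math import lgamma, exp, log

    total = 0.0
    i = max(k, 0)
    # sum upward until the remaining mass is negligible
    while True:
        term = exp(i * log(lam) - lam - lgamma(i + 1))
        total += term
        if i > lam and term < tol:
            break
        i += 1
        if i > k + 10_000_000:  # pragma: no cover - safety valve
            break
    return min(total, 1.0)


def brute_force_poisson_lower(k, lam):
    from math import lgamma, exp, log

    if lam == 0:
        return 1.0
    return min(
        sum(exp(i * log(lam) - lam - lgamma(i + 1)) for i in range(0, k + 1)), 1.0
    )


def group_matrix_from_counts(counts, libs, region_len=1000, groups=None):
    counts = np.asarray(counts, dtype=np.int64)
    R, G = counts.shape
    rows = [("chr1", i * (region_len + 10), i * (region_len + 10) + region_len) for i in range(R)]
    uni = RegionUniverse(IntervalSet(rows), "merged_hmr")
    libs = np.asarray(libs, dtype=np.int64)
    groups = groups or [f"G{j}" for j in range(G)]
    kb = region_len / 1000.0
    norm = counts / (kb * (libs / 1e6)[None, :])
    return GroupMatrix(uni, list(groups), counts, libs, norm)


class TestPoissonTail:
    def test_closed_forms(self):
        assert poisson_tail(0, 0.0, "lower") == 1.0
        assert poisson_tail(0, 3.7, "lower") == pytest.approx(np.exp(-3.7), rel=1e-12)
        assert poisson_tail(0, 123.0, "upper") == 1.0
        assert poisson_tail(5, 0.0, "upper") == 0.0

    def test_matches_bruteforce_summation(self):
        assert poisson_tail(10, 5.0, "upper") == pytest.approx(
            brute_force_poisson_upper(10, 5.0), abs=1e-12
        )
        assert poisson_tail(3, 8.0, "lower") == pytest.approx(
            brute_force_poisson_lower(3, 8.0), abs=1e-12
        )

    def test_stable_at_large_lambda(self):
        p = poisson_tail(1_001_000, 1e6, "upper")
        assert 0.0 < p < 1.0 and np.isfinite(p)

    def test_monotonicity_in_k(self):
        lam = 12.0
        ks = np.arange(0, 60)
        ps = poisson_tail(ks, lam, "upper")
        assert (np.diff(ps) <= 1e-15).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            poisson_tail(-1, 5.0)
        with pytest.raises(ValueError):
            poisson_tail(2, -0.5)
        with pytest.raises(ValueError):
            poisson_tail(2, 5.0, tail="sideways")


class TestBonferroni:
    def test_arithmetic_cap_and_zero(self):
        np.testing.assert_allclose(
            bonferroni([0.001, 0.5, 0.0], m=10), [0.01, 1.0, 0.0]
        )

    def test_family_must_cover_list(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)
        with pytest.raises(ValueError):
            bonferroni([1.5], m=2)


class TestPsdhmrTest:
    def test_identical_groups_yield_no_calls(self):
        counts = np.full((50, 6), 30)
        gm = group_matrix_from_counts(counts, [1_000_000] * 6)
        res = psdhmr_test(gm)
        assert res.n_significant == 0

    def test_strong_gain_is_called_with_matching_oracle_p(self):
        counts = np.array([[100, 10, 10, 10, 10, 10]])
        gm = group_matrix_from_counts(counts, [1_000_000] * 6)
        res = PoissonDifferentialModel(gm).fit(adjustment="none")
        row = res.frame.iloc[0]
        assert row["direction"] == "gain"
        assert row["lambda"] == pytest.approx(10.0)
        assert row["fold_change"] == pytest.approx(100.5 / 10.5, rel=1e-9)
        assert row["p_value"] == pytest.approx(
            brute_force_poisson_upper(100, 10.0), rel=1e-9
        )
        assert row["p_value"] < 1e-50
        assert bool(row["significant"])

    def test_library_rescaling_of_lambda(self):
        # same relative signal, very different library sizes: no calls
        counts = np.array([[100, 10], [200, 20]])
        gm = group_matrix_from_counts(counts, [10_000_000, 1_000_000])
        res = PoissonDifferentialModel(gm).fit()
        assert res.frame.loc[res.frame["group"] == "G0", "lambda"].tolist() == [100.0, 200.0]
        assert res.n_significant == 0

    def test_all_zero_region_is_degenerate_null(self):
        counts = np.zeros((1, 3), dtype=int)
        gm = group_matrix_from_counts(counts, [1_000_000] * 3)
        res = PoissonDifferentialModel(gm).fit()
        row = res.frame.iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["p_value"] == 1.0
        assert not row["significant"]

    def test_single_group_rejected(self):
        gm = group_matrix_from_counts(np.array([[5]]), [1_000_000])
        with pytest.raises(ValueError, match="2 groups"):
            PoissonDifferentialModel(gm)

    def test_non_integer_counts_rejected(self):
        uni = RegionUniverse(IntervalSet([("chr1", 0, 1000)]), "merged_hmr")
        gm = GroupMatrix(uni, ["A", "B"], np.array([[1.5, 2.0]]),
                         np.array([100, 100]), np.array([[1.5, 2.0]]))
        with pytest.raises(ValueError, match="integral"):
            PoissonDifferentialModel(gm)

    def test_recovery_on_planted_design(self):
        cfg = SimConfig(seed=4, genome=(("chr1", 6_000_000),), n_genes=60,
                        n_hmrs=1000, n_planted_per_group=50)
        cm = simulate_count_matrix(cfg)
        res = PoissonDifferentialModel(merge_replicates(cm)).fit(preset="methods")
        sig = res.significant()
        called = set(zip(sig.chrom, sig.start, sig.end, sig.group, sig.direction))
        uni = cm.universe.regions
        # SimTruth is regenerated deterministically from the same config
        from cfhydroxy.simulate import simulate_annotation, simulate_hmr_landscape

        _, truth = simulate_hmr_landscape(cfg, simulate_annotation(cfg))
        planted = truth.planted_keys()
        tp = len(called & planted)
        assert tp / len(planted) >= 0.9
        assert tp / len(called) >= 0.9

    def test_power_increases_with_baseline_depth(self):
        sens = {}
        for base in (5.0, 20.0, 50.0):
            cfg = SimConfig(seed=8, genome=(("chr1", 4_000_000),), n_genes=40,
                            n_hmrs=600, n_planted_per_group=30,
                            baseline_mean_count=base)
            cm = simulate_count_matrix(cfg)
            res = PoissonDifferentialModel(merge_replicates(cm)).fit(preset="methods")
            sig = res.significant()
            called = set(zip(sig.chrom, sig.start, sig.end, sig.group, sig.direction))
            from cfhydroxy.simulate import simulate_annotation, simulate_hmr_landscape

            _, truth = simulate_hmr_landscape(cfg, simulate_annotation(cfg))
            planted = truth.planted_keys()
            sens[base] = len(called & planted) / len(planted)
        assert sens[5.0] <= sens[20.0] + 0.02
        assert sens[20.0] <= sens[50.0] + 0.02
        assert sens[5.0] < sens[50.0]

    def test_null_calibration_with_known_lambda(self, rng):
        """With the true mean supplied, the exact Poisson tail is
        conservative: P(p < t) <= t for either tail."""
        lam = 20.0
        k = rng.poisson(lam, size=200_000)
        p_up = poisson_tail(k, lam, "upper")
        p_lo = poisson_tail(k, lam, "lower")
        for t in (0.01, 0.05):
            assert (p_up < t).mean() <= t
            assert (p_lo < t).mean() <= t


class TestTwoGroupTest:
    def test_antisymmetry_under_contrast_swap(self):
        counts = np.array([[40, 40, 10, 10], [10, 12, 30, 33], [20, 20, 20, 20]])
        gm = group_matrix_from_counts(counts, [1_000_000] * 4,
                                      groups=["a1", "a2", "b1", "b2"])
        ab = two_group_test(gm, (["a1", "a2"], ["b1", "b2"]), adjustment="none")
        ba = two_group_test(gm, (["b1", "b2"], ["a1", "a2"]), adjustment="none")
        flip = {"gain": "loss", "loss": "gain"}
        for (_, ra), (_, rb) in zip(ab.frame.iterrows(), ba.frame.iterrows()):
            if ra["count"] == ra["lambda"]:
                continue  # exactly balanced rows carry no direction
            assert rb["direction"] == flip[ra["direction"]]
        np.testing.assert_allclose(ab.frame["fold_change"] , 1.0 / ba.frame["fold_change"],
                                   rtol=1e-9)

    def test_overlapping_strata_rejected(self):
        gm = group_matrix_from_counts(np.array([[1, 2, 3]]), [100] * 3,
                                      groups=["A", "B", "C"])
        with pytest.raises(ValueError, match="overlap"):
            two_group_test(gm, (["A", "B"], ["B", "C"]))

    def test_ip_style_planted_gains_recovered(self):
        cfg = SimConfig(seed=9, genome=(("chr1", 4_000_000),), n_genes=40,
                        n_hmrs=500, n_planted_per_group=40,
                        planted_direction_mix=1.0,
                        group_names=("PT-DLBCL", "PCNS-DLBCL", "LN-DLBCL",
                                     "PG-DLBCL", "PI-DLBCL", "Healthy"))
        cm = simulate_count_matrix(cfg)
        gm = merge_replicates(cm)
        res = PoissonDifferentialModel(gm).fit_contrast(
            ["PT-DLBCL", "PCNS-DLBCL"], ["LN-DLBCL", "PG-DLBCL", "PI-DLBCL"],
            preset="methods",
        )
        from cfhydroxy.simulate import simulate_annotation, simulate_hmr_landscape

        _, truth = simulate_hmr_landscape(cfg, simulate_annotation(cfg))
        ip_gains = {
            (p.region.chrom, p.region.start, p.region.end)
            for p in truth.planted
            if p.group in ("PT-DLBCL", "PCNS-DLBCL") and p.direction == "gain"
        }
        sig = res.significant()
        called_gain = set(
            zip(sig.chrom, sig.start, sig.end)
        ) & ip_gains
        recovered = sig.loc[sig.direction == "gain"]
        rec_keys = set(zip(recovered.chrom, recovered.start, recovered.end))
        assert len(rec_keys & ip_gains) / len(ip_gains) >= 0.8

    def test_strata_api_runs_each_versus_rest(self, small_groups):
        model = PoissonDifferentialModel(small_groups)
        out = model.fit_strata(
            {"IP": ["PT-DLBCL", "PCNS-DLBCL"],
             "nonIP": ["LN-DLBCL", "PG-DLBCL", "PI-DLBCL"]},
            preset="methods",
        )
        assert set(out) == {"IP", "nonIP"}
        for res in out.values():
            assert len(res.frame) == len(small_groups.universe)


class TestSummaries:
    def test_empty_calls_all_zero(self):
        gm = group_matrix_from_counts(np.full((5, 3), 10), [1_000_000] * 3)
        res = PoissonDifferentialModel(gm).fit()
        summary = summarize_calls(res)
        assert (summary[["n_gain", "n_loss", "n_unique_regions"]].to_numpy() == 0).all()

    def test_region_significant_in_two_groups_is_not_unique(self):
        # one region: huge in A and B, tiny elsewhere -> significant in both
        counts = np.array([[500, 500, 10, 10, 10, 10]])
        gm = group_matrix_from_counts(counts, [1_000_000] * 6)
        res = PoissonDifferentialModel(gm).fit()
        summary = res.group_summary().set_index("group")
        assert summary.loc["G0", "n_significant"] == 1
        assert summary.loc["G1", "n_significant"] == 1
        assert summary.loc["G0", "n_unique_regions"] == 0
        assert summary.loc["G1", "n_unique_regions"] == 0

    def test_single_group_effects_are_fully_unique(self):
        cfg = SimConfig(seed=12, genome=(("chr1", 3_000_000),), n_genes=30,
                        n_hmrs=300, n_planted_per_group=0)
        cm = simulate_count_matrix(cfg)
        gm = merge_replicates(cm)
        # plant manually: inflate one group's counts on 10 regions; at 3x the
        # other groups' reciprocal fold change (~1/1.4) stays well inside the
        # FC gate, so the calls belong to the inflated group alone
        gm.group_counts[:10, 0] *= 3
        kb = gm.universe.lengths() / 1000.0
        gm.group_norm = gm.group_counts / (kb[:, None] * (gm.group_library_sizes / 1e6)[None, :])
        res = PoissonDifferentialModel(gm).fit(preset="methods")
        summary = res.group_summary().set_index("group")
        g0 = gm.groups[0]
        assert summary.loc[g0, "n_gain"] >= 8
        assert summary.loc[g0, "n_unique_regions"] == summary.loc[g0, "n_significant"]
        others = summary.drop(index=g0)
        assert (others["n_gain"] == 0).all()

    def test_summary_text_mentions_parameters(self, small_groups):
        res = PoissonDifferentialModel(small_groups).fit(preset="methods")
        text = res.summary()
        assert "bonferroni" in text and "merged_hmr" in text
        assert str(res.params["m"]) in text
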