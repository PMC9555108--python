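"""Feature assignment, enrichment scores, metagene/centred profiles,
group separability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfhydroxy.intervals import GeneModel, IntervalSet
from cfhydroxy.profiles import (
    centered_profile,
    enrichment_scores,
    feature_distribution,
    metagene_profile,
    separability,
)
from cfhydroxy.simulate import SimConfig, simulate_annotation


@pytest.fixture(scope="module")
def annotation():
    cfg = SimConfig(
        seed=21, genome=(("chr1", 5_000_000), ("chr2", 5_000_000)),
        n_genes=80, n_hmrs=10, n_planted_per_group=1,
    )
    return simulate_annotation(cfg), cfg


class TestFeatureDistribution:
    def test_all_in_exon(self, annotation):
        (genes, features), _ = annotation
        rows = []
        for g in genes[:20]:
            s, e = g.exons[0]
            rows.append((g.chrom, s, min(e, s + 50)))
        hmrs = IntervalSet(rows)
        dist = feature_distribution(hmrs, features)
        assert dist.fraction("exon") == 1.0
        assert abs(dist.table["fraction"].sum() - 1.0) < 1e-9

    def test_priority_rule(self):
        features = {
            "promoter": IntervalSet([("chr1", 0, 200)]),
            "exon": IntervalSet([("chr1", 100, 300)]),
            "intergenic": IntervalSet([("chr1", 300, 1000)]),
        }
        hmr = IntervalSet([("chr1", 120, 180)])  # midpoint 150: promoter & exon
        dist = feature_distribution(hmr, features)
        assert dist.fraction("promoter") == 1.0

    def test_fallback_class_collects_unassigned(self):
        features = {"exon": IntervalSet([("chr1", 0, 100)]),
                    "intergenic": IntervalSet()}
        hmr = IntervalSet([("chr1", 500, 700)])
        dist = feature_distribution(hmr, features)
        assert dist.fraction("intergenic") == 1.0

    def test_uniform_hmrs_match_genome_fractions(self, annotation):
        """Chi-square GOF of class counts vs genome fractions, uniform draws."""
        (genes, features), cfg = annotation
        rng = np.random.default_rng(5)
        n = 2000
        chroms = [c for c, _ in cfg.genome]
        sizes = np.array([s for _, s in cfg.genome])
        ci = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
        mids = (rng.random(n) * (sizes[ci] - 100)).astype(int)
        hmrs = IntervalSet(
            [(chroms[c], int(m), int(m) + 100) for c, m in zip(ci, mids)]
        )
        dist = feature_distribution(hmrs, features)
        from cfhydroxy.intervals import feature_fraction

        classes = dist.table["class"].tolist()
        observed = dist.table["n_assigned"].to_numpy()
        expected = np.array(
            [n * feature_fraction(features[c], cfg.genome_map) for c in classes]
        )
        expected *= observed.sum() / expected.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(classes) - 1)
        assert p > 0.01


class TestEnrichmentScores:
    def test_null_and_arithmetic(self):
        # all 100 hMRs inside a class covering 10% of a 1 Mb genome
        features = {
            "exon": IntervalSet([("chr1", 0, 100_000)]),
            "intergenic": IntervalSet([("chr1", 100_000, 1_000_000)]),
        }
        hmrs = IntervalSet([("chr1", i * 900, i * 900 + 100) for i in range(100)])
        scores = enrichment_scores(hmrs, features, 1_000_000)
        assert scores.score("exon") == pytest.approx(
            np.log2(100.5 / 10.5), rel=1e-9
        )
        assert scores.score("intergenic") < 0

    def test_observed_equal_expected_scores_zero(self):
        features = {
            "exon": IntervalSet([("chr1", 0, 500_000)]),
            "intergenic": IntervalSet([("chr1", 500_000, 1_000_000)]),
        }
        hmrs = IntervalSet(
            [("chr1", i * 10_000 + 2_000, i * 10_000 + 2_100) for i in range(100)]
        )
        scores = enrichment_scores(hmrs, features, 1_000_000)
        # 50 midpoints land in each half
        assert abs(scores.score("exon")) < 0.05
        assert abs(scores.score("intergenic")) < 0.05


def uniform_fragments(rng, genome, n, length=160):
    chroms = list(genome)
    sizes = np.array([genome[c] for c in chroms])
    ci = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    mids = (rng.random(n) * sizes[ci]).astype(np.int64)
    starts = np.maximum(mids - length // 2, 0)
    return IntervalSet(
        pd.DataFrame(
            {
                "chrom": np.array(chroms, dtype=object)[ci],
                "start": starts,
                "end": starts + length,
            }
        )
    )


class TestMetagene:
    def test_uniform_coverage_is_flat(self, annotation, rng):
        (genes, _), cfg = annotation
        frags = uniform_fragments(rng, cfg.genome_map, 1_500_000)
        prof = metagene_profile(frags, genes)
        dev = np.abs(prof.values - prof.values.mean()).max()
        assert dev < 0.1 * prof.values.mean()

    def test_zero_coverage_profile_is_zero(self, annotation):
        (genes, _), cfg = annotation
        empty_like = IntervalSet([("chrZ", 0, 100)])  # no overlap with genes
        prof = metagene_profile(empty_like, genes)
        assert np.allclose(prof.values, 0.0)

    def test_body_only_coverage_dominates_flanks(self, rng):
        gene = GeneModel("chr1", "+", 10_000, 20_000, ((10_000, 20_000),), "g")
        mids = rng.integers(10_000, 20_000, size=5_000)
        frags = IntervalSet([("chr1", int(m), int(m) + 2) for m in mids])
        prof = metagene_profile(frags, [gene])
        up, down = prof.flanks()
        assert prof.body().mean() > 50 * max(up.mean(), down.mean(), 1e-9)

    def test_minus_strand_orientation(self):
        """Signal at the physical right end of a minus-strand gene (its TSS)
        must land at the TSS end (start) of the profile."""
        gene = GeneModel("chr1", "-", 10_000, 20_000, ((10_000, 20_000),), "g")
        frags = IntervalSet([("chr1", 19_900, 19_902)] * 100)
        prof = metagene_profile(frags, [gene])
        body = prof.body()
        assert body[:5].sum() > 0
        assert body[5:].sum() == 0

    def test_short_genes_skipped_with_warning(self):
        long_gene = GeneModel("chr1", "+", 0, 5_000, ((0, 5_000),), "long")
        short_gene = GeneModel("chr1", "+", 6_000, 6_050, ((6_000, 6_050),), "short")
        frags = IntervalSet([("chr1", 100, 200)])
        with pytest.warns(UserWarning, match="skipped"):
            prof = metagene_profile(frags, [long_gene, short_gene])
        assert prof.n_genes_used == 1


class TestCenteredProfile:
    def test_saturated_marks_give_unit_bins(self):
        q = IntervalSet([("chr1", 100_000, 101_000)])
        marks = IntervalSet([("chr1", 0, 1_000_000)])
        prof = centered_profile(q, marks)
        assert np.allclose(prof.values, 1.0)

    def test_self_centered_marks_peak_at_zero(self):
        rows = [("chr1", 50_000 * (i + 1), 50_000 * (i + 1) + 1_000) for i in range(10)]
        q = IntervalSet(rows)
        prof = centered_profile(q, IntervalSet(rows), half_window=5_000, bin_size=100)
        centre = np.abs(prof.offsets) < 500
        flank = np.abs(prof.offsets) > 2_000
        assert prof.values[centre].mean() > 0.9
        assert prof.values[flank].mean() < 0.05

    def test_planted_proximal_marks_exceed_flanks(self, rng):
        mids = rng.integers(100_000, 900_000, size=50)
        q = IntervalSet([("chr1", int(m) - 200, int(m) + 200) for m in mids])
        offsets = rng.integers(-500, 500, size=50)
        marks = IntervalSet(
            [("chr1", int(m + o) - 150, int(m + o) + 150) for m, o in zip(mids, offsets)]
        )
        prof = centered_profile(q, marks, half_window=5_000, bin_size=100)
        central = np.abs(prof.offsets) <= 500
        flank = np.abs(prof.offsets) >= 2_500
        assert prof.values[central].mean() >= 2 * max(prof.values[flank].mean(), 1e-9)

    def test_distal_filter_drops_tss_proximal_queries(self):
        q = IntervalSet([("chr1", 9_500, 10_500), ("chr1", 200_000, 201_000)])
        marks = IntervalSet([("chr1", 0, 1_000_000)])
        tss = {"chr1": np.array([10_000])}
        prof = centered_profile(q, marks, tss_positions=tss, distal_min_bp=10_000)
        assert prof.n_queries == 1


class TestSeparability:
    def test_ideal_two_group_separation(self):
        values = np.zeros((60, 4))  # regions x samples, orthogonal blocks
        values[:30, :2] = 50.0
        values[30:, 2:] = 50.0
        _, sil = separability(values, ["A", "A", "B", "B"])
        assert sil > 0.95

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="silhouette undefined"):
            separability(np.ones((10, 4)), ["A", "A", "B", "B"])

    def test_group_size_requirements(self):
        with pytest.raises(ValueError, match="2 groups"):
            separability(np.random.default_rng(0).random((5, 4)), ["A"] * 4)

    def test_permuted_labels_score_near_zero_without_structure(self, rng):
        values = rng.poisson(50, size=(200, 12)).astype(float)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        sils = [
            separability(values, list(rng.permutation(labels)))[1] for _ in range(20)
        ]
        assert np.abs(np.mean(sils)) < 0.1

    def test_silhouette_increases_with_fold_change(self):
        """Planted effect size drives separability monotonically."""
        from cfhydroxy.diff import PoissonDifferentialModel
        from cfhydroxy.quant import merge_replicates, rpkm
        from cfhydroxy.simulate import simulate_count_matrix

        sils = {}
        for fc in (1.0, 2.0, 4.0):
            cfg = SimConfig(
                seed=31, genome=(("chr1", 6_000_000),), n_genes=50,
                n_hmrs=800, n_planted_per_group=40, planted_fold_change=fc,
            )
            cm = simulate_count_matrix(cfg)
            nm = rpkm(cm)
            truth_regions = slice(0, 300)  # fixed region subset, same for all fc
            values = pd.DataFrame(nm.values[truth_regions], columns=nm.sample_ids)
            labels = [s.group for s in cm.samples]
            sils[fc] = separability(values, labels)[1]
        assert sils[1.0] < sils[2.0] < sils[4.0]
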