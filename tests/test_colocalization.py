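import numpy as np
import pytest
from scipy import stats

from regcoloc.colocalization import (
    coloc_panel,
    cooccupancy_profile,
    f_score,
    fisher_overlap_test,
    format_p,
    overlap_stats,
    sample_random_intervals,
)
from regcoloc.intervals import GenomicInterval, IntervalSet

from conftest import exact_fisher_two_sided, random_interval_set

GENOME = {"chr1": 10_000_000, "chr2": 10_000_000}


def centered(center, chrom="chr1", half=150):
    return GenomicInterval(chrom, center - half, center + half)


class TestCooccupancyProfile:
    def test_features_at_centers_fill_central_bin(self):
        ref = IntervalSet([centered(c) for c in (100_000, 500_000, 900_000)], genome=GENOME)
        prof = cooccupancy_profile(ref, ref, half_window=20_000, bin_size=500)
        mid = len(prof.counts) // 2
        assert prof.counts[mid] == 3
        assert prof.counts.sum() == 3

    def test_no_features_gives_zero_profile(self):
        ref = IntervalSet([centered(100_000)], genome=GENOME)
        prof = cooccupancy_profile(ref, IntervalSet(genome=GENOME))
        assert prof.counts.sum() == 0

    def test_uniform_features_have_unit_fold_enrichment(self, rng):
        genome = {"chr1": 10_000_000}
        ref = IntervalSet(
            [centered(int(c)) for c in rng.integers(50_000, 9_950_000, size=60)],
            genome=genome,
        )
        n_feat = 5_000
        starts = rng.integers(0, 10_000_000 - 200, size=n_feat)
        feats = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 200) for s in starts], genome=genome
        )
        prof = cooccupancy_profile(ref, feats, half_window=20_000, bin_size=2_000)
        # Poisson bound: each bin expects ~ n_ref * bin * density counts
        expected = len(ref) * 2_000 * n_feat / 10_000_000
        se = np.sqrt(expected)
        assert np.all(np.abs(prof.counts - expected) < 4 * se + 1)
        assert prof.fold_enrichment.mean() == pytest.approx(1.0, abs=0.15)

    def test_profile_integrates_to_pair_count(self, rng):
        ref = IntervalSet(
            [centered(int(c)) for c in rng.integers(50_000, 950_000, size=20)],
            genome=GENOME,
        )
        feats = random_interval_set(rng, 300, chroms=("chr1",), span=1_000_000, genome=GENOME)
        prof = cooccupancy_profile(ref, feats, half_window=20_000, bin_size=500)
        pairs = sum(
            1
            for r in ref
            for f in feats
            if r.chrom == f.chrom and -20_000 <= f.center - r.center < 20_000
        )
        assert prof.counts.sum() == pairs
        # fold-enrichment integrates back to the raw pair count
        density = len(feats) / sum(GENOME.values())
        integral = (prof.fold_enrichment * len(ref) * prof.bin_size * density).sum()
        assert integral == pytest.approx(pairs)

    def test_bin_size_must_divide_window(self):
        ref = IntervalSet([centered(100_000)], genome=GENOME)
        with pytest.raises(ValueError):
            cooccupancy_profile(ref, ref, half_window=20_000, bin_size=777)


class TestRandomIntervals:
    def test_zero_draws(self):
        assert len(sample_random_intervals(0, GENOME, [100], seed=1)) == 0

    def test_seed_determinism(self):
        a = sample_random_intervals(50, GENOME, [100, 200, 300], seed=42)
        b = sample_random_intervals(50, GENOME, [100, 200, 300], seed=42)
        assert a.intervals == b.intervals

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sample_random_intervals(-1, GENOME, [100], seed=1)

    def test_chromosome_proportions_follow_length(self):
        genome = {"chrA": 1_000_000, "chrB": 3_000_000}
        draws = sample_random_intervals(10_000, genome, [200], seed=7)
        frac_a = sum(iv.chrom == "chrA" for iv in draws) / len(draws)
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac_a - 0.25) < 3 * se

    def test_lengths_resampled_from_multiset(self):
        draws = sample_random_intervals(500, GENOME, [111, 222], seed=3)
        assert {iv.length for iv in draws} <= {111, 222}
        for iv in draws:
            assert 0 <= iv.start and iv.end <= GENOME[iv.chrom]


class TestOverlapStats:
    def test_self_overlap_is_full(self, rng):
        ref = random_interval_set(rng, 30, genome=None)
        n, frac = overlap_stats(ref, ref, 100)
        assert (n, frac) == (30, 1.0)

    def test_absent_chromosome_gives_zero(self):
        ref = IntervalSet([centered(100_000)])
        feats = IntervalSet([centered(100_000, chrom="chr9")])
        assert overlap_stats(ref, feats, 100) == (0, 0.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats(IntervalSet(), IntervalSet([centered(1_000)]), 100)

    def test_planted_colocalization_fraction_recovered(self, rng):
        """rho = 0.6 of 500 sites get a jittered partner; estimate hits the CI."""
        rho, n = 0.6, 500
        centers = rng.choice(np.arange(100_000, 9_900_000, 15_000), size=n, replace=False)
        ref = IntervalSet([centered(int(c)) for c in centers], genome={"chr1": 10_000_000})
        chosen = rng.random(n) < rho
        feats = IntervalSet(
            [
                centered(int(c) + int(rng.integers(-30, 31)))
                for c, keep in zip(centers, chosen)
                if keep
            ],
            genome={"chr1": 10_000_000},
        )
        _, frac = overlap_stats(ref, feats, 100)
        lo, hi = stats.binom.interval(0.99, n, rho)
        assert lo / n <= frac <= hi / n


class TestFisher:
    def test_identical_rows_null(self):
        odds, p = fisher_overlap_test((10, 100), (10, 100))
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_exact_enumeration_small_table(self):
        _, p = fisher_overlap_test((8, 10), (1, 10))
        want = float(exact_fisher_two_sided(8, 2, 1, 9))
        assert p == pytest.approx(want, rel=1e-12)

    def test_large_table_underflows_below_printed_bound(self):
        _, p = fisher_overlap_test((1007, 1229), (55, 1229))
        assert 0 <= p < 2.2e-16
        assert format_p(p) == "< 2.2e-16"

    def test_matches_exact_enumeration_random_tables(self, rng):
        for _ in range(100):
            n_ref = int(rng.integers(1, 200))
            n_rand = int(rng.integers(1, 200))
            a = int(rng.integers(0, n_ref + 1))
            b = int(rng.integers(0, n_rand + 1))
            _, p = fisher_overlap_test((a, n_ref), (b, n_rand))
            want = float(exact_fisher_two_sided(a, n_ref - a, b, n_rand - b))
            assert p == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_haldane_correction_only_on_zero_cells(self):
        odds, _ = fisher_overlap_test((0, 10), (5, 10))
        assert odds == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))
        odds2, _ = fisher_overlap_test((2, 10), (5, 10))
        assert odds2 == pytest.approx((2 * 5) / (8 * 5))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap_test((1, 0), (0, 10))
        with pytest.raises(ValueError):
            fisher_overlap_test((11, 10), (0, 10))


class TestFScore:
    def test_perfect_match(self, rng):
        ref = random_interval_set(rng, 20)
        assert f_score(ref, ref, 100) == pytest.approx(1.0)

    def test_disjoint_sets_zero(self):
        a = IntervalSet([centered(100_000)])
        b = IntervalSet([centered(5_000_000)])
        assert f_score(a, b, 100) == 0.0

    def test_constructed_precision_recall(self):
        # all 2 refs matched (R=1); 2 of 4 features matched (P=0.5) -> F=2/3
        ref = IntervalSet([centered(100_000), centered(200_000)])
        feats = IntervalSet(
            [centered(100_000), centered(200_000), centered(5_000_000), centered(6_000_000)]
        )
        f, precision, recall = f_score(ref, feats, 100, return_components=True)
        assert (precision, recall) == (0.5, 1.0)
        assert f == pytest.approx(2 / 3)

    def test_swap_symmetry(self, rng):
        ref = random_interval_set(rng, 40)
        feats = random_interval_set(rng, 60)
        f_ab, p_ab, r_ab = f_score(ref, feats, 50, return_components=True)
        f_ba, p_ba, r_ba = f_score(feats, ref, 50, return_components=True)
        assert f_ab == pytest.approx(f_ba)
        assert (p_ab, r_ab) == (r_ba, p_ba)


class TestColocPanel:
    def test_identity_panel(self, rng):
        ref = IntervalSet(
            [centered(int(c)) for c in rng.integers(50_000, 9_950_000, size=40)],
            genome={"chr1": 10_000_000},
        )
        df = coloc_panel(ref, {"self": ref}, window_bp=100, seed=1)
        row = df.iloc[0]
        assert row["fraction"] == 1.0
        assert row["f_score"] == pytest.approx(1.0)

    def test_empty_feature_row_flagged_not_fatal(self, rng):
        ref = IntervalSet(
            [centered(int(c)) for c in rng.integers(50_000, 9_950_000, size=30)],
            genome={"chr1": 10_000_000},
        )
        df = coloc_panel(ref, {"self": ref, "empty": IntervalSet()}, seed=1)
        assert df.loc[df["feature"] == "empty", "error"].notna().all()
        assert df.loc[df["feature"] == "self", "error"].isna().all()

    def test_estimated_fractions_monotone_in_rho(self, sim_default, rng):
        genome = sim_default["genome"]
        truth = sim_default["truth"]
        sites = truth.sites
        panel = {}
        for rho in (0.0, 0.2, 0.4, 0.6, 0.8):
            idx = rng.choice(len(sites), size=int(rho * len(sites)), replace=False)
            feats = [
                GenomicInterval(sites[i]["chrom"], sites[i]["start"], sites[i]["end"])
                for i in idx
            ]
            # pad with uniform background so every set has equal size
            n_bg = len(sites) - len(feats)
            chroms = list(genome)
            for _ in range(n_bg):
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, genome[chrom] - 300))
                feats.append(GenomicInterval(chrom, s, s + 300))
            panel[f"rho{rho:.1f}"] = IntervalSet(feats, genome=genome)
        ref = IntervalSet(
            [GenomicInterval(s["chrom"], s["start"], s["end"]) for s in sites],
            genome=genome,
        )
        df = coloc_panel(ref, panel, genome=genome, window_bp=100, seed=5)
        fracs = df.set_index("feature")["fraction"]
        ordered = [fracs[f"rho{r:.1f}"] for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert all(a < b for a, b in zip(ordered, ordered[1:]))
        # BH column exists and is monotone-compatible with raw p
        assert (df["p_adj_bh"] >= df["p_value"] - 1e-12).all()
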