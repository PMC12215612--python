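"""SNP filtering, r², Hill-Weir decay, LD landscape, het contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from grapesdr.formats import GenotypeMatrix
from grapesdr.ld import (
    FilterProfile,
    LDPair,
    TETRASTIGMA_PROFILE,
    aggregate_ld_bins,
    filter_variants,
    fit_ld_decay,
    hill_weir_expected,
    hom_het_ratio,
    pairwise_r2,
    recover_high_ld_interval,
)


def matrix(positions, genotypes, qual=None, depths=None, info=None, ns=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    nv, n_samples = genotypes.shape
    if ns is None:
        ns = n_samples
    return GenotypeMatrix(
        "chr2",
        np.asarray(positions),
        ["A"] * nv,
        ["G"] * nv,
        np.asarray(qual if qual is not None else [60.0] * nv, dtype=float),
        genotypes,
        np.asarray(
            depths if depths is not None else np.full((nv, ns), 10), dtype=np.int32
        ),
        info if info is not None else pd.DataFrame(index=range(nv)),
        [f"s{i}" for i in range(ns)],
    )


class TestFilterVariants:
    def test_six_record_toy_one_survivor_per_filter_tally(self):
        # records: low qual / low DP / low MAF / missing / QD fail / all pass
        genos = np.array(
            [
                [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
                [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
                [0, 0, 0, 0, 0, 0, 0, 0, 0, 1],  # MAF 0.05, not > 0.05
                [0, 1, 2, 0, 1, 2, 0, 1, 2, -1],
                [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
                [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
            ],
            dtype=np.int8,
        )
        depths = np.full((6, 10), 10)
        depths[1, 3] = 4  # below DP > 5
        qual = np.array([25.0, 60, 60, 60, 60, 60])
        info = pd.DataFrame(
            {"QD": [20.0, 20, 20, 20, 1.5, 20], "SOR": [1.0] * 6}
        )
        m = matrix([100, 200, 300, 400, 500, 600], genos, qual, depths, info)
        out, tally = filter_variants(m, FilterProfile())
        assert out.n_variants == 1
        assert list(out.positions) == [600]
        assert tally == {"qual": 1, "depth": 1, "maf": 1, "missing": 1, "hard": 1}

    def test_low_coverage_depth_bounds_are_exclusive(self):
        genos = np.tile([0, 1, 2, 0, 1, 2], (4, 1)).astype(np.int8)
        depths = np.full((4, 6), 5)
        depths[0, 0] = 1   # too low
        depths[1, 0] = 15  # too high
        depths[2, 0] = 2   # boundary kept
        depths[3, 0] = 14  # boundary kept
        m = matrix([10, 20, 30, 40], genos, depths=depths)
        out, tally = filter_variants(m, TETRASTIGMA_PROFILE)
        assert list(out.positions) == [30, 40]
        assert tally["depth"] == 2

    def test_sor_hard_filter(self):
        genos = np.tile([0, 1, 2, 0, 1, 2], (2, 1)).astype(np.int8)
        info = pd.DataFrame({"SOR": [3.5, 1.0], "QD": [20.0, 20.0]})
        m = matrix([10, 20], genos, info=info)
        out, tally = filter_variants(m)
        assert list(out.positions) == [20] and tally["hard"] == 1

    def test_empty_matrix_passes_through(self):
        m = matrix(np.empty(0, dtype=int), np.empty((0, 4), dtype=np.int8),
                   qual=[], depths=np.empty((0, 4)), ns=4)
        out, tally = filter_variants(m)
        assert out.n_variants == 0 and sum(tally.values()) == 0


class TestPairwiseR2:
    def test_identical_vectors_full_ld(self):
        g = np.array([[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2]], dtype=np.int8)
        (pair,) = pairwise_r2(matrix([100, 200], g))
        assert pair.r2 == pytest.approx(1.0)

    def test_orthogonal_vectors_zero_ld(self):
        g = np.array([[0, 0, 1, 1], [0, 1, 0, 1]], dtype=np.int8)
        (pair,) = pairwise_r2(matrix([100, 200], g), maf_min=0.0)
        assert pair.r2 == pytest.approx(0.0)

    def test_distance_cap(self):
        g = np.array([[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2]], dtype=np.int8)
        assert pairwise_r2(matrix([100, 350_100], g)) == []

    def test_pairs_with_few_shared_samples_skipped(self):
        g = np.array(
            [[0, 1, -1, -1, 2, 0], [-1, -1, 0, 1, -1, -1]], dtype=np.int8
        )
        assert pairwise_r2(matrix([100, 200], g), maf_min=0.0) == []

    def test_r2_bounds_and_symmetry(self, population_ld):
        _, pairs, _ = population_ld
        sample = pairs[:: max(1, len(pairs) // 500)]
        for p in sample:
            assert 0.0 <= p.r2 <= 1.0
        # symmetry: recompute a few pairs with swapped rows
        filt = population_ld[0]
        g = filt.genotypes[:2].astype(float)
        r_ab = np.corrcoef(g[0], g[1])[0, 1] ** 2
        r_ba = np.corrcoef(g[1], g[0])[0, 1] ** 2
        assert r_ab == pytest.approx(r_ba)


class TestHillWeir:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        d = rng.integers(1, 300_000, 2000)
        pairs = [
            LDPair(0, int(x), float(hill_weir_expected(x, 1e-4, 20))) for x in d
        ]
        fit = fit_ld_decay(pairs, 20)
        assert fit.rho == pytest.approx(1e-4, rel=1e-6)

    def test_noisy_recovery_within_20_percent(self):
        rng = np.random.default_rng(1)
        d = rng.integers(1, 300_000, 5000)
        r2 = np.clip(
            hill_weir_expected(d, 1e-4, 20) + rng.normal(0, 0.02, len(d)), 0, 1
        )
        fit = fit_ld_decay(
            [LDPair(0, int(x), float(v)) for x, v in zip(d, r2)], 20
        )
        assert abs(fit.rho - 1e-4) / 1e-4 < 0.2
        assert fit.half_decay_bp > 0

    def test_flat_input_degenerate(self):
        pairs = [LDPair(0, d, 0.3) for d in (10, 100, 1000, 10_000)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_ld_decay(pairs, 20)

    def test_near_zero_rho_reports_no_decay(self):
        rng = np.random.default_rng(2)
        d = rng.integers(1, 300_000, 500)
        flat = hill_weir_expected(d, 0.0, 20) + rng.normal(0, 1e-4, len(d))
        fit = fit_ld_decay(
            [LDPair(0, int(x), float(v)) for x, v in zip(d, flat)], 20
        )
        assert fit.no_decay

    def test_curve_monotone_nonincreasing(self):
        d = np.linspace(0, 1e6, 200)
        y = hill_weir_expected(d, 5e-5, 20)
        assert np.all(np.diff(y) <= 1e-12)


class TestLandscape:
    def test_bin_mean(self):
        pairs = [LDPair(100, 5100, 0.2), LDPair(200, 5200, 0.4),
                 LDPair(300, 5300, 0.6)]
        df = aggregate_ld_bins(pairs, (0, 2000), 1000)
        assert df["mean_r2"].iloc[0] == pytest.approx(0.4)
        assert df["snp_count"].iloc[0] == 3

    def test_min_snps_masking(self):
        pairs = [LDPair(i * 100, 5000 + i, 0.5) for i in range(1, 5)]
        df = aggregate_ld_bins(pairs, (0, 1000), 1000, min_snps=5)
        assert bool(df["masked"].iloc[0])
        assert np.isnan(df["mean_r2"].iloc[0])

    def test_empty_bin(self):
        df = aggregate_ld_bins([], (0, 3000), 1000, min_snps=1)
        assert (df["snp_count"] == 0).all()
        assert df["masked"].all()
        assert df["mean_r2"].isna().all()

    def test_bins_tile_region_without_overlap(self):
        df = aggregate_ld_bins([], (1000, 5000), 1000)
        assert df["bin_start"].tolist() == [1000, 2000, 3000, 4000]


class TestPlantedRegion:
    def test_r2_decays_across_distance_deciles(self, population_ld):
        _, pairs, _ = population_ld
        sdr = (925_000, 1_075_000)
        d = np.array([p.distance for p in pairs])
        r2 = np.array([p.r2 for p in pairs])
        outside = np.array(
            [not (sdr[0] <= p.pos_a <= sdr[1]) for p in pairs]
        )
        d, r2 = d[outside], r2[outside]
        edges = np.quantile(d, np.linspace(0, 1, 11))
        means = [
            r2[(d >= edges[i]) & (d < edges[i + 1])].mean() for i in range(10)
        ]
        assert spearmanr(range(10), means).statistic <= 0

    def test_planted_sdr_elevates_ld_and_bounds_recovered(
        self, population, population_ld
    ):
        _, _, landscape = population_ld
        lo, hi = population.truth.params["sdr_interval"]
        inside = landscape[
            (landscape.bin_start >= lo) & (landscape.bin_start < hi)
        ]
        flank = landscape[
            ((landscape.bin_start >= lo - 200_000) & (landscape.bin_start < lo))
            | ((landscape.bin_start >= hi) & (landscape.bin_start < hi + 200_000))
        ]
        assert (
            np.nanmean(inside.mean_r2) - np.nanmean(flank.mean_r2) > 0.3
        )
        interval = recover_high_ld_interval(landscape)
        assert interval is not None
        assert abs(interval[0] - lo) <= 2000
        assert abs(interval[1] - hi) <= 2000


class TestHomHetRatio:
    def test_ratio_arithmetic_and_infinite_flag(self):
        g = np.array(
            [[2, 1, 0], [2, 1, 0], [2, 1, 0], [2, 0, 0], [2, 0, 0], [2, 0, 0]],
            dtype=np.int8,
        ).reshape(6, 3)
        m = matrix([10, 20, 30, 40, 50, 60], g)
        df = hom_het_ratio(m)
        assert np.isinf(df.loc[df["sample"] == "s0", "ratio"].iloc[0])
        assert bool(df.loc[df["sample"] == "s0", "infinite"].iloc[0])
        assert df.loc[df["sample"] == "s1", "ratio"].iloc[0] == pytest.approx(0.0)

    def test_six_hom_three_het_gives_two(self):
        g = np.array([[2]] * 6 + [[1]] * 3, dtype=np.int8)
        m = matrix(list(range(10, 100, 10)), g)
        df = hom_het_ratio(m)
        assert df["ratio"].iloc[0] == pytest.approx(2.0)

    def test_heterogametic_samples_have_lower_ratio_in_sdr(self, population):
        from grapesdr.ld import compare_ratio_groups

        m = population.genotype_matrix()
        lo, hi = population.truth.params["sdr_interval"]
        ratios = hom_het_ratio(m, (lo, hi))
        flags = population.truth.params["heterogametic"]
        group_of = {
            s: ("het" if f else "hom") for s, f in zip(m.samples, flags)
        }
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            H, p, dunn = compare_ratio_groups(ratios, group_of)
        df = ratios.assign(group=ratios["sample"].map(group_of))
        finite = df[~df["infinite"]]
        assert (
            finite[finite.group == "het"]["ratio"].median()
            < finite[finite.group == "hom"]["ratio"].median()
        )
        assert p < 0.05
        assert (dunn["p_adj"] < 0.05).any()
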