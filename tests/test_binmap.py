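"""Tests of bin construction, distortion screening, imputation and the map."""

import numpy as np
import pandas as pd
import pytest

from binqtl import (
    BinMap,
    CallerConfig,
    GenomeLayout,
    LineMosaic,
    SimulationParams,
    adjacent_rf,
    build_genetic_map,
    call_population,
    construct_bins,
    count_crossovers,
    filter_distorted_bins,
    impute_genotypes,
    kosambi_cm,
    kosambi_r,
    pairwise_rf,
    recombination_profile,
    ril_R_from_r,
    ril_r_from_R,
    simulate_population,
    test_segregation_distortion,
)
from binqtl.genome import Chromosome, HET, MISSING, P1, P2


def _mosaic(blocks, chrom="chr1", length=None):
    starts, ends, genos, counts = zip(*blocks)
    length = length or max(ends)
    return LineMosaic(
        chrom, length,
        np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64),
        np.array(genos, dtype=np.int8), np.array(counts, dtype=np.int64),
    )


def _layout_1chrom(length=30_000_000, cm=100.0):
    return GenomeLayout(
        [Chromosome("chr1", length, cm)],
        {"chr1": np.arange(50_000, length + 1, 50_000, dtype=np.int64)},
    )


def _binmap(G, bin_bp=100_000, chrom="chr1"):
    G = np.asarray(G, dtype=np.int8)
    n = G.shape[1]
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * bin_bp + 1,
            "end": (np.arange(n) + 1) * bin_bp,
        }
    )
    return BinMap(bins, G, [f"L{i}" for i in range(G.shape[0])], {chrom: n * bin_bp})


class TestConstructBins:
    def test_union_of_breakpoints(self):
        layout = _layout_1chrom()
        mosaics = {
            "a": {"chr1": _mosaic([(1, 10_000_000, P1, 50), (10_000_001, 30_000_000, P2, 50)])},
            "b": {"chr1": _mosaic([(1, 10_000_000, P2, 50), (10_000_001, 20_000_000, P1, 50), (20_000_001, 30_000_000, P2, 50)])},
            "c": {"chr1": _mosaic([(1, 30_000_000, P1, 150)])},
        }
        bm = construct_bins(mosaics, layout)
        assert bm.n_bins == 3
        assert list(bm.bins["start"]) == [1, 10_000_001, 20_000_001]
        assert list(bm.bins["end"]) == [10_000_000, 20_000_000, 30_000_000]
        # genotype matrix reflects each line's covering block
        assert list(bm.G[bm.lines.index("a")]) == [P1, P2, P2]
        assert list(bm.G[bm.lines.index("c")]) == [P1, P1, P1]

    def test_sub5kb_bins_merge(self):
        layout = _layout_1chrom()
        mosaics = {
            "a": {"chr1": _mosaic([(1, 10_000_000, P1, 50), (10_000_001, 30_000_000, P2, 50)])},
            "b": {"chr1": _mosaic([(1, 10_003_000, P1, 50), (10_003_001, 30_000_000, P2, 50)])},
        }
        bm = construct_bins(mosaics, layout)
        # boundaries 3 kb apart would create a 3 kb bin; it must be merged
        widths = bm.bins["end"] - bm.bins["start"] + 1
        assert (widths >= 5_000).all()
        assert bm.n_bins == 2

    def test_no_breakpoints_gives_one_bin(self):
        layout = _layout_1chrom()
        mosaics = {
            "a": {"chr1": _mosaic([(1, 30_000_000, P1, 100)])},
            "b": {"chr1": _mosaic([(1, 30_000_000, P2, 100)])},
        }
        bm = construct_bins(mosaics, layout)
        assert bm.n_bins == 1

    def test_bins_tile_chromosome(self, small_layout, called_population):
        retained, _ = called_population
        bm = construct_bins(retained, small_layout)
        for chrom in small_layout.chrom_names:
            sub = bm.bins[bm.bins["chrom"] == chrom]
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == small_layout.chrom(chrom).length_bp
            assert (sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy() + 1).all()
        # every cell defined (possibly MISSING): right shape and codes
        assert bm.G.shape == (len(retained), bm.n_bins)
        assert set(np.unique(bm.G)) <= {P1, HET, P2, MISSING}


class TestSegregationDistortion:
    def test_balanced_counts_not_flagged(self):
        G = np.array([[P1] * 510 + [P2] * 511]).T  # one bin, 1021 lines
        res = test_segregation_distortion(_binmap(G))
        assert res["p"].iloc[0] > 0.9
        assert not res["distorted"].iloc[0]

    def test_strong_distortion_flagged_with_expected_statistic(self):
        G = np.array([[P1] * 700 + [P2] * 321]).T
        res = test_segregation_distortion(_binmap(G))
        expect = (700 - 510.5) ** 2 / 510.5 + (321 - 510.5) ** 2 / 510.5
        assert res["chi2"].iloc[0] == pytest.approx(expect, rel=1e-12)
        assert res["distorted"].iloc[0]

    def test_exact_expectation_gives_zero_statistic(self):
        G = np.array([[P1] * 50 + [P2] * 50]).T
        res = test_segregation_distortion(_binmap(G))
        assert res["chi2"].iloc[0] == 0.0

    def test_uninformative_bin_excluded_from_correction(self):
        G = np.full((5, 2), MISSING, dtype=np.int8)
        G[:, 0] = [P1, P1, P2, P2, P1]
        G[0, 1] = P1  # single informative line -> untestable
        res = test_segregation_distortion(_binmap(G))
        assert np.isnan(res["p"].iloc[1])
        # Bonferroni denominator is 1, so bin 0 keeps its raw p
        assert res["p_bonferroni"].iloc[0] == pytest.approx(res["p"].iloc[0])


class TestFilterDistortedBins:
    def _map_with_freqs(self, f_p1, f_p2, f_het, n=100):
        n_p1 = int(round(f_p1 * n))
        n_p2 = int(round(f_p2 * n))
        n_het = int(round(f_het * n))
        col = [P1] * n_p1 + [P2] * n_p2 + [HET] * n_het
        col += [MISSING] * (n - len(col))
        return _binmap(np.array([col]).T)

    def test_ratio_above_two_discarded(self):
        bm = self._map_with_freqs(0.60, 0.25, 0.0)
        out, report = filter_distorted_bins(bm)
        assert out.n_bins == 0
        assert report["n_discarded"] == 1

    def test_ratio_exactly_two_retained(self):
        bm = self._map_with_freqs(0.50, 0.25, 0.25)  # het 25%? no: keep het low
        bm = self._map_with_freqs(0.50, 0.25, 0.10)
        out, _ = filter_distorted_bins(bm)
        assert out.n_bins == 1

    def test_high_het_discarded(self):
        bm = self._map_with_freqs(0.40, 0.40, 0.20)
        out, _ = filter_distorted_bins(bm)
        assert out.n_bins == 0

    def test_zero_minor_frequency_discarded(self):
        bm = self._map_with_freqs(1.0, 0.0, 0.0)
        out, _ = filter_distorted_bins(bm)
        assert out.n_bins == 0


class TestImputation:
    def test_missing_bin_flanked_by_p1_imputed_p1(self):
        G = np.array([[P1, MISSING, P1]] * 30, dtype=np.int8)
        G[:10] = [P2, P2, P2]  # keep adjacent R estimable
        out = impute_genotypes(_binmap(G))
        assert (out.G[10:, 1] == P1).all()

    def test_het_set_missing_then_filled(self):
        G = np.array([[P1, HET, P1]] * 30, dtype=np.int8)
        G[:10] = [P2, P2, P2]
        out = impute_genotypes(_binmap(G))
        assert (out.G != HET).all()
        assert (out.G[10:, 1] == P1).all()

    def test_missing_filled_from_genetically_closer_flank(self):
        # hand Viterbi on a 3-bin chain: R(0,1) small, R(1,2) large ->
        # the middle missing bin copies the left flank
        rows = []
        for _ in range(40):
            rows.append([P1, P1, P2])
            rows.append([P2, P2, P1])
        rows.append([P1, MISSING, P2])
        G = np.array(rows, dtype=np.int8)
        out = impute_genotypes(_binmap(G))
        assert out.G[-1, 1] == P1

    def test_no_missing_identity(self):
        G = np.array([[P1, P1, P2], [P2, P2, P1], [P1, P2, P2]] * 10, dtype=np.int8)
        out = impute_genotypes(_binmap(G))
        assert np.array_equal(out.G, G)

    def test_fully_missing_chromosome_left_missing_with_warning(self):
        G = np.array([[P1, P1], [P2, P2], [MISSING, MISSING]], dtype=np.int8)
        with pytest.warns(UserWarning, match="left missing"):
            out = impute_genotypes(_binmap(G))
        assert (out.G[2] == MISSING).all()


class TestRecombinationFractions:
    def test_identical_columns_give_zero(self):
        G = np.array([[P1, P1]] * 20 + [[P2, P2]] * 20, dtype=np.int8)
        rf = adjacent_rf(_binmap(G))
        assert rf["R"].iloc[0] == 0.0
        assert rf["r"].iloc[0] == 0.0

    def test_ril_correction_value(self):
        assert ril_r_from_R(0.4) == pytest.approx(0.4 / 1.2, rel=1e-12)

    def test_independent_columns_clamp_near_half(self):
        rng = np.random.default_rng(0)
        G = rng.choice([P1, P2], size=(2000, 2)).astype(np.int8)
        rf = adjacent_rf(_binmap(G))
        assert 0.4 < rf["R"].iloc[0] <= 0.55
        assert rf["r"].iloc[0] < 0.5

    def test_pairwise_matches_brute_force_counts(self, rng):
        G = rng.choice([P1, P2, HET, MISSING], size=(30, 6), p=[0.45, 0.45, 0.05, 0.05]).astype(np.int8)
        R = pairwise_rf(_binmap(G))
        for i in range(6):
            for j in range(6):
                info = (
                    np.isin(G[:, i], (P1, P2)) & np.isin(G[:, j], (P1, P2))
                )
                if info.sum() == 0:
                    assert np.isnan(R[i, j])
                else:
                    expect = float(np.mean(G[info, i] != G[info, j]))
                    assert R[i, j] == pytest.approx(expect, abs=1e-12)

    def test_low_information_flagged(self):
        G = np.array([[P1, P1]] * 5 + [[MISSING, MISSING]] * 20, dtype=np.int8)
        rf = adjacent_rf(_binmap(G))
        assert rf["low_confidence"].iloc[0]


def selfed_ril_R_oracle(r: float, n_generations: int = 400) -> float:
    """Brute-force two-locus selfing recursion to (near) fixation.

    Tracks the distribution over ordered two-locus diplotypes under
    selfing with per-meiosis recombination r, starting from the F1
    (AB/ab).  Returns the probability a fixed line is recombinant.
    Gametes from a diplotype (h1, h2): parental with prob (1-r)/2 each,
    recombinant with prob r/2 each.
    """
    gametes = [(0, 0), (0, 1), (1, 0), (1, 1)]  # alleles at locus1, locus2
    # state: unordered pair of gametes
    from collections import defaultdict

    def gamete_dist(h1, h2):
        out = defaultdict(float)
        out[h1] += (1 - r) / 2
        out[h2] += (1 - r) / 2
        out[(h1[0], h2[1])] += r / 2
        out[(h2[0], h1[1])] += r / 2
        return out

    state = {tuple(sorted(((0, 0), (1, 1)))): 1.0}
    for _ in range(n_generations):
        new = defaultdict(float)
        for (h1, h2), prob in state.items():
            if h1 == h2:  # fixed line breeds true
                new[(h1, h2)] += prob
                continue
            gd = gamete_dist(h1, h2)
            for g1, p1 in gd.items():
                for g2, p2 in gd.items():
                    new[tuple(sorted((g1, g2)))] += prob * p1 * p2
        state = dict(new)
    fixed = {k: v for k, v in state.items() if k[0] == k[1]}
    total = sum(fixed.values())
    recomb = sum(v for (h, _), v in fixed.items() if h in ((0, 1), (1, 0)))
    return recomb / total


class TestKosambi:
    def test_spot_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.25) == pytest.approx(25 * np.log(3), rel=1e-12)
        assert kosambi_cm(0.25) == pytest.approx(27.465, abs=5e-4)
        assert kosambi_cm(0.1) == pytest.approx(25 * np.log(1.5), rel=1e-12)
        assert kosambi_cm(0.1) == pytest.approx(10.137, abs=5e-4)

    def test_round_trip_machine_precision(self):
        grid = np.linspace(0.0, 0.49, 200)
        back = kosambi_r(kosambi_cm(grid))
        assert np.max(np.abs(grid - back)) < 1e-12

    def test_rejects_r_at_least_half(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)

    @pytest.mark.parametrize("r", [0.01, 0.05, 0.1, 0.2])
    def test_ril_correction_matches_selfing_oracle(self, r):
        R = selfed_ril_R_oracle(r)
        assert ril_R_from_r(r) == pytest.approx(R, abs=1e-6)
        assert ril_r_from_R(R) == pytest.approx(r, abs=1e-6)


class TestGeneticMap:
    def test_single_bin_chromosome_zero_cM(self):
        G = np.array([[P1], [P2], [P1], [P2]] * 5, dtype=np.int8)
        gmap, summary = build_genetic_map(_binmap(G))
        assert gmap.total_cM == 0.0
        assert summary["total_cM"].iloc[0] == 0.0

    def test_mean_interval_convention(self):
        # three bins with planted adjacent R giving known interval cM
        rng = np.random.default_rng(1)
        n = 4000
        col0 = rng.choice([P1, P2], size=n)
        # R chosen to make intervals ~1 and ~2 cM
        flip1 = rng.random(n) < ril_R_from_r(kosambi_r(1.0))
        col1 = np.where(flip1, P1 + P2 - col0, col0)
        flip2 = rng.random(n) < ril_R_from_r(kosambi_r(2.0))
        col2 = np.where(flip2, P1 + P2 - col1, col1)
        G = np.stack([col0, col1, col2], axis=1).astype(np.int8)
        gmap, summary = build_genetic_map(_binmap(G))
        total = summary["total_cM"].iloc[0]
        assert summary["mean_interval_cM"].iloc[0] == pytest.approx(total / 2)
        assert total == pytest.approx(3.0, abs=0.6)

    def test_map_positions_monotone(self, small_layout, called_population):
        retained, _ = called_population
        bm = construct_bins(retained, small_layout)
        bm, _ = filter_distorted_bins(bm)
        imputed = impute_genotypes(bm)
        gmap, _ = build_genetic_map(imputed)
        for chrom in small_layout.chrom_names:
            cm = gmap.table.loc[gmap.table["chrom"] == chrom, "cM"].to_numpy()
            assert (np.diff(cm) >= 0).all()

    def test_simulated_map_length_recovery(self):
        # one 100 cM chromosome, dense lines: recovered length within 10%
        layout = GenomeLayout.regular(
            n_chromosomes=1, length_bp=100_000_000, genetic_length_cM=100.0
        )
        truth, obs = simulate_population(layout, SimulationParams(n_lines=300, seed=17))
        retained, _ = call_population(obs, layout)
        bm = construct_bins(retained, layout)
        bm, _ = filter_distorted_bins(bm)
        gmap, _ = build_genetic_map(impute_genotypes(bm))
        assert gmap.total_cM == pytest.approx(100.0, rel=0.10)


class TestCrossoverCounting:
    def test_toy_counts(self):
        G = np.array(
            [[P1, P2, P1], [P1, P1, P2], [P2, P2, P2]], dtype=np.int8
        )
        out = count_crossovers(_binmap(G))
        assert out["total"] == 3
        assert out["mean_per_line_per_chrom"] == pytest.approx(1.0)

    def test_monotone_line_has_zero(self):
        G = np.array([[P1, P1, P1], [P2, P2, P2]], dtype=np.int8)
        assert count_crossovers(_binmap(G))["total"] == 0

    def test_missing_gaps_do_not_create_crossovers(self):
        G = np.array([[P1, MISSING, P1], [P2, MISSING, P2]], dtype=np.int8)
        assert count_crossovers(_binmap(G))["total"] == 0


class TestRecombinationProfile:
    def test_uniform_map_gives_flat_profile(self):
        rng = np.random.default_rng(2)
        n, B = 2000, 30
        R = ril_R_from_r(kosambi_r(1.0))
        G = np.empty((n, B), dtype=np.int8)
        G[:, 0] = rng.choice([P1, P2], size=n)
        for k in range(1, B):
            flip = rng.random(n) < R
            G[:, k] = np.where(flip, P1 + P2 - G[:, k - 1], G[:, k - 1])
        bm = _binmap(G, bin_bp=1_000_000)
        layout = GenomeLayout(
            [Chromosome("chr1", B * 1_000_000, 100.0)],
            {"chr1": np.arange(50_000, B * 1_000_000, 50_000, dtype=np.int64)},
        )
        gmap, _ = build_genetic_map(bm)
        profile, _ = recombination_profile(gmap, bm, layout)
        interior = profile["cM_per_Mb"].iloc[2:-2]
        assert interior.std() / interior.mean() < 0.5

    def test_planted_intensity_correlates_with_profile(self):
        n_mb = 150
        weights = np.concatenate(
            [np.full(n_mb // 2, 0.2), np.full(n_mb - n_mb // 2, 1.8)]
        )
        layout = GenomeLayout.regular(
            n_chromosomes=1, crossover_intensity=None
        )
        layout = GenomeLayout(
            layout.chromosomes, layout.snp_positions, {"chr1": weights}
        )
        truth, obs = simulate_population(layout, SimulationParams(n_lines=250, seed=23))
        retained, _ = call_population(obs, layout)
        bm = construct_bins(retained, layout)
        bm, _ = filter_distorted_bins(bm)
        gmap, _ = build_genetic_map(impute_genotypes(bm))
        track = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_mb) * 1_000_000 + 1,
                "value": weights,
            }
        )
        profile, corr = recombination_profile(gmap, bm, layout, {"intensity": track})
        r = corr.set_index("track").loc["intensity", "pearson_r"]
        assert r > 0.5

    def test_track_on_wrong_tiling_rejected(self, small_layout, called_population):
        retained, _ = called_population
        bm = construct_bins(retained, small_layout)
        gmap, _ = build_genetic_map(impute_genotypes(bm))
        bad = pd.DataFrame({"chrom": "chr1", "start": [17], "value": [1.0]})
        with pytest.raises(ValueError, match="tiling"):
            recombination_profile(gmap, bm, small_layout, {"bad": bad})
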