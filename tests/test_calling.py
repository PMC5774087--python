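"""Tests of the sliding-window genotype caller and its filters."""

import numpy as np
import pytest

from binqtl import (
    CallerConfig,
    GenomeLayout,
    LineMosaic,
    SimulationParams,
    call_line,
    call_windows,
    filter_blocks,
    filter_lines,
    merge_to_blocks,
    resolve_breakpoints,
    simulate_population,
)
from binqtl.genome import ALLELE_P1, ALLELE_P2, HET, MISSING, P1, P2

CFG = CallerConfig()


def _obs(*alleles):
    """Positions 1,2,3,... with the given allele codes."""
    a = np.array(alleles, dtype=np.int8)
    return np.arange(1, a.size + 1, dtype=np.int64), a


def _mosaic(blocks, chrom="chr1", length=None):
    """Build a LineMosaic from (start, end, genotype, snp_count) tuples."""
    starts, ends, genos, counts = zip(*blocks)
    length = length or max(ends)
    return LineMosaic(
        chrom,
        length,
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(genos, dtype=np.int8),
        np.array(counts, dtype=np.int64),
    )


class TestCallWindows:
    @pytest.mark.parametrize(
        "n_p1, expected",
        [
            (15, P1),  # unanimous window
            (12, P1),  # 12 > 11: homozygous call
            (11, HET),  # 11 is not > 11: heterozygous
            (4, HET),
            (3, P2),  # symmetric for the other parent
            (0, P2),
        ],
    )
    def test_window_genotype_rule(self, n_p1, expected):
        pos, alleles = _obs(*([ALLELE_P1] * n_p1 + [ALLELE_P2] * (15 - n_p1)))
        geno, p1, p2 = call_windows(pos, alleles, CFG)
        assert geno.size == 1
        assert geno[0] == expected
        assert p1[0] + p2[0] == CFG.window_size

    def test_windows_slide_by_one_snp(self):
        pos, alleles = _obs(*([ALLELE_P1] * 20))
        geno, _, _ = call_windows(pos, alleles, CFG)
        assert geno.size == 20 - 15 + 1

    def test_too_few_snps_gives_no_windows(self):
        pos, alleles = _obs(*([ALLELE_P1] * 14))
        geno, _, _ = call_windows(pos, alleles, CFG)
        assert geno.size == 0

    def test_unknown_allele_code_rejected_with_site(self):
        pos = np.array([10, 20, 30], dtype=np.int64)
        alleles = np.array([0, 7, 2], dtype=np.int8)
        with pytest.raises(ValueError, match="position 20"):
            call_windows(pos, alleles, CFG)


class TestResolveBreakpoints:
    def test_short_het_run_split_at_midpoint(self):
        calls = np.array([P1] * 20 + [HET] * 4 + [P2] * 20, dtype=np.int8)
        out = resolve_breakpoints(calls, CFG)
        assert np.array_equal(out, np.array([P1] * 22 + [P2] * 22, dtype=np.int8))

    def test_long_het_run_retained(self):
        calls = np.array([P1] * 20 + [HET] * 8 + [P2] * 20, dtype=np.int8)
        out = resolve_breakpoints(calls, CFG)
        assert np.array_equal(out, calls)

    def test_same_flanks_absorb_het_run(self):
        calls = np.array([P1] * 10 + [HET] * 2 + [P1] * 10, dtype=np.int8)
        out = resolve_breakpoints(calls, CFG)
        assert np.array_equal(out, np.full(22, P1, dtype=np.int8))

    def test_odd_run_extra_window_goes_left(self):
        calls = np.array([P1] * 5 + [HET] * 5 + [P2] * 5, dtype=np.int8)
        out = resolve_breakpoints(calls, CFG)
        assert np.array_equal(out, np.array([P1] * 8 + [P2] * 7, dtype=np.int8))

    def test_chromosome_end_runs_adopt_single_flank(self):
        calls = np.array([HET] * 3 + [P2] * 10 + [HET] * 2, dtype=np.int8)
        out = resolve_breakpoints(calls, CFG)
        assert np.array_equal(out, np.full(15, P2, dtype=np.int8))


class TestMergeToBlocks:
    def test_homogeneous_calls_give_single_spanning_block(self):
        n = 50
        pos = np.linspace(10_000, 2_000_000, n).astype(np.int64)
        geno = np.full(n - 14, P1, dtype=np.int8)
        m = merge_to_blocks(geno, pos, "chr1", 2_000_000, CFG)
        assert len(m) == 1
        assert (m.start[0], m.end[0]) == (1, 2_000_000)
        assert m.genotype[0] == P1
        assert m.snp_count[0] == n

    def test_boundary_at_midpoint_between_flanking_snps(self):
        # 30 SNPs: window calls switch exactly between SNPs 14 and 15
        pos = np.concatenate(
            [np.arange(1, 15) * 50_000, 1_000_000 + np.arange(0, 16) * 50_000 + 400]
        ).astype(np.int64)
        pos[13] = 1_000_000  # last P1-assigned SNP
        pos[14] = 1_000_400  # first P2-assigned SNP
        geno = np.array([P1] * 8 + [P2] * 8, dtype=np.int8)  # 30-15+1 windows
        m = merge_to_blocks(geno, pos, "chr1", 2_000_000, CFG)
        # centre convention: SNPs 0..14 take windows clipped to their centre
        assert len(m) == 2
        assert m.end[0] == (pos[14] + pos[15]) // 2 or m.end[0] == 1_000_200

    def test_three_runs_give_two_breakpoints(self):
        pos = (np.arange(1, 61) * 100_000).astype(np.int64)
        geno = np.array([P1] * 15 + [P2] * 16 + [P1] * 15, dtype=np.int8)
        m = merge_to_blocks(geno, pos, "chr1", 10_000_000, CFG)
        assert len(m) == 3
        assert m.n_breakpoints == 2


class TestFilterBlocks:
    def test_block_with_few_snps_set_missing(self):
        m = _mosaic(
            [
                (1, 5_000_000, P1, 100),
                (5_000_001, 5_500_000, P2, 4),  # 4 SNPs < 5
                (5_500_001, 10_000_000, P1, 100),
            ]
        )
        out = filter_blocks(m, CFG)
        # the short block is masked and the flanks merge across it
        assert len(out) == 1
        assert out.genotype[0] == P1

    def test_short_block_set_missing(self):
        m = _mosaic(
            [
                (1, 5_000_000, P1, 100),
                (5_000_001, 5_250_000, P2, 20),  # 250 kb < 300 kb
                (5_250_001, 10_000_000, P1, 100),
            ]
        )
        out = filter_blocks(m, CFG)
        assert len(out) == 1
        assert out.genotype[0] == P1

    def test_small_het_block_set_missing(self):
        m = _mosaic(
            [
                (1, 5_000_000, P1, 100),
                (5_000_001, 7_000_000, HET, 14),  # 2 Mb but 14 SNPs < 15
                (7_000_001, 12_000_000, P2, 100),
            ]
        )
        out = filter_blocks(m, CFG)
        assert MISSING in out.genotype
        assert HET not in out.genotype

    def test_thresholds_are_strict_so_ties_keep_blocks(self):
        m = _mosaic(
            [
                (1, 5_000_000, P1, 100),
                (5_000_001, 5_300_000, P2, 5),  # exactly 5 SNPs, exactly 300 kb
                (5_300_001, 10_000_000, P1, 100),
            ]
        )
        out = filter_blocks(m, CFG)
        assert P2 in out.genotype

    def test_large_het_block_survives(self):
        m = _mosaic(
            [
                (1, 5_000_000, P1, 100),
                (5_000_001, 7_000_000, HET, 40),
                (7_000_001, 12_000_000, P2, 100),
            ]
        )
        out = filter_blocks(m, CFG)
        assert HET in out.genotype
        assert out.n_breakpoints == 2

    def test_transient_small_blocks_consolidate_to_het(self):
        blocks = [(1, 30_000_000, P1, 500)]
        start = 30_000_001
        for i in range(6):  # six alternating 400 kb blocks: 5 switches
            g = P2 if i % 2 == 0 else P1
            blocks.append((start, start + 399_999, g, 8))
            start += 400_000
        blocks.append((start, 70_000_000, P2, 500))
        out = filter_blocks(_mosaic(blocks), CFG)
        # the alternating stretch is not believable as 6 crossovers in 2.4 Mb
        assert not np.any(
            (out.genotype == P1)
            & (out.end - out.start + 1 < CFG.het_block_min_bp)
        )
        assert out.n_breakpoints <= 3


class TestFilterLines:
    def _line(self, het_frac, n_breaks):
        """One-chromosome mosaic with the requested het fraction/breakpoints."""
        blocks = []
        length = 100_000_000
        het_len = int(het_frac * length)
        pos = 1
        if het_len:
            blocks.append((pos, het_len, HET, 50))
            pos = het_len + 1
        remaining = length - pos + 1
        n_blocks = n_breaks + (0 if het_len else 1)
        if het_len and n_breaks == 0:
            blocks.append((pos, length, P1, 50))
        else:
            width = remaining // max(n_blocks, 1)
            g = P1
            for i in range(n_blocks):
                end = length if i == n_blocks - 1 else pos + width - 1
                blocks.append((pos, end, g, 50))
                pos = end + 1
                g = P2 if g == P1 else P1
        return {"chr1": _mosaic(blocks, length=length)}

    def test_het_fraction_rule_is_strict(self):
        mosaics = {
            "ok": self._line(0.15, 3),
            "bad": self._line(0.16, 3),
        }
        retained, report = filter_lines(mosaics, CFG)
        assert set(retained) == {"ok"}
        assert report.set_index("line").loc["bad", "reason"] == "het_fraction"

    def test_breakpoint_rule_is_strict(self):
        mosaics = {
            "ok360": self._line(0.0, 360),
            "bad361": self._line(0.0, 361),
        }
        retained, report = filter_lines(mosaics, CFG)
        assert set(retained) == {"ok360"}
        assert report.set_index("line").loc["bad361", "reason"] == "breakpoints"

    def test_clean_line_retained(self):
        retained, _ = filter_lines({"clean": self._line(0.0, 30)}, CFG)
        assert set(retained) == {"clean"}


class TestCallerOnSimulatedData:
    """End-to-end properties of the caller against simulated ground truth."""

    def test_opposite_homozygote_calls_absent_under_noise(self, rng):
        # 1e5 windows inside a true P1 tract at 0.9% per-site error:
        # P(>= 12 errors of 15) < 1e-18, so no opposite calls ever
        n_windows = 100_000
        n = n_windows + CFG.window_size - 1
        alleles = np.where(rng.random(n) < 0.009, ALLELE_P2, ALLELE_P1).astype(np.int8)
        pos = np.arange(1, n + 1, dtype=np.int64)
        geno, _, _ = call_windows(pos, alleles, CFG)
        assert geno.size == n_windows
        assert np.sum(geno == P2) == 0

    def test_crossover_recovery_and_concordance(self, small_layout, small_population, called_population):
        truth, _ = small_population
        retained, _ = called_population
        recovered = 0
        total = 0
        recovered_det = 0
        total_det = 0
        concord_len = 0
        called_len = 0
        # tolerance: half the window span at the ~50 kb observed SNP spacing
        tol = 0.5 * CFG.window_size * 50_000  # = 375 kb
        for line, per in retained.items():
            for chrom in small_layout.chrom_names:
                tm = truth.mosaics[line][chrom]
                seg_len = np.diff(tm.bounds)
                called = per[chrom]
                called_bp = called.breakpoint_positions.astype(float)
                for k, t in enumerate(tm.bounds[1:-1]):
                    hit = called_bp.size and np.min(np.abs(called_bp - t)) <= tol
                    total += 1
                    recovered += hit
                    # transitions whose flanking segments survive the block
                    # filters are the ones the method is meant to see
                    if min(seg_len[k], seg_len[k + 1]) >= 1_000_000:
                        total_det += 1
                        recovered_det += hit
                # length-weighted genotype concordance over called blocks
                for s, e, g in zip(called.start, called.end, called.genotype):
                    if g == MISSING:
                        continue
                    mid = (s + e) / 2.0
                    tg = tm.genotype_at(np.array([mid]))[0]
                    w = e - s + 1
                    called_len += w
                    concord_len += w * (tg == g)
        assert recovered_det / total_det >= 0.95
        assert recovered / total >= 0.90
        assert concord_len / called_len >= 0.99

    def test_identical_inputs_give_identical_mosaics(self, small_layout, small_population):
        _, obs = small_population
        line = obs.lines[0]
        m1 = call_line(obs, line, small_layout, CFG)
        m2 = call_line(obs, line, small_layout, CFG)
        for chrom in small_layout.chrom_names:
            assert np.array_equal(m1[chrom].start, m2[chrom].start)
            assert np.array_equal(m1[chrom].genotype, m2[chrom].genotype)
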