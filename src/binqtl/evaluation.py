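"""Calibration and recovery experiments run on the synthetic generator.

These are the package's evaluation procedures: window-caller error
robustness, selfing-heterozygosity recovery, permutation-threshold
family-wise error calibration, and planted-QTL detection/coverage.
Each experiment builds its own inputs from the simulator, runs the
pipeline components under test, and returns measured quantities; they
back both the test suite and the reproducibility script.
"""

from __future__ import annotations

import numpy as np

from .binmap import BinMap, build_genetic_map
from .calling import CallerConfig, call_windows
from .genome import ALLELE_P1, ALLELE_P2, GenomeLayout, HET, P1, P2
from .qtl import (
    ScanConfig,
    cim_scan,
    encode_genotypes,
    find_peaks_and_intervals,
    permutation_threshold,
    select_cofactors,
)
from .simulate import SimulationParams, simulate_population

__all__ = [
    "window_error_robustness",
    "selfing_heterozygosity",
    "truth_binmap",
    "permutation_fwer",
    "qtl_recovery",
]


def window_error_robustness(
    n_windows: int = 100_000,
    error_rate: float = 0.009,
    seed: int = 0,
    cfg: CallerConfig = CallerConfig(),
) -> dict:
    """Opposite-homozygote window calls inside a noisy homozygous tract.

    Simulates one long true-P1 tract with per-site miscalls and counts
    windows the caller assigns to the *other* parent.  The binomial
    tail P(X >= 12 | n=15, p=0.009) is ~1e-19, so the expected count
    is zero even at 1e5 windows.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_windows + cfg.window_size - 1
    alleles = np.where(rng.random(n_sites) < error_rate, ALLELE_P2, ALLELE_P1).astype(
        np.int8
    )
    pos = np.arange(1, n_sites + 1, dtype=np.int64)
    geno, _, _ = call_windows(pos, alleles, cfg)
    return {
        "n_windows": int(geno.size),
        "opposite_calls": int(np.sum(geno == P2)),
        "het_calls": int(np.sum(geno == HET)),
    }


def selfing_heterozygosity(
    n_lines: int = 500,
    n_generations: int = 6,
    seed: int = 0,
) -> dict:
    """Mean residual heterozygous genome fraction after selfing.

    Closed-form expectation is (1/2)^g per site; the experiment
    measures the physical HET fraction of the true mosaics over
    ``n_lines`` lines on two 150 cM chromosomes.
    """
    layout = GenomeLayout.regular(n_chromosomes=2, snp_spacing_bp=500_000)
    params = SimulationParams(
        n_lines=n_lines,
        n_selfing_generations=n_generations,
        site_sampling_rate=1.0,
        error_rate_p1=0.0,
        error_rate_p2=0.0,
        seed=seed,
    )
    truth, _ = simulate_population(layout, params)
    fractions = np.array([truth.het_fraction(l) for l in truth.lines])
    expect = 0.5**n_generations
    return {
        "mean_het_fraction": float(fractions.mean()),
        "expected": expect,
        "binomial_se": float(np.sqrt(expect * (1 - expect) / n_lines)),
        "n_lines": n_lines,
    }


def truth_binmap(
    n_lines: int,
    n_chromosomes: int,
    bins_per_chrom: int,
    seed: int,
    genetic_length_cM: float = 120.0,
    length_bp: int = 150_000_000,
) -> BinMap:
    """Bin genotype matrix read off the simulator's true mosaics.

    Bins are an even tiling of each chromosome; each cell is the true
    genotype at the bin midpoint (HET retained).  This isolates the
    scan statistics from genotype-calling noise.
    """
    import pandas as pd

    layout = GenomeLayout.regular(
        n_chromosomes=n_chromosomes,
        length_bp=length_bp,
        genetic_length_cM=genetic_length_cM,
        snp_spacing_bp=1_000_000,  # observations unused; keep them cheap
    )
    truth, _ = simulate_population(
        layout, SimulationParams(n_lines=n_lines, seed=seed)
    )
    width = length_bp // bins_per_chrom
    rows = []
    for chrom in layout.chrom_names:
        for b in range(bins_per_chrom):
            rows.append(
                {
                    "chrom": chrom,
                    "start": b * width + 1,
                    "end": (b + 1) * width if b < bins_per_chrom - 1 else length_bp,
                }
            )
    bins = pd.DataFrame(rows)
    mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
    chrom_arr = bins["chrom"].to_numpy()
    G = np.empty((n_lines, len(bins)), dtype=np.int8)
    for li, line in enumerate(truth.lines):
        for chrom in layout.chrom_names:
            idx = np.flatnonzero(chrom_arr == chrom)
            G[li, idx] = truth.mosaics[line][chrom].genotype_at(mids[idx])
    return BinMap(
        bins, G, list(truth.lines), {c.name: c.length_bp for c in layout.chromosomes}
    )


def permutation_fwer(
    n_traits: int = 100,
    n_lines: int = 500,
    n_bins: int = 500,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the permutation threshold on null traits.

    One simulated RIL bin matrix; for each independent null trait the
    genome-wide max LOD is compared against its own permutation
    threshold.  The hit rate estimates the family-wise error and should
    match ``alpha`` within binomial sampling bounds.
    """
    n_chrom = 5
    bm = truth_binmap(n_lines, n_chrom, n_bins // n_chrom, seed)
    gmap, _ = build_genetic_map(bm)
    X, info = encode_genotypes(bm)
    cm = gmap.table["cM"].to_numpy()
    ci = bm.chrom_index()
    rng = np.random.default_rng(seed + 1)
    cfg = ScanConfig(n_permutations=n_permutations, alpha=alpha, seed=seed)
    hits = 0
    for t in range(n_traits):
        y = rng.normal(0.0, 1.0, n_lines)
        cof = select_cofactors(X, y, cfg)
        lod = cim_scan(X, y, cof, cm, ci, cfg, info)
        thr, _ = permutation_threshold(
            X, y, cm, ci, cfg, rng=np.random.default_rng(seed + 1000 + t),
            informative=info,
        )
        hits += np.nanmax(lod) > thr
    lo = alpha - 1.96 * np.sqrt(alpha * (1 - alpha) / n_traits)
    hi = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / n_traits)
    return {
        "fwer": hits / n_traits,
        "n_traits": n_traits,
        "alpha": alpha,
        "binomial_bounds": (max(lo, 0.0), hi),
    }


def qtl_recovery(
    n_replicates: int = 20,
    n_lines: int = 500,
    n_bins: int = 2000,
    pves: tuple[float, ...] = (0.08, 0.05, 0.02),
    n_permutations: int = 200,
    seed: int = 0,
) -> dict:
    """Detection and interval coverage of planted additive QTLs.

    Each replicate simulates a fresh population, plants one QTL per
    entry of ``pves`` on separate chromosomes, scans with permutation
    thresholds, and records whether a significant peak on the causal
    chromosome has a 1.5-LOD interval covering the causal bin.
    """
    n_chrom = 10
    bins_per = n_bins // n_chrom
    detected = {p: 0 for p in pves}
    covered = {p: 0 for p in pves}
    total_pve = sum(pves)
    effects = [np.sqrt(p / (1.0 - total_pve)) for p in pves]
    for rep in range(n_replicates):
        bm = truth_binmap(n_lines, n_chrom, bins_per, seed + 31 * rep + 1)
        gmap, _ = build_genetic_map(bm)
        X, info = encode_genotypes(bm)
        cm = gmap.table["cM"].to_numpy()
        ci = bm.chrom_index()
        chrom_names = list(dict.fromkeys(bm.bins["chrom"]))
        causal_bins = [
            k * bins_per + bins_per // 2 for k in range(len(pves))
        ]  # one per chromosome, mid-chromosome
        rng = np.random.default_rng(seed + 97 * rep + 2)
        y = rng.normal(0.0, 1.0, n_lines)
        for a, cb in zip(effects, causal_bins):
            y = y + a * X[:, cb]
        cfg = ScanConfig(n_permutations=n_permutations, seed=seed + rep)
        cof = select_cofactors(X, y, cfg)
        lod = cim_scan(X, y, cof, cm, ci, cfg, info)
        thr, _ = permutation_threshold(
            X, y, cm, ci, cfg, rng=np.random.default_rng(seed + 7000 + rep),
            informative=info,
        )
        peaks = find_peaks_and_intervals(lod, thr, bm, cm, cfg)
        for p, cb in zip(pves, causal_bins):
            chrom = chrom_names[causal_bins.index(cb)]
            on_chrom = peaks[peaks["chrom"] == chrom]
            if on_chrom.empty:
                continue
            detected[p] += 1
            start = bm.bins["start"].iloc[cb]
            end = bm.bins["end"].iloc[cb]
            if (
                (on_chrom["interval_start_bp"] <= start)
                & (on_chrom["interval_end_bp"] >= end)
            ).any():
                covered[p] += 1
    return {
        "n_replicates": n_replicates,
        "detected": {p: d / n_replicates for p, d in detected.items()},
        "covered": {p: c / n_replicates for p, c in covered.items()},
    }
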