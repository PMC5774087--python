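"""Population-wide bin map, segregation screening and genetic map.

A *bin* is a genomic interval with no recombination breakpoint in any
retained line: bin boundaries are the union of all lines' block
boundaries, with bins shorter than 5 kb merged away.  Bins are the
atomic markers of the linkage map.  The module also provides the
segregation-distortion chi-square screen, the distorted-bin discard
rule (parental ratio > 2/1 or heterozygosity > 15%), Viterbi ("argmax")
imputation of residual heterozygous/missing cells over a two-state
Markov chain, recombination-fraction estimation with the
Haldane-Waddington correction for selfed RILs (R = 2r/(1+2r)), the
Kosambi map function, per-chromosome map summaries, crossover counts
and the cM/Mb recombination landscape in 1-Mb windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import LineMosaic
from .genome import HET, MISSING, P1, P2, GenomeLayout

__all__ = [
    "BinMap",
    "GeneticMap",
    "construct_bins",
    "test_segregation_distortion",
    "filter_distorted_bins",
    "impute_genotypes",
    "adjacent_rf",
    "pairwise_rf",
    "ril_r_from_R",
    "ril_R_from_r",
    "kosambi_cm",
    "kosambi_r",
    "build_genetic_map",
    "recombination_profile",
    "count_crossovers",
]

MERGE_FLOOR_BP = 5_000  # bins shorter than this are merged into a neighbour


@dataclass
class BinMap:
    """Bin boundaries plus the lines x bins genotype matrix.

    ``bins`` has columns (chrom, start, end), 1-based inclusive;
    ``G`` is int8 coded P1=0, HET=1, P2=2, MISSING=-1 with shape
    (n_lines, n_bins) in the order of ``lines`` / ``bins``.
    """

    bins: pd.DataFrame
    G: np.ndarray
    lines: list[str]
    chrom_lengths: dict[str, int]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def chrom_index(self) -> np.ndarray:
        names = list(dict.fromkeys(self.bins["chrom"]))
        lookup = {n: i for i, n in enumerate(names)}
        return self.bins["chrom"].map(lookup).to_numpy()

    def midpoints(self) -> np.ndarray:
        return (self.bins["start"].to_numpy() + self.bins["end"].to_numpy()) / 2.0

    def allele_freq(self) -> pd.DataFrame:
        """Per-bin P1/P2/HET frequencies among called lines."""
        called = (self.G != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_p1 = (self.G == P1).sum(axis=0) / called
            f_p2 = (self.G == P2).sum(axis=0) / called
            f_het = (self.G == HET).sum(axis=0) / called
        return pd.DataFrame(
            {"f_P1": f_p1, "f_P2": f_p2, "f_HET": f_het, "n_called": called}
        )

    def subset_bins(self, mask: np.ndarray) -> "BinMap":
        return BinMap(
            self.bins.loc[mask].reset_index(drop=True),
            self.G[:, mask],
            list(self.lines),
            dict(self.chrom_lengths),
        )


@dataclass
class GeneticMap:
    """Per-bin cM positions and adjacent-interval estimates.

    ``table`` columns: chrom, start, end, mid_bp, cM (cumulative within
    chromosome), R_adj (observed RIL recombinant fraction to the next
    bin), r_adj (per-meiosis, Haldane-Waddington corrected),
    interval_cM (Kosambi), n_informative, low_confidence.
    """

    table: pd.DataFrame
    map_function: str = "kosambi"

    def chrom_total_cM(self) -> pd.Series:
        return self.table.groupby("chrom", sort=False)["interval_cM"].sum()

    @property
    def total_cM(self) -> float:
        return float(self.table["interval_cM"].sum())


# ---------------------------------------------------------------------------
# Bin construction
# ---------------------------------------------------------------------------


def construct_bins(
    mosaics: dict[str, dict[str, LineMosaic]],
    layout: GenomeLayout,
    merge_floor_bp: int = MERGE_FLOOR_BP,
) -> BinMap:
    """Group breakpoint-free intervals across the population into bins.

    Bin boundaries on each chromosome are the sorted union of every
    line's block boundaries; bins shorter than ``merge_floor_bp`` are
    merged into their right neighbour (left neighbour at the chromosome
    end).  Each matrix cell takes the genotype of the line's covering
    block; where a merged bin straddles several blocks the genotype of
    the largest-overlap block wins.
    """
    lines = list(mosaics.keys())
    if len(lines) < 2:
        raise ValueError("need at least 2 retained lines to build a bin map")
    bin_rows = []
    per_chrom_edges: dict[str, np.ndarray] = {}
    for chrom in layout.chromosomes:
        cuts = {0, chrom.length_bp}
        for line in lines:
            m = mosaics[line][chrom.name]
            if m.end.size and (m.end[-1] > chrom.length_bp):
                raise ValueError(
                    f"line {line}: block beyond chromosome {chrom.name} end"
                )
            cuts.update(int(e) for e in m.end[:-1])
        edges = np.array(sorted(cuts), dtype=np.int64)
        # merge short bins rightward (leftward for the final bin)
        widths = np.diff(edges)
        while widths.size > 1 and (widths < merge_floor_bp).any():
            i = int(np.argmax(widths < merge_floor_bp))
            # dropping the right edge of bin i merges it into its right
            # neighbour; for the last bin drop its left edge instead
            drop = i + 1 if i + 1 < widths.size else i
            edges = np.delete(edges, drop)
            widths = np.diff(edges)
        per_chrom_edges[chrom.name] = edges
        for s, e in zip(edges[:-1], edges[1:]):
            bin_rows.append({"chrom": chrom.name, "start": int(s) + 1, "end": int(e)})
    bins = pd.DataFrame(bin_rows)

    G = np.full((len(lines), len(bins)), MISSING, dtype=np.int8)
    offset = 0
    for chrom in layout.chromosomes:
        edges = per_chrom_edges[chrom.name]
        nb = edges.size - 1
        starts = edges[:-1].astype(float)  # 0-based bin starts
        ends = edges[1:].astype(float)
        for li, line in enumerate(lines):
            m = mosaics[line][chrom.name]
            overlap = np.zeros((nb, 4))  # columns: P1, HET, P2, MISSING
            col = {P1: 0, HET: 1, P2: 2, MISSING: 3}
            for bs, be, g in zip(m.start, m.end, m.genotype):
                lo = np.searchsorted(ends, bs - 1, side="right")
                hi = np.searchsorted(starts, be, side="left")
                if hi <= lo:
                    continue
                ov = np.minimum(ends[lo:hi], be) - np.maximum(starts[lo:hi], bs - 1)
                overlap[lo:hi, col[int(g)]] += ov
            best = np.argmax(overlap, axis=1)
            codes = np.array([P1, HET, P2, MISSING], dtype=np.int8)
            cell = codes[best]
            cell[overlap.sum(axis=1) == 0] = MISSING
            G[li, offset : offset + nb] = cell
        offset += nb
    return BinMap(
        bins, G, lines, {c.name: c.length_bp for c in layout.chromosomes}
    )


# ---------------------------------------------------------------------------
# Segregation distortion
# ---------------------------------------------------------------------------


def test_segregation_distortion(binmap: BinMap, alpha: float = 0.01) -> pd.DataFrame:
    """Chi-square goodness-of-fit of each bin against 1:1 segregation.

    HET and MISSING cells are ignored; the test runs on the parental
    homozygote counts with df = 1.  P-values are Bonferroni-adjusted
    over the number of testable bins (>= 2 informative lines) and a bin
    is flagged when adjusted p < ``alpha``.
    """
    n_p1 = (binmap.G == P1).sum(axis=0)
    n_p2 = (binmap.G == P2).sum(axis=0)
    total = n_p1 + n_p2
    testable = total >= 2
    m = int(testable.sum())
    chi2 = np.full(binmap.n_bins, np.nan)
    p = np.full(binmap.n_bins, np.nan)
    if m:
        obs = np.stack([n_p1[testable], n_p2[testable]], axis=0).astype(float)
        stat, pval = stats.chisquare(obs, axis=0)
        chi2[testable] = stat
        p[testable] = pval
    p_adj = np.minimum(p * m, 1.0)
    return pd.DataFrame(
        {
            "n_P1": n_p1,
            "n_P2": n_p2,
            "chi2": chi2,
            "p": p,
            "p_bonferroni": p_adj,
            "distorted": (p_adj < alpha) & testable,
        }
    )


test_segregation_distortion.__test__ = False  # not a pytest test


def filter_distorted_bins(
    binmap: BinMap, max_ratio: float = 2.0, max_het: float = 0.15
) -> tuple[BinMap, dict]:
    """Discard bins with a parental ratio > ``max_ratio`` or HET > ``max_het``.

    A zero minor-parent frequency counts as an infinite ratio and is
    discarded.  Thresholds are strict (a ratio of exactly 2.0 stays).
    Returns the filtered map and a report with the discarded fraction.
    """
    freq = binmap.allele_freq()
    hi = np.maximum(freq["f_P1"], freq["f_P2"]).to_numpy()
    lo = np.minimum(freq["f_P1"], freq["f_P2"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
    bad = (ratio > max_ratio) | (freq["f_HET"].to_numpy() > max_het)
    bad |= ~np.isfinite(ratio)
    report = {
        "n_bins": binmap.n_bins,
        "n_discarded": int(bad.sum()),
        "discarded_fraction": float(bad.mean()) if binmap.n_bins else 0.0,
    }
    return binmap.subset_bins(~bad), report


# ---------------------------------------------------------------------------
# Recombination fractions and the Kosambi map function
# ---------------------------------------------------------------------------


def ril_r_from_R(R: np.ndarray | float) -> np.ndarray | float:
    """Per-meiosis r from the observed RIL recombinant fraction R.

    Inverts the Haldane-Waddington fixed-point relation R = 2r/(1+2r)
    for a selfed RIL population: r = R / (2 (1 - R)), clamped to
    [0, 0.5).
    """
    R = np.asarray(R, dtype=float)
    r = R / (2.0 * (1.0 - R))
    out = np.clip(r, 0.0, np.nextafter(0.5, 0.0))
    return float(out) if out.ndim == 0 else out


def ril_R_from_r(r: np.ndarray | float) -> np.ndarray | float:
    """Observed RIL recombinant fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def kosambi_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM for r in [0, 0.5)."""
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * arr) / (1.0 - 2.0 * arr))
    return float(out) if out.ndim == 0 else out


def kosambi_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(d/50) / 2; round-trips with kosambi_cm."""
    d = np.asarray(d_cM, dtype=float)
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


def _discordance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Fraction of doubly informative homozygous lines with differing genotype."""
    info = (a != MISSING) & (b != MISSING) & (a != HET) & (b != HET)
    n = int(info.sum())
    if n == 0:
        return np.nan, 0
    return float((a[info] != b[info]).mean()), n


def adjacent_rf(binmap: BinMap, min_informative: int = 10) -> pd.DataFrame:
    """Observed recombinant fraction between each pair of adjacent bins.

    Returns one row per within-chromosome interval: R (observed),
    r (per-meiosis after RIL correction), informative count and a
    low-confidence flag below ``min_informative``.
    """
    chrom = binmap.bins["chrom"].to_numpy()
    rows = []
    for j in range(binmap.n_bins - 1):
        if chrom[j] != chrom[j + 1]:
            continue
        R, n = _discordance(binmap.G[:, j], binmap.G[:, j + 1])
        Rc = min(R, np.nextafter(0.5, 0.0)) if np.isfinite(R) else np.nan
        rows.append(
            {
                "chrom": chrom[j],
                "left_bin": j,
                "right_bin": j + 1,
                "R": R,
                "r": ril_r_from_R(Rc) if np.isfinite(R) else np.nan,
                "n_informative": n,
                "low_confidence": n < min_informative,
            }
        )
    return pd.DataFrame(rows)


def pairwise_rf(binmap: BinMap) -> np.ndarray:
    """All-pairs observed recombinant fraction matrix (NaN where uninformative).

    Intended for modest bin counts (diagnostics, small fixtures); the
    linkage map itself only needs adjacent intervals.
    """
    G = binmap.G
    n_bins = binmap.n_bins
    hom = (G == P1) | (G == P2)
    X = np.where(G == P2, 1.0, 0.0)
    M = hom.astype(float)
    Xm = X * M
    both = M.T @ M
    # discordant pairs = x(1-y) + (1-x)y among doubly informative lines
    agree = Xm.T @ Xm + (M - Xm).T @ (M - Xm)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (both - agree) / both
    R[both == 0] = np.nan
    return R


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_genotypes(
    binmap: BinMap, epsilon: float = 1e-4, min_R: float = 1e-4
) -> BinMap:
    """Fill heterozygous and missing cells by most-probable-path decoding.

    HET cells are first set missing (RIL mapping models only the two
    parental homozygotes), then each line x chromosome is decoded with
    a two-state Viterbi pass: transition probabilities between adjacent
    bins are the observed RIL discordance fractions R (floored at
    ``min_R``), emissions are correct with probability 1 - ``epsilon``.
    Chromosomes with no observed genotype for a line are left missing.
    """
    G = binmap.G.copy()
    G[G == HET] = MISSING
    rf = adjacent_rf(BinMap(binmap.bins, G, binmap.lines, binmap.chrom_lengths))
    chrom_ids = binmap.bins["chrom"].to_numpy()
    R_by_left = dict(zip(rf["left_bin"], rf["R"]))
    out = G.copy()
    warned = False
    for chrom in dict.fromkeys(chrom_ids):
        idx = np.flatnonzero(chrom_ids == chrom)
        B = idx.size
        sub = G[:, idx]  # (N, B)
        N = sub.shape[0]
        R = np.array(
            [R_by_left.get(int(idx[k]), np.nan) for k in range(B - 1)], dtype=float
        )
        R = np.where(np.isfinite(R), R, np.nanmean(R) if np.isfinite(np.nanmean(R)) else 0.01)
        R = np.clip(R, min_R, 0.499)
        log_stay = np.log1p(-R)
        log_switch = np.log(R)
        # emission log-likelihoods per state (P1, P2)
        emit = np.zeros((N, B, 2))
        emit[:, :, 0] = np.where(sub == P1, np.log1p(-epsilon), np.where(sub == P2, np.log(epsilon), 0.0))
        emit[:, :, 1] = np.where(sub == P2, np.log1p(-epsilon), np.where(sub == P1, np.log(epsilon), 0.0))
        score = emit[:, 0, :] + np.log(0.5)
        back = np.zeros((N, B, 2), dtype=np.int8)
        for k in range(1, B):
            # score from previous state s_prev to state s
            stay = score + log_stay[k - 1]
            switch = score[:, ::-1] + log_switch[k - 1]
            back[:, k, :] = (switch > stay).astype(np.int8)
            score = np.maximum(stay, switch) + emit[:, k, :]
        state = np.argmax(score, axis=1).astype(np.int8)
        path = np.empty((N, B), dtype=np.int8)
        path[:, B - 1] = state
        for k in range(B - 1, 0, -1):
            flip = back[np.arange(N), k, state].astype(bool)
            state = np.where(flip, 1 - state, state).astype(np.int8)
            path[:, k - 1] = state
        decoded = np.where(path == 0, P1, P2).astype(np.int8)
        all_missing = (sub == MISSING).all(axis=1)
        if all_missing.any() and not warned:
            warnings.warn(
                "some line/chromosome pairs have no observed bins; left missing",
                stacklevel=2,
            )
            warned = True
        decoded[all_missing, :] = MISSING
        out[:, idx] = decoded
    return BinMap(binmap.bins.copy(), out, list(binmap.lines), dict(binmap.chrom_lengths))


# ---------------------------------------------------------------------------
# Genetic map and summaries
# ---------------------------------------------------------------------------


def build_genetic_map(binmap: BinMap) -> tuple[GeneticMap, pd.DataFrame]:
    """Estimate the Kosambi genetic map and a per-chromosome summary.

    Map distances come from adjacent-bin recombinant fractions only
    (with the dense bin scaffold the chain structure makes multipoint
    re-estimation redundant).  The summary reports, per chromosome:
    bin count, mean/max adjacent physical interval between bin
    midpoints (Mb), total cM, mean/max adjacent cM interval (both the
    interval mean and total/(bins-1) convention coincide here), the
    cM/Mb ratio over the physical length, and mean crossovers per line.
    """
    rf = adjacent_rf(binmap)
    chrom_ids = binmap.bins["chrom"].to_numpy()
    mids = binmap.midpoints()
    interval_cM = np.zeros(binmap.n_bins)
    R_adj = np.full(binmap.n_bins, np.nan)
    r_adj = np.full(binmap.n_bins, np.nan)
    n_inf = np.zeros(binmap.n_bins, dtype=int)
    low = np.zeros(binmap.n_bins, dtype=bool)
    for row in rf.itertuples():
        j = int(row.left_bin)
        R_adj[j] = row.R
        r_adj[j] = row.r
        n_inf[j] = row.n_informative
        low[j] = row.low_confidence
        if np.isfinite(row.r):
            interval_cM[int(row.right_bin)] = kosambi_cm(row.r)
    cM = np.zeros(binmap.n_bins)
    for chrom in dict.fromkeys(chrom_ids):
        idx = np.flatnonzero(chrom_ids == chrom)
        cM[idx] = np.cumsum(interval_cM[idx])
    table = binmap.bins.copy()
    table["mid_bp"] = mids
    table["cM"] = cM
    table["R_adj"] = R_adj
    table["r_adj"] = r_adj
    table["interval_cM"] = interval_cM
    table["n_informative"] = n_inf
    table["low_confidence"] = low
    gmap = GeneticMap(table)

    xo = count_crossovers(binmap)
    rows = []
    for chrom in dict.fromkeys(chrom_ids):
        idx = np.flatnonzero(chrom_ids == chrom)
        nb = idx.size
        phys_int = np.diff(mids[idx]) / 1e6
        cm_int = interval_cM[idx][1:]
        total = float(cm_int.sum())
        length_mb = binmap.chrom_lengths[chrom] / 1e6
        per_line = xo["per_chrom_mean"].get(chrom, 0.0)
        rows.append(
            {
                "chrom": chrom,
                "bins": nb,
                "mean_interval_Mb": float(phys_int.mean()) if nb > 1 else np.nan,
                "max_interval_Mb": float(phys_int.max()) if nb > 1 else np.nan,
                "total_cM": total,
                "mean_interval_cM": total / (nb - 1) if nb > 1 else np.nan,
                "max_interval_cM": float(cm_int.max()) if nb > 1 else np.nan,
                "cM_per_Mb": total / length_mb,
                "mean_crossovers_per_line": per_line,
            }
        )
    return gmap, pd.DataFrame(rows)


def count_crossovers(binmap: BinMap) -> dict:
    """Population crossover bookkeeping from the bin genotype matrix.

    A crossover is a genotype transition between consecutive called
    bins within a line.  Returns the total, the mean per line per
    chromosome (one decimal is what summary tables print), and
    per-chromosome means.
    """
    chrom_ids = binmap.bins["chrom"].to_numpy()
    chroms = list(dict.fromkeys(chrom_ids))
    total = 0
    per_chrom_mean: dict[str, float] = {}
    for chrom in chroms:
        idx = np.flatnonzero(chrom_ids == chrom)
        sub = binmap.G[:, idx]
        count = 0
        for li in range(sub.shape[0]):
            g = sub[li][sub[li] != MISSING]
            if g.size > 1:
                count += int(np.sum(g[1:] != g[:-1]))
        per_chrom_mean[chrom] = count / binmap.n_lines
        total += count
    denom = binmap.n_lines * len(chroms)
    return {
        "total": total,
        "mean_per_line_per_chrom": total / denom if denom else 0.0,
        "per_chrom_mean": per_chrom_mean,
    }


def recombination_profile(
    gmap: GeneticMap,
    binmap: BinMap,
    layout: GenomeLayout,
    tracks: dict[str, pd.DataFrame] | None = None,
    window_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """cM/Mb landscape in fixed physical windows, with track correlations.

    Each adjacent-bin interval's cM is spread over the physical span
    between the two bin midpoints and apportioned to windows by overlap
    fraction.  SNP density from the layout is always included.  Any
    supplied per-window track (DataFrame with chrom, start, value on
    the same window tiling) is joined and Pearson-correlated against
    the cM/Mb profile.
    """
    rows = []
    table = gmap.table
    for chrom in layout.chromosomes:
        sub = table[table["chrom"] == chrom.name]
        mids = sub["mid_bp"].to_numpy()
        cm = sub["interval_cM"].to_numpy()[1:]
        n_win = int(np.ceil(chrom.length_bp / window_bp))
        alloc = np.zeros(n_win)
        for k in range(mids.size - 1):
            lo, hi = mids[k], mids[k + 1]
            if hi <= lo:
                continue
            w0 = int(lo // window_bp)
            w1 = int(min(hi, chrom.length_bp - 1) // window_bp)
            for wi in range(w0, w1 + 1):
                ws, we = wi * window_bp, min((wi + 1) * window_bp, chrom.length_bp)
                ov = max(0.0, min(hi, we) - max(lo, ws))
                alloc[wi] += cm[k] * ov / (hi - lo)
        snps = layout.snp_positions[chrom.name]
        for wi in range(n_win):
            ws = wi * window_bp
            we = min(ws + window_bp, chrom.length_bp)
            mb = (we - ws) / 1e6
            dens = int(
                np.searchsorted(snps, we, side="right")
                - np.searchsorted(snps, ws + 1, side="left")
            )
            rows.append(
                {
                    "chrom": chrom.name,
                    "start": ws + 1,
                    "end": we,
                    "cM_per_Mb": alloc[wi] / mb,
                    "snp_density": dens / mb,
                }
            )
    profile = pd.DataFrame(rows)

    corr_rows = []
    def _corr(name: str, values: np.ndarray) -> None:
        x = profile["cM_per_Mb"].to_numpy()
        ok = np.isfinite(x) & np.isfinite(values)
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(values[ok]) > 0:
            r, p = stats.pearsonr(x[ok], values[ok])
        else:
            r, p = np.nan, np.nan
        corr_rows.append({"track": name, "pearson_r": r, "p": p, "n": int(ok.sum())})

    _corr("snp_density", profile["snp_density"].to_numpy())
    if tracks:
        for name, tr in tracks.items():
            merged = profile.merge(
                tr, on=["chrom", "start"], how="left", validate="one_to_one"
            )
            if merged["value"].isna().all():
                raise ValueError(f"track {name!r} does not align with the window tiling")
            _corr(name, merged["value"].to_numpy(dtype=float))
    return profile, pd.DataFrame(corr_rows)
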