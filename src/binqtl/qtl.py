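"""Composite-interval-style QTL scanning on a dense bin map.

With bins every ~100 kb there is nothing between adjacent markers to
interpolate, so the scan is marker regression at each bin with
forward-stepwise background cofactors and a cM exclusion window around
the tested bin — the dense-map analogue of composite interval mapping.
At bin ``j`` the phenotype is regressed on the bin's -1/+1 genotype
code plus the retained cofactors; the score is

    LOD_j = (n/2) * log10(RSS_reduced / RSS_full)

with the reduced model containing the same cofactors only, which
reduces to LOD = -(n/2) log10(1 - rho^2) for the partial correlation
rho of the bin with the cofactor-residualized phenotype.  Genome-wide
significance comes from phenotype permutations (cofactors reselected
inside each permutation), and support intervals from the 1.5-LOD drop
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binmap import BinMap, GeneticMap
from .genome import HET, MISSING, P1, P2

__all__ = [
    "ScanConfig",
    "QTLResult",
    "encode_genotypes",
    "select_cofactors",
    "cim_scan",
    "permutation_threshold",
    "find_peaks_and_intervals",
    "qtl_effects",
    "interval_length",
    "scan_trait",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan, permutation and interval parameters."""

    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    n_cofactors_max: int = 5
    cofactor_window_cM: float = 30.0
    entry_pvalue: float = 1e-3  # partial-F entry threshold for stepwise cofactors
    min_informative: int = 20  # bins with fewer called lines get no LOD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lod_drop <= 0:
            raise ValueError("lod_drop must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class QTLResult:
    """Scan output for one trait."""

    trait: str
    lod: np.ndarray
    threshold: float
    peaks: pd.DataFrame
    cofactors: list[int]
    n_permutations: int
    seed: int


def encode_genotypes(binmap: BinMap) -> tuple[np.ndarray, np.ndarray]:
    """Code the bin matrix for regression: P1 -> -1, HET -> 0, P2 -> +1.

    Missing cells are replaced by the bin mean (they carry no signal).
    Returns the (n_lines, n_bins) float matrix and the per-bin count of
    informative (called) lines.
    """
    G = binmap.G
    X = np.where(G == P1, -1.0, np.where(G == P2, 1.0, np.where(G == HET, 0.0, np.nan)))
    informative = np.sum(G != MISSING, axis=0)
    col_mean = np.nanmean(np.where(informative > 0, X, 0.0), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    return X, informative


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project columns of M onto the orthogonal complement of span(C)."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def _partial_lod(
    Xr: np.ndarray, yr: np.ndarray, n: int, eps: float = 1e-12
) -> np.ndarray:
    """LOD from cofactor-residualized genotypes/phenotype."""
    sy = float(yr @ yr)
    if sy <= eps:
        return np.zeros(Xr.shape[1])
    sx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        rho2 = np.where(sx > eps, sxy**2 / (sx * sy), 0.0)
    rho2 = np.clip(rho2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - rho2)


def select_cofactors(
    X: np.ndarray, y: np.ndarray, cfg: ScanConfig = ScanConfig()
) -> list[int]:
    """Forward stepwise selection of background marker cofactors.

    At each step the bin most reducing the residual sum of squares is
    added while its partial F exceeds the entry threshold
    (p < ``entry_pvalue``), stopping at ``n_cofactors_max``.  A constant
    phenotype selects nothing.
    """
    n = y.size
    y = y - y.mean()
    if float(y @ y) <= 1e-12 * n:
        return []
    chosen: list[int] = []
    C = np.ones((n, 1))
    for _ in range(cfg.n_cofactors_max):
        Xr = _residualize(X, C)
        yr = _residualize(y[:, None], C)[:, 0]
        sy = float(yr @ yr)
        if sy <= 1e-12:
            break
        sx = np.einsum("ij,ij->j", Xr, Xr)
        sxy = Xr.T @ yr
        with np.errstate(invalid="ignore", divide="ignore"):
            rho2 = np.where(sx > 1e-12, sxy**2 / (sx * sy), 0.0)
        rho2[chosen] = 0.0
        best = int(np.argmax(rho2))
        dof = n - C.shape[1] - 1
        if dof <= 0:
            break
        F = rho2[best] / (1.0 - rho2[best]) * dof
        if stats.f.sf(F, 1, dof) >= cfg.entry_pvalue:
            break
        chosen.append(best)
        C = np.column_stack([C, X[:, best]])
    return chosen


def cim_scan(
    X: np.ndarray,
    y: np.ndarray,
    cofactors: list[int],
    cm_pos: np.ndarray,
    chrom_idx: np.ndarray,
    cfg: ScanConfig = ScanConfig(),
    informative: np.ndarray | None = None,
) -> np.ndarray:
    """Genome scan: per-bin LOD with window-excluded cofactors.

    Cofactors lying within ``cofactor_window_cM`` of the tested bin on
    the same chromosome are dropped from both the full and the reduced
    model at that bin.  Bins with fewer than ``min_informative`` called
    lines get NaN.
    """
    n, n_bins = X.shape
    y = y - y.mean()
    lod = np.zeros(n_bins)
    # retained-cofactor mask per bin -> group bins sharing a mask
    masks = np.ones((n_bins, len(cofactors)), dtype=bool)
    for ci, c in enumerate(cofactors):
        near = (chrom_idx == chrom_idx[c]) & (
            np.abs(cm_pos - cm_pos[c]) < cfg.cofactor_window_cM
        )
        masks[near, ci] = False
    if cofactors:
        keys = np.packbits(masks, axis=1, bitorder="little")
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
    else:
        inverse = np.zeros(n_bins, dtype=int)
    for key in np.unique(inverse):
        bins_here = np.flatnonzero(inverse == key)
        kept = [c for ci, c in enumerate(cofactors) if masks[bins_here[0], ci]]
        C = np.column_stack([np.ones(n)] + [X[:, c] for c in kept]) if kept else np.ones((n, 1))
        Xr = _residualize(X[:, bins_here], C)
        yr = _residualize(y[:, None], C)[:, 0]
        lod[bins_here] = _partial_lod(Xr, yr, n)
    if informative is not None:
        lod[informative < cfg.min_informative] = np.nan
    return lod


def permutation_threshold(
    X: np.ndarray,
    y: np.ndarray,
    cm_pos: np.ndarray,
    chrom_idx: np.ndarray,
    cfg: ScanConfig = ScanConfig(),
    rng: np.random.Generator | None = None,
    informative: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from phenotype permutations.

    Each permutation shuffles phenotype values across lines, reselects
    cofactors and re-scans; the threshold is the empirical
    ``1 - alpha`` quantile (conservative ``higher`` interpolation) of
    the per-permutation maximum LOD.  Returns the threshold and the
    max-LOD null distribution.
    """
    import warnings as _warnings

    if cfg.n_permutations < 100:
        _warnings.warn(
            "fewer than 100 permutations gives an unstable threshold", stacklevel=2
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    y_canon = np.sort(y)  # threshold depends on the value multiset only
    max_lod = np.empty(cfg.n_permutations)
    for p in range(cfg.n_permutations):
        yp = rng.permutation(y_canon)
        cof = select_cofactors(X, yp, cfg)
        lod = cim_scan(X, yp, cof, cm_pos, chrom_idx, cfg, informative)
        max_lod[p] = np.nanmax(lod) if np.isfinite(lod).any() else 0.0
    threshold = float(np.quantile(max_lod, 1.0 - cfg.alpha, method="higher"))
    return threshold, max_lod


def find_peaks_and_intervals(
    lod: np.ndarray,
    threshold: float,
    binmap: BinMap,
    cm_pos: np.ndarray,
    cfg: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Peaks above threshold with 1.5-LOD support intervals.

    Local maxima at or above the threshold are candidate QTLs; two
    maxima on a chromosome stay distinct only if the profile between
    them drops at least ``lod_drop`` below the lesser peak, otherwise
    they merge into the stronger one.  Each support interval is the
    contiguous run of bins with LOD >= peak - ``lod_drop``, extended
    one bin outward on each side where available.
    """
    chrom_ids = binmap.bins["chrom"].to_numpy()
    starts = binmap.bins["start"].to_numpy()
    ends = binmap.bins["end"].to_numpy()
    work = np.where(np.isfinite(lod), lod, -np.inf)
    rows = []
    for chrom in dict.fromkeys(chrom_ids):
        idx = np.flatnonzero(chrom_ids == chrom)
        l = work[idx]
        cand = []
        for k in range(l.size):
            left = l[k - 1] if k > 0 else -np.inf
            right = l[k + 1] if k + 1 < l.size else -np.inf
            if l[k] >= threshold and l[k] >= left and l[k] > right:
                cand.append(k)
        cand.sort(key=lambda k: -l[k])
        kept: list[int] = []
        for k in cand:
            merged = False
            for kk in kept:
                lo, hi = min(k, kk), max(k, kk)
                valley = l[lo : hi + 1].min()
                if valley > min(l[k], l[kk]) - cfg.lod_drop:
                    merged = True
                    break
            if not merged:
                kept.append(k)
        kept.sort()
        # partition the chromosome between adjacent kept peaks at the
        # deepest valley, then take the span of bins within the drop of
        # each peak inside its own basin (small dips do not truncate)
        edges = [0]
        for left, right in zip(kept[:-1], kept[1:]):
            edges.append(left + int(np.argmin(l[left : right + 1])))
        edges.append(l.size - 1)
        for pi, k in enumerate(kept):
            lo_edge, hi_edge = edges[pi], edges[pi + 1]
            cut = l[k] - cfg.lod_drop
            qualifying = np.flatnonzero(l[lo_edge : hi_edge + 1] >= cut) + lo_edge
            a = int(qualifying.min())
            b = int(qualifying.max())
            a = max(0, a - 1)  # one bin outward each side
            b = min(l.size - 1, b + 1)
            gi = idx[k]
            rows.append(
                {
                    "chrom": chrom,
                    "peak_bin": int(gi),
                    "peak_bp": int((starts[gi] + ends[gi]) // 2),
                    "peak_cM": float(cm_pos[gi]),
                    "lod": float(l[k]),
                    "interval_start_bp": int(starts[idx[a]]),
                    "interval_end_bp": int(ends[idx[b]]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "peak_bin",
            "peak_bp",
            "peak_cM",
            "lod",
            "interval_start_bp",
            "interval_end_bp",
        ],
    )


def qtl_effects(genotypes: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Additive effect and PVE of the single-locus linear model at a peak.

    Fits y = mu + a * x on the parental homozygotes (x = -1 for P1, +1
    for P2), so ``a`` is positive when the P2 allele increases the
    trait and equals half the class-mean difference.  PVE is 100 * R^2
    of this fit.  Raises when a homozygote class is absent.
    """
    hom = (genotypes == P1) | (genotypes == P2)
    g = genotypes[hom]
    yy = y[hom]
    if not ((g == P1).any() and (g == P2).any()):
        raise ValueError("both homozygote classes are required to estimate an effect")
    x = np.where(g == P2, 1.0, -1.0)
    a = (yy[x > 0].mean() - yy[x < 0].mean()) / 2.0
    vy = np.var(yy)
    if vy == 0:
        return float(a), 0.0
    r = np.corrcoef(x, yy)[0, 1]
    return float(a), float(100.0 * r**2)


def interval_length(start_mb: float, end_mb: float, ndigits: int = 3) -> float:
    """Physical interval length in Mb at the table's printed precision."""
    if end_mb < start_mb:
        raise ValueError("interval end before start")
    return round(end_mb - start_mb, ndigits)


def scan_trait(
    binmap: BinMap,
    gmap: GeneticMap,
    phenotype: pd.Series | np.ndarray,
    trait: str = "trait",
    cfg: ScanConfig = ScanConfig(),
) -> QTLResult:
    """Full single-trait scan: cofactors, LOD profile, threshold, peaks.

    ``phenotype`` is one value per line in ``binmap.lines`` order (a
    Series indexed by line is realigned).  Permutations derive from
    ``cfg.seed`` so the result is reproducible.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(binmap.lines).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    if y.size != binmap.n_lines:
        raise ValueError("phenotype length does not match the bin map lines")
    ok = np.isfinite(y)
    if not ok.all():
        bm = BinMap(
            binmap.bins, binmap.G[ok], [l for l, m in zip(binmap.lines, ok) if m],
            binmap.chrom_lengths,
        )
        return scan_trait(bm, gmap, y[ok], trait, cfg)

    X, informative = encode_genotypes(binmap)
    cm_pos = gmap.table["cM"].to_numpy()
    chrom_idx = binmap.chrom_index()
    rng = np.random.default_rng(cfg.seed)
    cof = select_cofactors(X, y, cfg)
    lod = cim_scan(X, y, cof, cm_pos, chrom_idx, cfg, informative)
    threshold, _ = permutation_threshold(
        X, y, cm_pos, chrom_idx, cfg, rng, informative
    )
    peaks = find_peaks_and_intervals(lod, threshold, binmap, cm_pos, cfg)
    effects, pves = [], []
    for row in peaks.itertuples():
        try:
            a, pve = qtl_effects(binmap.G[:, int(row.peak_bin)], y)
        except ValueError:
            a, pve = np.nan, np.nan
        effects.append(a)
        pves.append(pve)
    peaks = peaks.assign(trait=trait, additive_effect=effects, pve_pct=pves)
    return QTLResult(trait, lod, threshold, peaks, cof, cfg.n_permutations, cfg.seed)
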