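"""Sliding-window genotype calling for sparse low-coverage GBS calls.

Each line's chromosome is scanned with a 15-SNP window sliding one SNP
at a time.  A window is called homozygous for a parent when strictly
more than 11 of its 15 sites carry that parent's allele, heterozygous
otherwise.  Crossover breakpoints show up as short runs of heterozygous
windows: maximal HET runs shorter than seven windows flanked by the two
different homozygotes are split at their midpoint between the flanking
genotypes.  Same-genotype windows are merged into physical blocks, and
blocks too small to trust (few SNPs or short span) are masked to
missing, avoiding spurious double crossovers.  Lines with excessive
residual heterozygosity or implausibly many breakpoints are excluded.

All thresholds are strict inequalities; ties keep the item.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ALLELE_P1, ALLELE_P2, GENO_LABELS, HET, MISSING, P1, P2, GenomeLayout
from .simulate import GenotypeObservations

__all__ = [
    "CallerConfig",
    "LineMosaic",
    "call_windows",
    "resolve_breakpoints",
    "merge_to_blocks",
    "filter_blocks",
    "filter_lines",
    "call_line",
    "call_population",
]


@dataclass(frozen=True)
class CallerConfig:
    """Window, block and line thresholds of the genotype caller.

    Defaults implement the canonical rule set: 15-SNP windows called
    homozygous at > 11/15 sites; HET runs of < 7 windows treated as
    breakpoints; blocks masked below 5 SNPs / 300 kb; HET blocks masked
    below 15 SNPs / 1 Mb; lines dropped above 15% heterozygosity or 360
    breakpoints.  ``transient_switches``/``transient_span`` parameterize
    the consolidation of rapidly alternating short blocks into one
    heterozygous block (>= 3 genotype switches within 10 consecutive
    called blocks by default).
    """

    window_size: int = 15
    hom_threshold: int = 11  # call homozygous when same-parent count > this
    het_run_breakpoint_max: int = 7  # HET runs shorter than this are breakpoints
    block_min_snps: int = 5  # blocks with fewer SNPs than this -> missing
    block_min_bp: int = 300_000  # blocks shorter than this -> missing
    het_block_min_snps: int = 15
    het_block_min_bp: int = 1_000_000
    line_max_het_fraction: float = 0.15
    line_max_breakpoints: int = 360
    transient_switches: int = 3
    transient_span: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.hom_threshold < self.window_size:
            raise ValueError("need 0 < hom_threshold < window_size")
        for name in (
            "window_size",
            "het_run_breakpoint_max",
            "block_min_snps",
            "block_min_bp",
            "het_block_min_snps",
            "het_block_min_bp",
            "line_max_breakpoints",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LineMosaic:
    """One line's chromosome as an ordered list of genotype blocks.

    Blocks are 1-based inclusive ``[start, end]`` bp, sorted and
    non-overlapping; genotype codes are P1/P2/HET/MISSING.
    """

    chrom: str
    chrom_length: int
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    genotype: np.ndarray  # int8
    snp_count: np.ndarray  # int64

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def called_length(self) -> int:
        m = self.genotype != MISSING
        return int((self.end[m] - self.start[m] + 1).sum())

    @property
    def het_fraction(self) -> float:
        """HET share of the called (non-missing) physical length."""
        called = self.called_length
        if called == 0:
            return 0.0
        m = self.genotype == HET
        return float((self.end[m] - self.start[m] + 1).sum() / called)

    @property
    def n_breakpoints(self) -> int:
        g = self.genotype[self.genotype != MISSING]
        if g.size <= 1:
            return 0
        return int(np.sum(g[1:] != g[:-1]))

    @property
    def breakpoint_positions(self) -> np.ndarray:
        """Midpoints between consecutive called blocks of differing genotype."""
        idx = np.flatnonzero(self.genotype != MISSING)
        pos = []
        for a, b in zip(idx[:-1], idx[1:]):
            if self.genotype[a] != self.genotype[b]:
                pos.append((self.end[a] + self.start[b]) // 2)
        return np.asarray(pos, dtype=np.int64)

    def to_frame(self, line: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "genotype": [GENO_LABELS[int(g)] for g in self.genotype],
                "snp_count": self.snp_count,
            }
        )
        if line is not None:
            df.insert(0, "line", line)
        return df


# ---------------------------------------------------------------------------
# Window calling
# ---------------------------------------------------------------------------


def call_windows(
    positions: np.ndarray, alleles: np.ndarray, cfg: CallerConfig = CallerConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Call sliding windows over one line's observed SNPs on one chromosome.

    Returns ``(genotype, p1_count, p2_count)`` arrays with one entry per
    window; window ``i`` covers observed SNPs ``[i, i + window_size)``.
    Fewer observations than one window yields empty arrays (the whole
    chromosome is uncallable for that line).
    """
    positions = np.asarray(positions)
    alleles = np.asarray(alleles)
    bad = ~np.isin(alleles, (ALLELE_P1, ALLELE_P2))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown allele code {alleles[i]!r} at position {positions[i]}"
        )
    n = alleles.size
    w = cfg.window_size
    if n < w:
        empty = np.empty(0, dtype=np.int64)
        return empty.astype(np.int8), empty, empty
    is_p2 = np.concatenate(([0], np.cumsum(alleles == ALLELE_P2)))
    p2 = (is_p2[w:] - is_p2[:-w]).astype(np.int64)
    p1 = w - p2
    geno = np.full(p1.size, HET, dtype=np.int8)
    geno[p1 > cfg.hom_threshold] = P1
    geno[p2 > cfg.hom_threshold] = P2
    return geno, p1, p2


def resolve_breakpoints(
    window_geno: np.ndarray, cfg: CallerConfig = CallerConfig()
) -> np.ndarray:
    """Replace short HET window runs by their flanking homozygous genotypes.

    A maximal HET run shorter than ``het_run_breakpoint_max`` windows is
    a crossover breakpoint when its two flanks are different
    homozygotes: the run is split at its midpoint, the left half taking
    the left flank's genotype (odd runs give the extra window to the
    left).  A short HET run flanked by the same genotype on both sides
    adopts it; runs at chromosome ends adopt their single flank.  Longer
    HET runs are genuine residual heterozygosity and are retained.
    """
    g = np.asarray(window_geno, dtype=np.int8).copy()
    n = g.size
    i = 0
    while i < n:
        if g[i] != HET:
            i += 1
            continue
        j = i
        while j < n and g[j] == HET:
            j += 1
        run = j - i
        left = g[i - 1] if i > 0 else None
        right = g[j] if j < n else None
        if run < cfg.het_run_breakpoint_max:
            if left is None and right is None:
                pass  # whole chromosome HET, keep
            elif left is None:
                g[i:j] = right
            elif right is None:
                g[i:j] = left
            elif left == right:
                g[i:j] = left
            else:
                half = (run + 1) // 2  # extra window to the left side
                g[i : i + half] = left
                g[i + half : j] = right
        i = j
    return g


def merge_to_blocks(
    window_geno: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    chrom_length: int,
    cfg: CallerConfig = CallerConfig(),
) -> LineMosaic:
    """Merge same-genotype windows into physical blocks.

    Window calls are mapped back to per-SNP genotypes by the window
    centre (edge SNPs take the first/last window's call), maximal
    same-genotype SNP runs become blocks, and the boundary between two
    adjacent blocks is placed at the midpoint between their flanking
    observed SNPs.  Terminal blocks extend to the chromosome ends.
    """
    positions = np.asarray(positions, dtype=np.int64)
    g = np.asarray(window_geno, dtype=np.int8)
    if g.size == 0:
        return LineMosaic(
            chrom,
            chrom_length,
            np.array([1], dtype=np.int64),
            np.array([chrom_length], dtype=np.int64),
            np.array([MISSING], dtype=np.int8),
            np.array([positions.size], dtype=np.int64),
        )
    half = (cfg.window_size - 1) // 2
    n_snps = g.size + cfg.window_size - 1
    snp_geno = g[np.clip(np.arange(n_snps) - half, 0, g.size - 1)]

    change = np.flatnonzero(snp_geno[1:] != snp_geno[:-1])
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [n_snps - 1]))  # inclusive SNP indices

    starts = np.empty(run_starts.size, dtype=np.int64)
    ends = np.empty(run_starts.size, dtype=np.int64)
    starts[0] = 1
    ends[-1] = chrom_length
    for k in range(run_starts.size - 1):
        boundary = (positions[run_ends[k]] + positions[run_starts[k + 1]]) // 2
        ends[k] = boundary
        starts[k + 1] = boundary + 1
    return LineMosaic(
        chrom,
        chrom_length,
        starts,
        ends,
        snp_geno[run_starts].astype(np.int8),
        (run_ends - run_starts + 1).astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Block-level filtering
# ---------------------------------------------------------------------------


def _merge_adjacent(mosaic: LineMosaic) -> LineMosaic:
    """Merge same-genotype neighbours, absorbing MISSING gaps between them.

    Two called blocks of the same genotype separated only by MISSING are
    joined across the gap; directly adjacent same-genotype blocks merge
    trivially.  MISSING runs next to differing genotypes stay missing.
    """
    n = len(mosaic)
    if n <= 1:
        return mosaic
    starts, ends, genos, counts = [], [], [], []
    i = 0
    while i < n:
        g = mosaic.genotype[i]
        j = i
        snps = int(mosaic.snp_count[i])
        if g != MISSING:
            # extend across MISSING gaps to any same-genotype continuation
            k = i + 1
            while k < n:
                if mosaic.genotype[k] == g:
                    snps += int(mosaic.snp_count[j + 1 : k + 1].sum())
                    j = k
                    k += 1
                elif mosaic.genotype[k] == MISSING:
                    k += 1
                else:
                    break
        else:
            while j + 1 < n and mosaic.genotype[j + 1] == MISSING:
                j += 1
                snps += int(mosaic.snp_count[j])
        starts.append(int(mosaic.start[i]))
        ends.append(int(mosaic.end[j]))
        genos.append(int(g))
        counts.append(snps)
        i = j + 1
    return LineMosaic(
        mosaic.chrom,
        mosaic.chrom_length,
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(genos, dtype=np.int8),
        np.asarray(counts, dtype=np.int64),
    )


def _consolidate_transients(mosaic: LineMosaic, cfg: CallerConfig) -> LineMosaic:
    """Collapse runs of small, rapidly alternating blocks into one HET block.

    Only *small* called blocks (below the HET-block minima, i.e. short
    span or few SNPs) can be frequently transient: within each maximal
    run of consecutive small called blocks, at least
    ``transient_switches`` genotype switches inside any
    ``transient_span`` consecutive blocks marks the run unreliable, and
    the marked stretch is replaced by a single heterozygous block.
    Large blocks — ordinary crossover products — are never absorbed.
    """
    length = mosaic.end - mosaic.start + 1
    small = (
        (mosaic.genotype != MISSING)
        & ((length < cfg.het_block_min_bp) | (mosaic.snp_count < cfg.het_block_min_snps))
    )
    called = np.flatnonzero(small)
    if called.size == 0:
        return mosaic
    g = mosaic.genotype[called]
    marked = np.zeros(called.size, dtype=bool)
    span = cfg.transient_span
    # split into runs of blocks that are consecutive in the mosaic
    breaks = np.flatnonzero(np.diff(called) != 1) + 1
    for run in np.split(np.arange(called.size), breaks):
        if run.size < 2:
            continue
        switch = (g[run][1:] != g[run][:-1]).astype(int)
        csum = np.concatenate(([0], np.cumsum(switch)))
        width = min(span, run.size)
        for s in range(run.size - width + 1):
            if csum[min(s + width - 1, switch.size)] - csum[s] >= cfg.transient_switches:
                marked[run[s : s + width]] = True
    if not marked.any():
        return mosaic
    # map back to block indices and consolidate maximal marked runs
    to_het = np.zeros(len(mosaic), dtype=bool)
    to_het[called[marked]] = True
    starts, ends, genos, counts = [], [], [], []
    i = 0
    n = len(mosaic)
    while i < n:
        if not to_het[i]:
            starts.append(int(mosaic.start[i]))
            ends.append(int(mosaic.end[i]))
            genos.append(int(mosaic.genotype[i]))
            counts.append(int(mosaic.snp_count[i]))
            i += 1
            continue
        j = i
        while j + 1 < n and to_het[j + 1]:
            j += 1
        starts.append(int(mosaic.start[i]))
        ends.append(int(mosaic.end[j]))
        genos.append(HET)
        counts.append(int(mosaic.snp_count[i : j + 1].sum()))
        i = j + 1
    return LineMosaic(
        mosaic.chrom,
        mosaic.chrom_length,
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(genos, dtype=np.int8),
        np.asarray(counts, dtype=np.int64),
    )


def filter_blocks(mosaic: LineMosaic, cfg: CallerConfig = CallerConfig()) -> LineMosaic:
    """Apply the block-level reliability filters to one chromosome mosaic.

    Order: (a) blocks with fewer than ``block_min_snps`` observed SNPs
    or spanning less than ``block_min_bp`` are set missing (guarding
    against false double crossovers); (b) frequently transient stretches
    are consolidated into heterozygous blocks; (c) heterozygous blocks
    below ``het_block_min_snps`` SNPs or ``het_block_min_bp`` bp are set
    missing; (d) same-genotype blocks separated only by missing runs are
    merged.  Thresholds are strict: a block exactly at a minimum stays.
    """
    geno = mosaic.genotype.copy()
    length = mosaic.end - mosaic.start + 1
    small = (mosaic.snp_count < cfg.block_min_snps) | (length < cfg.block_min_bp)
    geno[small & (geno != MISSING)] = MISSING
    m = LineMosaic(
        mosaic.chrom, mosaic.chrom_length, mosaic.start.copy(), mosaic.end.copy(),
        geno, mosaic.snp_count.copy(),
    )
    m = _merge_adjacent(m)
    m = _consolidate_transients(m, cfg)
    length = m.end - m.start + 1
    bad_het = (
        (m.genotype == HET)
        & ((m.snp_count < cfg.het_block_min_snps) | (length < cfg.het_block_min_bp))
    )
    m.genotype[bad_het] = MISSING
    return _merge_adjacent(m)


def filter_lines(
    mosaics: dict[str, dict[str, LineMosaic]], cfg: CallerConfig = CallerConfig()
) -> tuple[dict[str, dict[str, LineMosaic]], pd.DataFrame]:
    """Exclude lines with excess heterozygosity or breakpoints.

    A line is dropped when its genome-wide HET fraction (of called
    physical length) exceeds ``line_max_het_fraction`` or its total
    breakpoint count exceeds ``line_max_breakpoints``.  Returns the
    retained mosaics and an exclusion report (one row per line with its
    metrics and, for excluded lines, the reasons).
    """
    rows = []
    retained: dict[str, dict[str, LineMosaic]] = {}
    for line, per_chrom in mosaics.items():
        called = sum(m.called_length for m in per_chrom.values())
        het = sum(m.het_fraction * m.called_length for m in per_chrom.values())
        het_frac = het / called if called else 0.0
        n_bp = sum(m.n_breakpoints for m in per_chrom.values())
        reasons = []
        if het_frac > cfg.line_max_het_fraction:
            reasons.append("het_fraction")
        if n_bp > cfg.line_max_breakpoints:
            reasons.append("breakpoints")
        rows.append(
            {
                "line": line,
                "het_fraction": het_frac,
                "n_breakpoints": n_bp,
                "excluded": bool(reasons),
                "reason": "+".join(reasons),
            }
        )
        if not reasons:
            retained[line] = per_chrom
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------


def call_line(
    obs: GenotypeObservations,
    line: str,
    layout: GenomeLayout,
    cfg: CallerConfig = CallerConfig(),
) -> dict[str, LineMosaic]:
    """Full window -> breakpoint -> block -> filter chain for one line."""
    out: dict[str, LineMosaic] = {}
    for chrom in layout.chromosomes:
        pos, alleles = obs.get(line, chrom.name)
        geno, _, _ = call_windows(pos, alleles, cfg)
        geno = resolve_breakpoints(geno, cfg)
        mosaic = merge_to_blocks(geno, pos, chrom.name, chrom.length_bp, cfg)
        out[chrom.name] = filter_blocks(mosaic, cfg)
    return out


def call_population(
    obs: GenotypeObservations,
    layout: GenomeLayout,
    cfg: CallerConfig = CallerConfig(),
) -> tuple[dict[str, dict[str, LineMosaic]], pd.DataFrame]:
    """Call every line and apply the line-level exclusion filter."""
    mosaics = {line: call_line(obs, line, layout, cfg) for line in obs.lines}
    return filter_lines(mosaics, cfg)
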