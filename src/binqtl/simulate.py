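"""Synthetic RIL populations with GBS-like sparse genotype observations.

The generator reproduces the statistical structure of a large biparental
recombinant-inbred population genotyped at very low coverage:

* an F1 between two fully homozygous parents is selfed for a fixed
  number of generations under single-seed descent (default 6, i.e. F7
  lines), with per-meiosis crossover counts Poisson-distributed at one
  crossover per Morgan of genetic length and positions drawn from an
  optional per-Mb intensity track (uniform by default, no interference);
* each line's final pair of haplotypes defines a true genotype mosaic
  (P1 / P2 / HET segments tiling every chromosome);
* GBS observation is modelled as independent Bernoulli site sampling at
  a configurable rate (default 0.08, matching ~0.08x depth where a site
  is effectively read at most once), a true-HET site emitting either
  parental allele with probability 1/2, and the emitted allele flipped
  with a parent-specific miscall rate (defaults 0.6% for P1, 0.9% for
  P2 calls).

Read-level sequencing, restriction-fragment structure and crossover
interference are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ALLELE_P1, ALLELE_P2, HET, P1, P2, GenomeLayout

__all__ = [
    "SimulationParams",
    "PhenotypeModel",
    "TrueMosaic",
    "PopulationTruth",
    "GenotypeObservations",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_backcross_progeny",
]


@dataclass(frozen=True)
class SimulationParams:
    """Population and observation-process parameters.

    ``site_sampling_rate`` is the probability a given parental SNP is
    observed in a given line; ``error_rate_p1`` / ``error_rate_p2`` are
    the probabilities an emitted P1 / P2 allele is miscalled as the
    other parent.
    """

    n_lines: int = 200
    n_selfing_generations: int = 6
    site_sampling_rate: float = 0.08
    error_rate_p1: float = 0.006
    error_rate_p2: float = 0.009
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.n_selfing_generations < 1:
            raise ValueError("n_selfing_generations must be >= 1")
        for name in ("site_sampling_rate", "error_rate_p1", "error_rate_p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.site_sampling_rate == 0.0:
            raise ValueError("site_sampling_rate of zero produces no observations")


@dataclass
class PhenotypeModel:
    """Additive multi-environment phenotype model.

    y_ij = mu + env_j + sum_k a_k * x_ik + e_ij with x in {-1, 0, +1}
    coding {P1, HET, P2} at each planted locus.
    """

    qtl_loci: list[tuple[str, int, float]]  # (chromosome, position_bp, additive effect)
    env_effects: list[float]
    residual_sd: float
    mu: float = 0.0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not self.env_effects:
            raise ValueError("need at least one environment")

    @property
    def n_environments(self) -> int:
        return len(self.env_effects)


# ---------------------------------------------------------------------------
# Haplotype / mosaic machinery
# ---------------------------------------------------------------------------
# A haplotype is (bounds, alleles): bounds is a float array of m+1 edges with
# bounds[0] == 0 and bounds[-1] == L; alleles[i] in {P1, P2} holds on the
# half-open physical interval (bounds[i], bounds[i+1]].

Haplotype = tuple[np.ndarray, np.ndarray]


def _simplify(bounds: np.ndarray, alleles: np.ndarray) -> Haplotype:
    """Merge adjacent intervals carrying the same allele."""
    if alleles.size <= 1:
        return bounds, alleles
    keep = np.concatenate(([True], alleles[1:] != alleles[:-1]))
    return np.concatenate((bounds[:-1][keep], bounds[-1:])), alleles[keep]


def _extract(h: Haplotype, lo: float, hi: float) -> Haplotype:
    """Sub-haplotype on (lo, hi]."""
    bounds, alleles = h
    i0 = int(np.searchsorted(bounds, lo, side="right")) - 1
    i1 = int(np.searchsorted(bounds, hi, side="left"))
    sub_b = np.concatenate(([lo], bounds[i0 + 1 : i1], [hi]))
    sub_a = alleles[i0:i1]
    return sub_b, sub_a


def _recombine(h1: Haplotype, h2: Haplotype, xo: np.ndarray, start: int) -> Haplotype:
    """Gamete from two haplotypes given sorted crossover positions.

    ``start`` selects which haplotype supplies the first interval; the
    source alternates at every crossover.
    """
    length = h1[0][-1]
    if xo.size == 0:
        src = h1 if start == 0 else h2
        return src[0].copy(), src[1].copy()
    cuts = np.concatenate(([0.0], xo, [length]))
    parts_b: list[np.ndarray] = []
    parts_a: list[np.ndarray] = []
    for i in range(cuts.size - 1):
        src = h1 if (start + i) % 2 == 0 else h2
        b, a = _extract(src, cuts[i], cuts[i + 1])
        if parts_b:
            b = b[1:]
        parts_b.append(b)
        parts_a.append(a)
    bounds = np.concatenate(parts_b)
    alleles = np.concatenate(parts_a)
    return _simplify(bounds, alleles)


def _mosaic_from_haplotypes(h1: Haplotype, h2: Haplotype) -> tuple[np.ndarray, np.ndarray]:
    """Diploid genotype mosaic (bounds, genotypes) from a haplotype pair."""
    bounds = np.union1d(h1[0], h2[0])
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    a1 = h1[1][np.searchsorted(h1[0], mids, side="right") - 1]
    a2 = h2[1][np.searchsorted(h2[0], mids, side="right") - 1]
    geno = np.where(a1 == a2, a1, HET).astype(np.int8)
    return _simplify(bounds, geno)


@dataclass
class TrueMosaic:
    """Ground-truth genotype mosaic of one line on one chromosome."""

    chrom: str
    bounds: np.ndarray  # float edges, bounds[0]=0, bounds[-1]=length
    genotypes: np.ndarray  # int8 in {P1, HET, P2}, one per interval
    crossover_positions: np.ndarray  # all meiotic crossover bp drawn over the pedigree

    def genotype_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bounds, positions, side="left") - 1
        idx = np.clip(idx, 0, self.genotypes.size - 1)
        return self.genotypes[idx]

    @property
    def n_transitions(self) -> int:
        return int(self.genotypes.size - 1)

    def het_length(self) -> float:
        seg = np.diff(self.bounds)
        return float(seg[self.genotypes == HET].sum())


@dataclass
class PopulationTruth:
    """True mosaics for every simulated line, plus crossover bookkeeping."""

    layout: GenomeLayout
    lines: list[str]
    mosaics: dict[str, dict[str, TrueMosaic]]
    n_meioses: int  # meioses per chromosome per line over the pedigree

    def het_fraction(self, line: str) -> float:
        tot = sum(c.length_bp for c in self.layout.chromosomes)
        het = sum(m.het_length() for m in self.mosaics[line].values())
        return het / tot

    def crossover_summary(self) -> pd.DataFrame:
        """Per-chromosome crossover means, both bookkeeping conventions.

        ``mosaic_mean`` counts genotype transitions visible in the final
        line mosaics (what a bin map recovers); ``meiotic_mean`` counts
        every crossover drawn over all generations, most of which leave
        no trace after inbreeding.
        """
        rows = []
        for chrom in self.layout.chrom_names:
            trans = [self.mosaics[l][chrom].n_transitions for l in self.lines]
            meio = [self.mosaics[l][chrom].crossover_positions.size for l in self.lines]
            rows.append(
                {
                    "chrom": chrom,
                    "mosaic_total": int(np.sum(trans)),
                    "mosaic_mean": float(np.mean(trans)),
                    "meiotic_total": int(np.sum(meio)),
                    "meiotic_mean": float(np.mean(meio)),
                }
            )
        return pd.DataFrame(rows)


class GenotypeObservations:
    """Sparse per-line parental-allele calls at physical SNP positions."""

    def __init__(self, data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]):
        # data[line][chrom] = (positions int64, alleles int8 in {ALLELE_P1, ALLELE_P2})
        self.data = data

    @property
    def lines(self) -> list[str]:
        return list(self.data.keys())

    def get(self, line: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self.data.get(line, {}).get(
            chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8))
        )

    def n_observations(self) -> int:
        return sum(p.size for per in self.data.values() for p, _ in per.values())

    def to_frame(self) -> pd.DataFrame:
        """Long table (chrom, pos, line, allele) sorted for stable output."""
        recs = []
        for line in self.lines:
            for chrom, (pos, allele) in self.data[line].items():
                recs.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "line": line,
                            "allele": np.where(allele == ALLELE_P1, "P1", "P2"),
                        }
                    )
                )
        if not recs:
            return pd.DataFrame(columns=["chrom", "pos", "line", "allele"])
        out = pd.concat(recs, ignore_index=True)
        return out.sort_values(["chrom", "pos", "line"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeObservations":
        bad = set(frame["allele"].unique()) - {"P1", "P2"}
        if bad:
            raise ValueError(f"unknown allele codes {sorted(bad)}")
        data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for (line, chrom), grp in frame.groupby(["line", "chrom"], sort=True):
            grp = grp.sort_values("pos", kind="stable")
            data.setdefault(str(line), {})[str(chrom)] = (
                grp["pos"].to_numpy(dtype=np.int64),
                np.where(grp["allele"].to_numpy() == "P1", ALLELE_P1, ALLELE_P2).astype(
                    np.int8
                ),
            )
        return cls(data)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def _draw_crossovers(
    rng: np.random.Generator,
    n: int,
    length_bp: int,
    intensity: np.ndarray | None,
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if intensity is None:
        pos = rng.uniform(0.0, length_bp, size=n)
    else:
        w = intensity / intensity.sum()
        win = rng.choice(w.size, size=n, p=w)
        lo = win * 1_000_000.0
        hi = np.minimum(lo + 1_000_000.0, float(length_bp))
        pos = rng.uniform(lo, hi)
    pos.sort()
    return pos


def simulate_population(
    layout: GenomeLayout, params: SimulationParams
) -> tuple[PopulationTruth, GenotypeObservations]:
    """Simulate a selfed RIL population and its sparse GBS observations.

    Deterministic for a fixed ``params.seed``.  Returns the ground-truth
    mosaics (with full crossover bookkeeping) and the noisy sparse
    observations the genotype caller consumes.
    """
    for name in layout.chrom_names:
        if layout.n_snps(name) == 0:
            raise ValueError(f"chromosome {name} has no SNP positions")
    root = np.random.SeedSequence(params.seed)
    line_seeds = root.spawn(params.n_lines)
    width = max(4, len(str(params.n_lines)))
    lines = [f"L{i + 1:0{width}d}" for i in range(params.n_lines)]

    mosaics: dict[str, dict[str, TrueMosaic]] = {}
    obs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    # F1 meiosis plus one per selfing generation, two gametes each.
    n_meioses = 2 * params.n_selfing_generations

    for line, seed in zip(lines, line_seeds):
        rng = np.random.default_rng(seed)
        mosaics[line] = {}
        obs[line] = {}
        for chrom in layout.chromosomes:
            length = chrom.length_bp
            mean_xo = chrom.genetic_length_cM / 100.0
            intensity = (
                None
                if layout.crossover_intensity is None
                else layout.crossover_intensity.get(chrom.name)
            )
            # F1 individual: one intact haplotype from each parent.
            edges = np.array([0.0, float(length)])
            h1: Haplotype = (edges.copy(), np.array([P1], dtype=np.int8))
            h2: Haplotype = (edges.copy(), np.array([P2], dtype=np.int8))
            all_xo: list[np.ndarray] = []
            for _ in range(params.n_selfing_generations):
                gametes = []
                for _g in range(2):
                    n_xo = rng.poisson(mean_xo)
                    xo = _draw_crossovers(rng, n_xo, length, intensity)
                    all_xo.append(xo)
                    start = int(rng.integers(2))
                    gametes.append(_recombine(h1, h2, xo, start))
                h1, h2 = gametes
            bounds, geno = _mosaic_from_haplotypes(h1, h2)
            mosaic = TrueMosaic(
                chrom.name,
                bounds,
                geno,
                np.sort(np.concatenate(all_xo)) if all_xo else np.empty(0),
            )
            mosaics[line][chrom.name] = mosaic

            # GBS observation process.
            snps = layout.snp_positions[chrom.name]
            sampled = rng.random(snps.size) < params.site_sampling_rate
            pos = snps[sampled]
            true_geno = mosaic.genotype_at(pos.astype(float))
            emitted = np.where(true_geno == P1, ALLELE_P1, ALLELE_P2).astype(np.int8)
            het = true_geno == HET
            if het.any():
                emitted[het] = np.where(
                    rng.random(int(het.sum())) < 0.5, ALLELE_P1, ALLELE_P2
                )
            u = rng.random(pos.size)
            flip = np.where(
                emitted == ALLELE_P1, u < params.error_rate_p1, u < params.error_rate_p2
            )
            emitted = np.where(flip, ALLELE_P2 + ALLELE_P1 - emitted, emitted).astype(
                np.int8
            )
            obs[line][chrom.name] = (pos, emitted)

    truth = PopulationTruth(layout, lines, mosaics, n_meioses)
    return truth, GenotypeObservations(obs)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    truth: PopulationTruth, model: PhenotypeModel, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate line x environment phenotypes from planted additive QTLs.

    Returns the long phenotype table (line, environment, trait, value)
    and a per-locus report with the realized proportion of phenotypic
    variance explained (PVE, %), computed against environment-centred
    phenotypic variance.
    """
    rng = np.random.default_rng(seed)
    names = {c.name for c in truth.layout.chromosomes}
    X = np.empty((len(truth.lines), len(model.qtl_loci)))
    for k, (chrom, pos, _a) in enumerate(model.qtl_loci):
        if chrom not in names:
            raise ValueError(f"QTL locus on unknown chromosome {chrom!r}")
        if not 1 <= pos <= truth.layout.chrom(chrom).length_bp:
            raise ValueError(f"QTL position {pos} outside chromosome {chrom}")
        for i, line in enumerate(truth.lines):
            g = truth.mosaics[line][chrom].genotype_at(np.array([float(pos)]))[0]
            X[i, k] = {P1: -1.0, HET: 0.0, P2: 1.0}[int(g)]
    effects = np.array([a for _, _, a in model.qtl_loci])
    genetic = X @ effects if effects.size else np.zeros(len(truth.lines))

    recs = []
    for j, env_shift in enumerate(model.env_effects):
        e = rng.normal(0.0, model.residual_sd, size=len(truth.lines))
        y = model.mu + env_shift + genetic + e
        for line, val in zip(truth.lines, y):
            recs.append((line, f"env{j + 1}", model.trait, float(val)))
    table = pd.DataFrame(recs, columns=["line", "environment", "trait", "value"])

    centred = (
        table["value"] - table.groupby("environment")["value"].transform("mean")
    ).to_numpy()
    total_var = float(np.var(centred))
    pve = []
    for k, (chrom, pos, a) in enumerate(model.qtl_loci):
        var_k = float(np.var(a * X[:, k]))
        pve.append(
            {
                "chrom": chrom,
                "position_bp": pos,
                "additive_effect": a,
                "realized_pve_pct": 100.0 * var_k / total_var if total_var > 0 else 0.0,
            }
        )
    return table, pd.DataFrame(pve)


# ---------------------------------------------------------------------------
# Backcross progeny simulation (introgression-line verification)
# ---------------------------------------------------------------------------


def simulate_backcross_progeny(
    donor_segment: tuple[int, int],
    markers: np.ndarray,
    n_progeny: int,
    effect: float,
    seed: int,
    base_mean: float = 0.0,
    residual_sd: float = 1.0,
    recombination: bool = False,
    segment_cM: float = 0.0,
) -> pd.DataFrame:
    """Progeny of an introgression line crossed back to the recurrent parent.

    The parent is heterozygous across ``donor_segment``; each progeny
    inherits the donor chromosome of that segment with probability 1/2
    (one dose), shifting its phenotype by ``effect / 2``.  With
    ``recombination`` enabled a crossover may fall inside the segment
    (Poisson at ``segment_cM``/100 per meiosis, uniform position),
    truncating the inherited heterozygous tract.  Marker genotypes are
    reported as ``H`` (heterozygous) / ``A`` (homozygous recurrent).
    """
    if n_progeny < 2:
        raise ValueError("need at least 2 progeny")
    lo, hi = donor_segment
    if hi <= lo:
        raise ValueError("empty donor segment")
    markers = np.asarray(markers, dtype=np.int64)
    rng = np.random.default_rng(seed)

    rows = []
    inside = (markers >= lo) & (markers <= hi)
    for i in range(n_progeny):
        het = np.zeros(markers.size, dtype=bool)
        if recombination and rng.poisson(segment_cM / 100.0) > 0:
            cut = rng.uniform(lo, hi)
            left_donor = bool(rng.integers(2))
            carried = inside & ((markers <= cut) == left_donor)
        else:
            carried = inside if rng.integers(2) == 0 else np.zeros_like(inside)
        het[carried] = True
        carrier = bool(het.any())
        y = base_mean + (effect / 2.0 if carrier else 0.0) + rng.normal(0.0, residual_sd)
        row = {"progeny_id": f"p{i + 1:03d}", "phenotype": float(y), "carrier": carrier}
        for m, h in zip(markers, het):
            row[f"m{m}"] = "H" if h else "A"
        rows.append(row)
    return pd.DataFrame(rows)
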