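"""Genome coordinate frame and shared genotype encodings.

Everything downstream works on one integer encoding of a biparental RIL
genotype: ``P1`` and ``P2`` are the two parental homozygotes (in the
motivating cross, Zheng58 and Chang7-2), ``HET`` is residual
heterozygosity left over from incomplete selfing, and ``MISSING`` marks
uncalled intervals.  Physical coordinates are 1-based inclusive bp in
memory; BED-like files on disk are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Genotype codes used in mosaics, bin matrices and truth tracks.
P1: int = 0
HET: int = 1
P2: int = 2
MISSING: int = -1

GENO_LABELS = {P1: "P1", HET: "HET", P2: "P2", MISSING: "NA"}
LABEL_TO_GENO = {v: k for k, v in GENO_LABELS.items()}

# Allele codes for single observed GBS sites (haploid-like calls).
ALLELE_P1: int = 0
ALLELE_P2: int = 2
ALLELE_LABELS = {ALLELE_P1: "P1", ALLELE_P2: "P2"}


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the mapping population's coordinate frame."""

    name: str
    length_bp: int
    genetic_length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")
        if self.genetic_length_cM <= 0:
            raise ValueError(f"chromosome {self.name}: genetic_length_cM must be > 0")


@dataclass
class GenomeLayout:
    """Physical and genetic skeleton the simulator and pipeline share.

    Parameters
    ----------
    chromosomes
        Ordered chromosomes with physical (bp) and genetic (cM) lengths.
    snp_positions
        Per-chromosome sorted, strictly increasing 1-based SNP positions:
        the sites at which parents are opposite-homozygous and GBS can
        emit an informative call.
    crossover_intensity
        Optional per-chromosome relative crossover weights over
        consecutive 1-Mb windows.  Uniform when omitted.  Weights are
        relative only; they are normalised at sampling time.
    """

    chromosomes: list[Chromosome]
    snp_positions: dict[str, np.ndarray]
    crossover_intensity: dict[str, np.ndarray] | None = None
    _by_name: dict[str, Chromosome] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        self._by_name = {c.name: c for c in self.chromosomes}
        if len(self._by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, pos in self.snp_positions.items():
            chrom = self._by_name.get(name)
            if chrom is None:
                raise ValueError(f"snp_positions for unknown chromosome {name!r}")
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"SNP positions on {name} not strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > chrom.length_bp):
                raise ValueError(f"SNP positions on {name} outside [1, length]")
            self.snp_positions[name] = pos
        if self.crossover_intensity is not None:
            for name, w in self.crossover_intensity.items():
                w = np.asarray(w, dtype=float)
                if np.any(w < 0) or not np.any(w > 0):
                    raise ValueError(
                        f"crossover intensity on {name}: weights must be "
                        "non-negative and not all zero"
                    )
                self.crossover_intensity[name] = w

    # -- accessors ---------------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> Chromosome:
        return self._by_name[name]

    def n_snps(self, name: str) -> int:
        return int(self.snp_positions.get(name, np.empty(0)).size)

    # -- factories ---------------------------------------------------------
    @classmethod
    def regular(
        cls,
        n_chromosomes: int = 10,
        length_bp: int = 150_000_000,
        genetic_length_cM: float = 150.0,
        snp_spacing_bp: int = 4_000,
        crossover_intensity: dict[str, np.ndarray] | None = None,
    ) -> "GenomeLayout":
        """Evenly spaced SNP scaffold, one SNP per ``snp_spacing_bp``.

        The default spacing describes the dense parental SNP set: at a
        0.08 site-sampling rate it yields roughly one observed SNP per
        50 kb per line, the working marker density of a low-coverage
        GBS RIL panel.
        """
        chroms = [
            Chromosome(f"chr{i + 1}", length_bp, genetic_length_cM)
            for i in range(n_chromosomes)
        ]
        positions = {
            c.name: np.arange(snp_spacing_bp, length_bp + 1, snp_spacing_bp, dtype=np.int64)
            for c in chroms
        }
        return cls(chroms, positions, crossover_intensity)
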