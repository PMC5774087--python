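"""Readers and writers for the pipeline's on-disk formats.

Canonical formats are plain TSV; a minimal VCF reader/writer is
provided as a convenience for genotype observations.  Coordinate
conventions: TSV tables are 1-based inclusive, BED-like files (mosaics,
bins, profiles) are 0-based half-open; each writer states the
convention in its header comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import CallerConfig, LineMosaic
from .binmap import BinMap, GeneticMap
from .genome import (
    ALLELE_P1,
    ALLELE_P2,
    GENO_LABELS,
    LABEL_TO_GENO,
    MISSING,
    Chromosome,
    GenomeLayout,
)
from .qtl import ScanConfig
from .simulate import GenotypeObservations, SimulationParams

__all__ = [
    "read_genotype_observations",
    "write_observations_tsv",
    "write_observations_vcf",
    "write_mosaics_bed",
    "read_mosaics_bed",
    "write_binmap",
    "read_binmap",
    "write_genetic_map",
    "write_profile",
    "write_phenotypes",
    "read_phenotypes",
    "load_run_config",
    "write_provenance",
]

_MATRIX_CODE = {0: "0", 1: "1", 2: "2", -1: "NA"}


# -- genotype observations --------------------------------------------------


def write_observations_tsv(obs: GenotypeObservations, path: str | Path) -> None:
    """Long TSV (chrom, pos, line, allele), 1-based positions."""
    frame = obs.to_frame()
    with open(path, "w") as fh:
        fh.write("# genotype observations; pos is 1-based\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_observations_vcf(
    obs: GenotypeObservations,
    layout: GenomeLayout,
    path: str | Path,
    parent1: str = "P1",
    parent2: str = "P2",
) -> None:
    """Minimal VCF: parents as the first two samples, lines after.

    REF/ALT are placeholders (A/T); the information content is entirely
    in the GT fields, with the P1 allele as REF.  Sites are the union
    of observed positions across lines.
    """
    lines = obs.lines
    per_site: dict[tuple[str, int], dict[str, int]] = {}
    for line in lines:
        for chrom in layout.chrom_names:
            pos, allele = obs.get(line, chrom)
            for p, a in zip(pos, allele):
                per_site.setdefault((chrom, int(p)), {})[line] = int(a)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in layout.chromosomes:
            fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                  parent1, parent2, *lines]
        fh.write("\t".join(header) + "\n")
        order = {c.name: i for i, c in enumerate(layout.chromosomes)}
        for (chrom, pos), calls in sorted(
            per_site.items(), key=lambda kv: (order[kv[0][0]], kv[0][1])
        ):
            gts = ["0/0", "1/1"]
            for line in lines:
                a = calls.get(line)
                if a is None:
                    gts.append("./.")
                else:
                    gts.append("0/0" if a == ALLELE_P1 else "1/1")
            fh.write(
                f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_genotype_observations(
    path: str | Path,
    fmt: str = "tsv",
    parent1: str = "P1",
    parent2: str = "P2",
) -> tuple[GenotypeObservations, dict]:
    """Read observations from TSV or minimal VCF.

    For VCF, alleles are polarized by the two named parent samples;
    sites where the parents are not opposite homozygotes (or either is
    missing) are dropped and counted in the returned report.
    """
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", comment="#")
        try:
            return GenotypeObservations.from_frame(frame), {"dropped_sites": 0}
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed observation table: {exc}") from exc
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")

    import pysam

    dropped = 0
    recs: dict[str, dict[str, tuple[list[int], list[int]]]] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for parent in (parent1, parent2):
            if parent not in samples:
                raise ValueError(f"{path}: parent sample {parent!r} not in VCF")
        lines = [s for s in samples if s not in (parent1, parent2)]
        for rec in vf:
            g1 = rec.samples[parent1]["GT"]
            g2 = rec.samples[parent2]["GT"]
            if (
                None in (g1, g2)
                or None in g1
                or None in g2
                or len(set(g1)) != 1
                or len(set(g2)) != 1
                or g1[0] == g2[0]
            ):
                dropped += 1
                continue
            p1_allele = g1[0]
            for line in lines:
                gt = rec.samples[line]["GT"]
                if gt is None or None in gt or len(set(gt)) != 1:
                    continue
                code = ALLELE_P1 if gt[0] == p1_allele else ALLELE_P2
                chrom_map = recs.setdefault(line, {})
                pos_list, al_list = chrom_map.setdefault(rec.chrom, ([], []))
                pos_list.append(rec.pos)
                al_list.append(code)
    data = {
        line: {
            chrom: (
                np.asarray(pos, dtype=np.int64),
                np.asarray(al, dtype=np.int8),
            )
            for chrom, (pos, al) in per.items()
        }
        for line, per in recs.items()
    }
    return GenotypeObservations(data), {"dropped_sites": dropped}


# -- mosaics ----------------------------------------------------------------


def write_mosaics_bed(
    mosaics: dict[str, dict[str, LineMosaic]], path: str | Path
) -> None:
    """BED-like per-line segments (0-based half-open on disk)."""
    with open(path, "w") as fh:
        fh.write("# line mosaics; BED-like, 0-based half-open\n")
        fh.write("line\tchrom\tstart\tend\tgenotype\tsnp_count\n")
        for line in sorted(mosaics):
            for chrom in mosaics[line]:
                m = mosaics[line][chrom]
                for s, e, g, c in zip(m.start, m.end, m.genotype, m.snp_count):
                    fh.write(
                        f"{line}\t{chrom}\t{s - 1}\t{e}\t{GENO_LABELS[int(g)]}\t{c}\n"
                    )


def read_mosaics_bed(
    path: str | Path, layout: GenomeLayout
) -> dict[str, dict[str, LineMosaic]]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    out: dict[str, dict[str, LineMosaic]] = {}
    for (line, chrom), grp in df.groupby(["line", "chrom"], sort=True):
        grp = grp.sort_values("start", kind="stable")
        out.setdefault(str(line), {})[str(chrom)] = LineMosaic(
            str(chrom),
            layout.chrom(str(chrom)).length_bp,
            grp["start"].to_numpy(dtype=np.int64) + 1,
            grp["end"].to_numpy(dtype=np.int64),
            grp["genotype"].map(LABEL_TO_GENO).to_numpy(dtype=np.int8),
            grp["snp_count"].to_numpy(dtype=np.int64),
        )
    # lines may legitimately miss chromosomes with no observations
    for line, per in out.items():
        for chrom in layout.chrom_names:
            if chrom not in per:
                per[chrom] = LineMosaic(
                    chrom,
                    layout.chrom(chrom).length_bp,
                    np.array([1], dtype=np.int64),
                    np.array([layout.chrom(chrom).length_bp], dtype=np.int64),
                    np.array([MISSING], dtype=np.int8),
                    np.array([0], dtype=np.int64),
                )
    return out


# -- bin map ----------------------------------------------------------------


def write_binmap(binmap: BinMap, bins_path: str | Path, matrix_path: str | Path) -> None:
    """Bin table (BED-like) plus lines x bins matrix (0/1/2/NA codes)."""
    with open(bins_path, "w") as fh:
        fh.write("# bins; BED-like, 0-based half-open\n")
        out = binmap.bins.copy()
        out["start"] = out["start"] - 1
        out.to_csv(fh, sep="\t", index=False)
    mat = pd.DataFrame(
        [[_MATRIX_CODE[int(v)] for v in row] for row in binmap.G],
        index=pd.Index(binmap.lines, name="line"),
        columns=[f"bin{i:05d}" for i in range(binmap.n_bins)],
    )
    with open(matrix_path, "w") as fh:
        fh.write("# genotype matrix; 0=P1 1=HET 2=P2 NA=missing\n")
        mat.to_csv(fh, sep="\t")


def read_binmap(
    bins_path: str | Path, matrix_path: str | Path, layout: GenomeLayout
) -> BinMap:
    bins = pd.read_csv(bins_path, sep="\t", comment="#")
    bins["start"] = bins["start"] + 1
    mat = pd.read_csv(
        matrix_path, sep="\t", comment="#", index_col=0, dtype=str,
        keep_default_na=False,
    )
    G = mat.replace("NA", "-1").to_numpy(dtype=np.int8)
    return BinMap(
        bins, G, list(mat.index), {c.name: c.length_bp for c in layout.chromosomes}
    )


# -- genetic map / profile / phenotypes ------------------------------------


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genetic map ({gmap.map_function}); 1-based inclusive bp\n")
        gmap.table.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# recombination profile; BEDGRAPH-like, 0-based half-open\n")
        out = profile.copy()
        out["start"] = out["start"] - 1
        out.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# phenotypes, long format\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"line", "environment", "trait", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: phenotype table needs columns {sorted(required)}")
    return df


# -- configuration / provenance ---------------------------------------------


def load_run_config(path: str | Path) -> dict:
    """Load a YAML/JSON run config into typed sections.

    Recognised sections: ``layout`` (chromosomes with name/length_bp/
    genetic_length_cM and snp_spacing_bp), ``simulation``
    (SimulationParams fields), ``caller`` (CallerConfig fields),
    ``scan`` (ScanConfig fields), plus free-form ``pipeline`` options.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    out: dict = {"raw": raw}
    if "layout" in raw:
        lay = raw["layout"]
        chroms = [
            Chromosome(c["name"], int(c["length_bp"]), float(c["genetic_length_cM"]))
            for c in lay["chromosomes"]
        ]
        spacing = int(lay.get("snp_spacing_bp", 50_000))
        positions = {
            c.name: np.arange(spacing, c.length_bp + 1, spacing, dtype=np.int64)
            for c in chroms
        }
        out["layout"] = GenomeLayout(chroms, positions)
    if "simulation" in raw:
        out["simulation"] = SimulationParams(**raw["simulation"])
    out["caller"] = CallerConfig(**raw.get("caller", {}))
    out["scan"] = ScanConfig(**raw.get("scan", {}))
    out["pipeline"] = raw.get("pipeline", {})
    return out


def write_provenance(path: str | Path, **fields) -> None:
    """Machine-readable provenance JSON (seed, thresholds, versions)."""
    import binqtl

    payload = {
        "binqtl_version": binqtl.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    payload.update(fields)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
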