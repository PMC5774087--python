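"""End-to-end orchestration: simulate -> call -> binmap -> map -> scan.

Each stage logs record counts (lines excluded, bins discarded, peaks
found) and the run emits a provenance JSON carrying the seed and every
threshold, so a rerun with the same seed reproduces every artifact
byte-for-byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as bio
from .binmap import (
    build_genetic_map,
    construct_bins,
    count_crossovers,
    filter_distorted_bins,
    impute_genotypes,
    recombination_profile,
    test_segregation_distortion,
)
from .calling import CallerConfig, call_population
from .genome import GenomeLayout
from .pheno import blup_line_values
from .qtl import ScanConfig, scan_trait
from .simulate import (
    GenotypeObservations,
    PhenotypeModel,
    SimulationParams,
    simulate_phenotypes,
    simulate_population,
)

logger = logging.getLogger("binqtl")

__all__ = ["run_pipeline", "default_layout", "default_phenotype_model"]


def default_layout(n_chromosomes: int = 2) -> GenomeLayout:
    """Compact layout for smoke runs: 150 Mb / 150 cM chromosomes."""
    return GenomeLayout.regular(n_chromosomes=n_chromosomes)


def default_phenotype_model(layout: GenomeLayout) -> PhenotypeModel:
    """Two planted additive QTLs in two environments."""
    chroms = layout.chromosomes
    loci = [(chroms[0].name, chroms[0].length_bp // 3, 1.0)]
    if len(chroms) > 1:
        loci.append((chroms[1].name, 2 * chroms[1].length_bp // 3, 0.7))
    return PhenotypeModel(loci, env_effects=[0.0, 2.0], residual_sd=2.5)


def run_pipeline(
    outdir: str | Path,
    layout: GenomeLayout | None = None,
    sim_params: SimulationParams | None = None,
    caller_cfg: CallerConfig | None = None,
    scan_cfg: ScanConfig | None = None,
    phenotype_model: PhenotypeModel | None = None,
    observations: GenotypeObservations | None = None,
    phenotypes: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """Run the full analysis and write all artifacts under ``outdir``.

    With no ``observations`` the synthetic generator provides them
    (that run is fully reproducible from ``seed``).  Returns a summary
    dict mirroring the provenance JSON.  Any stage failure raises with
    the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = layout or default_layout()
    caller_cfg = caller_cfg or CallerConfig()
    scan_cfg = scan_cfg or ScanConfig(seed=seed)
    summary: dict = {"seed": seed, "stages": {}}

    stage = "simulate"
    try:
        if observations is None:
            sim_params = sim_params or SimulationParams(seed=seed)
            truth, observations = simulate_population(layout, sim_params)
            phenotype_model = phenotype_model or default_phenotype_model(layout)
            phenotypes, planted = simulate_phenotypes(truth, phenotype_model, seed + 1)
            planted.to_csv(outdir / "planted_qtls.tsv", sep="\t", index=False)
            summary["stages"][stage] = {
                "n_lines": len(truth.lines),
                "n_observations": observations.n_observations(),
            }
        bio.write_observations_tsv(observations, outdir / "observations.tsv")
        if phenotypes is not None:
            bio.write_phenotypes(phenotypes, outdir / "phenotypes.tsv")

        stage = "call"
        retained, report = call_population(observations, layout, caller_cfg)
        report.to_csv(outdir / "line_filter_report.tsv", sep="\t", index=False)
        bio.write_mosaics_bed(retained, outdir / "mosaics.bed")
        summary["stages"][stage] = {
            "n_lines_in": len(report),
            "n_lines_retained": len(retained),
            "n_lines_excluded": int(report["excluded"].sum()),
        }
        if len(retained) < 2:
            summary["stages"]["binmap"] = {"skipped": "fewer than 2 retained lines"}
            bio.write_provenance(outdir / "provenance.json", **_prov(summary, caller_cfg, scan_cfg))
            return summary

        stage = "binmap"
        binmap = construct_bins(retained, layout)
        distortion = test_segregation_distortion(binmap)
        distortion.to_csv(outdir / "segregation_distortion.tsv", sep="\t", index=False)
        filtered, discard = filter_distorted_bins(binmap)
        imputed = impute_genotypes(filtered)
        bio.write_binmap(imputed, outdir / "bins.bed", outdir / "genotype_matrix.tsv")
        xo = count_crossovers(filtered)
        summary["stages"][stage] = {
            "n_bins": binmap.n_bins,
            "n_bins_discarded": discard["n_discarded"],
            "n_bins_distorted": int(distortion["distorted"].sum()),
            "crossovers_total": xo["total"],
            "crossovers_mean_per_line_per_chrom": round(
                xo["mean_per_line_per_chrom"], 1
            ),
        }

        stage = "map"
        gmap, map_summary = build_genetic_map(imputed)
        bio.write_genetic_map(gmap, outdir / "genetic_map.tsv")
        map_summary.to_csv(outdir / "map_summary.tsv", sep="\t", index=False)
        profile, corr = recombination_profile(gmap, imputed, layout)
        bio.write_profile(profile, outdir / "recombination_profile.tsv")
        corr.to_csv(outdir / "profile_correlations.tsv", sep="\t", index=False)
        summary["stages"][stage] = {"total_cM": round(gmap.total_cM, 3)}

        stage = "scan"
        peaks_all = []
        if phenotypes is not None:
            blups, comps = blup_line_values(phenotypes)
            blups.to_csv(outdir / "blups.tsv", sep="\t", float_format="%.6f")
            for trait in blups.columns:
                res = scan_trait(imputed, gmap, blups[trait], trait, scan_cfg)
                prof = gmap.table[["chrom", "start", "end"]].copy()
                prof["lod"] = res.lod
                prof.to_csv(
                    outdir / f"lod_profile_{trait}.tsv", sep="\t", index=False,
                    float_format="%.6f",
                )
                peaks_all.append(res.peaks.assign(threshold=res.threshold))
            peaks = (
                pd.concat(peaks_all, ignore_index=True)
                if peaks_all
                else pd.DataFrame()
            )
            if not peaks.empty:
                peaks["peak_Mb"] = peaks["peak_bp"] / 1e6
                peaks["interval_start_Mb"] = peaks["interval_start_bp"] / 1e6
                peaks["interval_end_Mb"] = peaks["interval_end_bp"] / 1e6
            peaks.to_csv(outdir / "qtl_peaks.tsv", sep="\t", index=False,
                         float_format="%.6f")
            summary["stages"][stage] = {
                "n_traits": len(blups.columns),
                "n_peaks": 0 if peaks.empty else len(peaks),
                "heritability": {t: round(c.h2, 4) for t, c in comps.items()},
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bio.write_provenance(
        outdir / "provenance.json", **_prov(summary, caller_cfg, scan_cfg)
    )
    logger.info("pipeline complete: %s", summary)
    return summary


def _prov(summary: dict, caller_cfg: CallerConfig, scan_cfg: ScanConfig) -> dict:
    return {
        "seed": summary["seed"],
        "caller_config": caller_cfg.__dict__,
        "scan_config": scan_cfg.__dict__,
        "stages": summary["stages"],
    }
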