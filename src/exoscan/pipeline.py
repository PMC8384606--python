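"""End-to-end orchestration: filter -> density/contrast -> Fst -> donor scan
-> spectral indices -> heritability, with a machine-readable summary.

All thresholds default to the study's values: depth >= 5 for reference
designation, <10% missing and MAF >= 5% locus filter, 500-kbp bins and Fst
windows (100-kbp bins for the density track), 5-fold donor classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, genome, introgression, phenomics
from .genotype import (
    GenotypeMatrix,
    apply_reference_call_rule,
    filter_loci,
    mask_varietal_snps,
    read_metadata,
    read_vcf,
)
from .introgression import build_donor_snpset
from .simulate import SimConfig, simulate_panel, simulate_spectra, simulate_traits

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run (defaults = study values)."""

    vcf: str | None = None
    donor_vcfs: dict[str, str] = field(default_factory=dict)
    mask_vcf: str | None = None
    metadata: str | None = None
    chrom_sizes: str | None = None
    spectra: str | None = None
    traits: str | None = None
    outdir: str = "exoscan_out"
    density_bin: int = 100_000
    scan_bin: int = 500_000
    fold: float = 5.0
    min_depth: int = 5
    max_missing: float = 0.10
    min_maf: float = 0.05
    fst_window: int = 500_000
    min_baseline: float = 1.0
    min_count: int = 10
    r: int | None = None
    e: int | None = None
    donor_subgenome: str = "D"
    seed: int = 0
    simulate: bool = False

    def validate(self) -> None:
        for name in ("density_bin", "scan_bin", "fst_window", "min_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if not self.simulate:
            for name in ("vcf", "metadata", "chrom_sizes"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} is required unless simulating")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the summary bundle under ``outdir``.

    Stage failures propagate with the stage name prefixed; outputs written
    before the failure are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "exoscan_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("donor_vcfs",) and not isinstance(v, dict)
        },
    }

    stage = "inputs"
    try:
        if config.simulate:
            sim = simulate_panel(SimConfig(seed=config.seed))
            sim.write(outdir / "simulated_inputs")
            matrix = sim.matrix
            chrom_sizes = sim.chrom_sizes
            metadata = sim.metadata
            donors = sim.donors
            mask = sim.varietal_mask
            spectra_table, _ = simulate_spectra(sim.config, n_samples=60)
            traits_table = simulate_traits(sim.config, n_genotypes=150)
        else:
            chrom_sizes = genome.read_chrom_sizes(config.chrom_sizes)
            matrix = read_vcf(config.vcf, chrom_sizes)
            metadata = read_metadata(config.metadata)
            mask = None
            if config.mask_vcf:
                mask = build_donor_snpset(config.mask_vcf, "varietal",
                                          chrom_sizes=chrom_sizes)
            donors = {
                name: build_donor_snpset(path, name, mask=mask,
                                         chrom_sizes=chrom_sizes)
                for name, path in config.donor_vcfs.items()
            }
            spectra_table = pd.read_csv(config.spectra, sep="\t") if config.spectra else None
            traits_table = pd.read_csv(config.traits, sep="\t") if config.traits else None
        metadata.validate_against(matrix)

        stage = "filter"
        designated = apply_reference_call_rule(matrix, min_depth=config.min_depth)
        masked = mask_varietal_snps(designated, mask) if mask is not None else designated
        filtered, report = filter_loci(
            masked, max_missing=config.max_missing, min_maf=config.min_maf,
            return_report=True,
        )
        report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        summary["filter"] = {
            "n_input_loci": int(matrix.n_loci),
            "n_after_mask": int(masked.n_loci),
            "n_filtered_loci": int(filtered.n_loci),
        }

        stage = "density"
        density = diversity.binned_density(filtered, chrom_sizes,
                                           bin_width=config.density_bin)
        density.to_csv(outdir / "snp_density.bedgraph.tsv", sep="\t", index=False)

        stage = "contrast"
        elites = metadata.elite_samples()
        exotics = metadata.exotic_samples()
        counts = diversity.per_line_snp_counts(masked, unit="subgenome")
        contrasts = diversity.contrast_table(counts, elites, exotics)
        contrasts.to_csv(outdir / "subgenome_contrast.tsv", sep="\t", index=False)
        summary["contrast"] = {
            row["unit"]: row["pct_difference"] for _, row in contrasts.iterrows()
        }

        stage = "fst"
        fst = diversity.windowed_fst(filtered, elites, exotics, chrom_sizes,
                                     window=config.fst_window)
        fst.to_csv(outdir / "fst.bedgraph.tsv", sep="\t", index=False)
        pseudo, _ = diversity.pseudo_split_control(
            filtered, elites, chrom_sizes, seed=config.seed,
            window=config.fst_window,
        )
        pseudo.to_csv(outdir / "fst_pseudo_split.bedgraph.tsv", sep="\t", index=False)
        summary["fst"] = {
            "mean_fst_elite_vs_exotic": float(np.nanmean(fst["fst_raw"])),
            "mean_fst_pseudo_split": float(np.nanmean(pseudo["fst_raw"])),
        }

        stage = "introgression"
        summary["introgression"] = {}
        for name, donor in donors.items():
            scan = introgression.scan_panel(
                masked, metadata, donor, chrom_sizes,
                bin_width=config.scan_bin, fold=config.fold,
                min_baseline=config.min_baseline, min_count=config.min_count,
                subgenome=config.donor_subgenome if name == "Ae_tauschii" else None,
            )
            segs = [s for line_segs in scan["segments"].values() for s in line_segs]
            introgression.segments_to_bed(segs).to_csv(
                outdir / f"segments_{name}.bed", sep="\t", index=False, header=False
            )
            summary["introgression"][name] = {
                "union_n_bins": scan["union"]["n_bins"],
                "union_span_gbp": scan["union"]["span_gbp"],
                "donor_fraction_pct": scan["fractions"],
                "theoretical_contribution_pct": scan["theoretical_contribution"],
            }

        stage = "indices"
        if spectra_table is not None:
            indices = phenomics.compute_all_indices(spectra_table)
            indices.to_csv(outdir / "spectral_indices.tsv", sep="\t")
            summary["indices"] = {"n_samples": int(len(indices)),
                                  "n_indices": int(indices.shape[1])}

        stage = "heritability"
        if traits_table is not None:
            h2 = phenomics.heritability_report(traits_table, r=config.r, e=config.e)
            h2.to_csv(outdir / "heritability.tsv", sep="\t", index=False)
            summary["heritability"] = {
                row["trait"]: {"H2": row["H2"], "class": row["class"]}
                for _, row in h2.iterrows()
            }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary
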