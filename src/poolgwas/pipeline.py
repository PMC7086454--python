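"""End-to-end orchestration: simulate -> assoc -> annotate -> enrich -> validate.

A run is driven by a :class:`PipelineConfig` (optionally loaded from TOML),
writes versioned TSV outputs plus a machine-readable manifest (config, seed,
input digests) into a run directory, and is byte-reproducible given the same
config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cohort_validation as cv
from . import enrichment, io_formats, pooling_gwas, prioritization, synthetic_data

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every analysis constant, with the study's values as defaults."""

    # QC and testing thresholds
    min_replicates: int = 3
    genomewide_alpha: float = 1.0e-7
    geneset_alpha: float = 1.0e-5
    window_bp: int = 20_000
    fprp_priors: tuple[float, ...] = prioritization.FPRP_PRIORS
    fprp_or_alt: float = prioritization.FPRP_OR_ALT
    bh_m_total: int | None = None
    reference_size: int | None = None
    # pool sizes (individuals) for the binomial variance term
    n_case: int = 200
    n_control: int = 200
    seed: int = 0
    # inputs; any left None is synthesized when simulate=True
    simulate: bool = False
    n_snps: int = 2000
    n_spiked: int = 10
    delta_f: float = 0.15
    noise_sd: float = synthetic_data.DEFAULT_NOISE_SD
    cohort_maf_control: float = 0.05
    cohort_or: float = 3.5
    n_cohort_cases: int = 250
    n_cohort_controls: int = 250
    intensities: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    genotypes: str | None = None
    platelets: str | None = None
    response_snp: str | None = None

    def __post_init__(self) -> None:
        for name in ("genomewide_alpha", "geneset_alpha"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "fprp_priors" in raw:
            raw["fprp_priors"] = tuple(raw["fprp_priors"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fprp_priors"] = list(self.fprp_priors)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline, returning the run directory.

    Stage order: simulate (if requested) -> assoc -> annotate -> enrich ->
    validate/response.  On a stage failure, outputs written so far are
    preserved and the manifest records the failed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "poolgwas",
        "version": __version__,
        "config": config.as_dict(),
        "stages": {},
        "inputs": {},
    }
    stage = "init"
    try:
        # --- simulate -----------------------------------------------------
        if config.simulate:
            stage = "simulate"
            table, truth = synthetic_data.simulate_pooled_experiment(
                n_snps=config.n_snps,
                n_spiked=config.n_spiked,
                delta_f=config.delta_f,
                n_case=config.n_case,
                n_control=config.n_control,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            io_formats.write_pool_intensities(table, out / "intensities.tsv")
            io_formats.write_results(truth.pool_truth, out / "truth.tsv")
            config.intensities = str(out / "intensities.tsv")

            ann = synthetic_data.synthetic_gene_annotation(truth.pool_truth, seed=config.seed)
            io_formats.write_gene_annotation(ann, out / "genes.bed")
            config.annotation = str(out / "genes.bed")

            pathways = synthetic_data.synthetic_pathways(
                ann["gene_symbol"].tolist(), seed=config.seed
            )
            io_formats.write_gmt(
                io_formats.PathwayDB(pathways, reference_size=len(ann)), out / "pathways.gmt"
            )
            config.gmt = str(out / "pathways.gmt")

            cohort, _ = synthetic_data.simulate_case_control_genotypes(
                n_cases=config.n_cohort_cases,
                n_controls=config.n_cohort_controls,
                maf_control=config.cohort_maf_control,
                or_allelic=config.cohort_or,
                seed=config.seed,
            )
            cohort = synthetic_data.simulate_treatment_response(
                cohort, "snp1", seed=config.seed
            )
            io_formats.write_genotypes(cohort, out / "cohort.tsv")
            io_formats.write_platelet_series(
                cohort.baseline_plt, cohort.plt, out / "platelets.tsv"
            )
            config.genotypes = str(out / "cohort.tsv")
            config.platelets = str(out / "platelets.tsv")
            config.response_snp = config.response_snp or "snp1"
            manifest["stages"]["simulate"] = "ok"

        for key in ("intensities", "annotation", "gmt", "genotypes", "platelets"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = _sha256(Path(path))

        # --- assoc --------------------------------------------------------
        stage = "assoc"
        table = io_formats.read_pool_intensities(config.intensities)
        filtered, qc_report = pooling_gwas.qc_filter(table, config.min_replicates)
        summary = pooling_gwas.summarize_pools(filtered, config.n_case, config.n_control)
        results = pooling_gwas.combined_z_test(summary)
        results["genomewide"] = results["p_value"] < config.genomewide_alpha
        io_formats.write_results(results, out / "assoc.tsv")
        (out / "qc.json").write_text(json.dumps(qc_report.as_dict(), indent=2))
        io_formats.write_results(
            pooling_gwas.qq_points(results["p_value"]), out / "qq.tsv"
        )
        io_formats.write_results(pooling_gwas.manhattan_points(results), out / "manhattan.tsv")
        r2 = pooling_gwas.raf_correlation(summary["f1"], summary["f2"])
        manifest["stages"]["assoc"] = {
            "qc": qc_report.as_dict(),
            "genomewide_hits": int(results["genomewide"].sum()),
            "raf_r2": r2,
        }

        # --- annotate -----------------------------------------------------
        stage = "annotate"
        annotation = io_formats.read_gene_annotation(config.annotation)
        assignments = prioritization.map_snps_to_genes(
            results, annotation, window_bp=config.window_bp
        )
        genes = prioritization.gene_level_best(assignments)
        io_formats.write_results(genes, out / "genes.tsv")
        hits = pooling_gwas.genomewide_hits(results, config.genomewide_alpha)
        fprp_rows = []
        for hit in hits.itertuples(index=False):
            f1 = summary.loc[hit.snp_id, "f1"]
            f2 = summary.loc[hit.snp_id, "f2"]
            if not (0 < f1 < 1 and 0 < f2 < 1):
                continue
            est = prioritization.or_from_raf(f1, f2, config.n_case, config.n_control)
            row = {
                "snp_id": hit.snp_id,
                "p_value": hit.p_value,
                "or": est.or_,
                "ci95_low": est.ci_low,
                "ci95_high": est.ci_high,
            }
            for prior in config.fprp_priors:
                row[f"fprp_pi_{prior:g}"] = prioritization.fprp(
                    hit.p_value, est.se_log_or, prior, or_alt=config.fprp_or_alt
                )
            fprp_rows.append(row)
        io_formats.write_results(pd.DataFrame(fprp_rows), out / "hits.tsv")
        manifest["stages"]["annotate"] = {
            "assignments": len(assignments),
            "genes": len(genes),
            "hits": len(hits),
        }

        # --- enrich ---------------------------------------------------------
        stage = "enrich"
        db = io_formats.read_gmt(config.gmt, reference_size=config.reference_size)
        if config.reference_size is None:
            # reference universe defaults to the annotated gene count
            db = io_formats.PathwayDB(db.pathways, reference_size=len(annotation))
        study = prioritization.select_gene_set(genes, config.geneset_alpha)
        enriched = enrichment.enrich_all(study, db, m_total=config.bh_m_total)
        io_formats.write_results(enriched, out / "enrich.tsv")
        manifest["stages"]["enrich"] = {
            "study_genes": len(study),
            "pathways": len(db.pathways),
        }

        # --- validate / response -------------------------------------------
        if config.genotypes:
            stage = "validate"
            cohort = io_formats.read_genotypes(config.genotypes)
            rows = []
            for snp in cohort.snp_ids:
                counts = cv.genotype_counts(cohort, snp, groups=("case", "control"))
                chi2, df, p = cv.genotype_assoc_2x3(counts["case"], counts["control"])
                orr = cv.allelic_or(counts["case"], counts["control"])
                hwe_case = cv.hwe_test(*counts["case"])
                hwe_ctrl = cv.hwe_test(*counts["control"])
                rows.append(
                    {
                        "snp_id": snp,
                        "chi2": chi2,
                        "df": df,
                        "p": p,
                        "or": orr.or_,
                        "ci95_low": orr.ci_low,
                        "ci95_high": orr.ci_high,
                        "hwe_p_case": hwe_case[1],
                        "hwe_p_control": hwe_ctrl[1],
                    }
                )
            io_formats.write_results(pd.DataFrame(rows), out / "validate.tsv")
            manifest["stages"]["validate"] = {"snps": len(rows)}

        if config.platelets and config.response_snp:
            stage = "response"
            baseline, plt = io_formats.read_platelet_series(config.platelets)
            cohort = io_formats.read_genotypes(config.genotypes)
            dosage = cohort.genotypes[config.response_snp].fillna(0).astype(int)
            carrier = dosage >= 1
            compare = cv.timepoint_compare(
                plt.loc[carrier[plt.index]], plt.loc[~carrier[plt.index]]
            )
            io_formats.write_results(compare, out / "response_timepoints.tsv")
            manifest["stages"]["response"] = {
                "carriers": int(carrier.sum()),
                "noncarriers": int((~carrier).sum()),
            }
    except Exception:
        manifest["stages"][stage] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
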