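"""Synthetic pooled-array and cohort data with known ground truth.

The generators emulate the two-stage study design the pipeline targets:

* a discovery stage where case and control DNA pools (200 individuals each)
  are hybridized on replicate arrays (3 per pool) and per-SNP relative
  allele frequencies (RAF) are read off two fluorescence channels, and
* a validation stage where 250 cases and 250 controls are individually
  genotyped at candidate SNPs, with a genotype-linked glucocorticoid
  response label and a platelet-count time series.

Generative model for the pooled stage: the realized pool allele frequency
is a binomial draw over the 2N chromosomes in the pool (the binomial
sampling variance v_k of the association test); each replicate array reads
that frequency with additive Gaussian error truncated to [0,1] (the
replicate measurement error estimated by eps_k^2); the two channels share a
multiplicative per-replicate brightness factor, so channel imbalance cancels
in G/(G+R).

All randomness flows from a single integer seed; each generator draws from
its own documented substream (spawn key) so adding SNPs to one stage never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AUTOSOMES, GenotypeCohort, PooledIntensityTable

#: default study conditions for the pooled discovery stage
DEFAULT_N_CASE = 200
DEFAULT_N_CONTROL = 200
DEFAULT_N_REPS = 3
#: replicate-to-replicate RAF measurement error (SD); calibrated so that the
#: null cross-pool correlation of mean RAF exceeds r^2 = 0.99
DEFAULT_NOISE_SD = 0.01
DEFAULT_INTENSITY_SCALE = 10_000.0
#: multiplicative per-replicate array-brightness jitter (SD of u)
CHANNEL_NOISE_SD = 0.02

#: validation-cohort defaults
DEFAULT_N_CASES_COHORT = 250
DEFAULT_N_CONTROLS_COHORT = 250

#: platelet sampling days after the start of glucocorticoid treatment
RESPONSE_DAYS = (1, 3, 5, 7, 11, 14)

# substream spawn keys (SeedSequence spawn_key), one per generator
_STREAM_POOLED = 0
_STREAM_COHORT = 1
_STREAM_RESPONSE = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Ground truth behind a synthetic data set."""

    seed: int
    #: per-SNP truth for the pooled stage: snp_id, f_case, f_control, spiked
    pool_truth: pd.DataFrame | None = None
    spiked_ids: list[str] = field(default_factory=list)
    delta_f: float = 0.0
    #: cohort-level truth
    maf_control: float | None = None
    or_allelic: float | None = None
    snp_maf: dict[str, tuple[float, float]] = field(default_factory=dict)


def case_frequency_from_or(maf_control: float, or_allelic: float) -> float:
    """Case allele frequency implied by a control MAF and an allelic OR.

    Inverts OR = [p(1-q)] / [q(1-p)]: p = OR*q / (1 - q + OR*q).
    """
    q = maf_control
    return (or_allelic * q) / (1.0 - q + or_allelic * q)


def simulate_pooled_experiment(
    n_snps: int,
    n_spiked: int = 0,
    delta_f: float = 0.15,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    n_reps: int = DEFAULT_N_REPS,
    intensity_scale: float = DEFAULT_INTENSITY_SCALE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[PooledIntensityTable, SimTruth]:
    """Simulate a two-pool replicate-array experiment.

    The first ``n_spiked`` SNPs carry a case/control allele-frequency
    differential of ``delta_f`` (clamped to [0,1]); the rest are null.
    Control truth is Uniform(0.05, 0.95) per SNP.  SNPs are tiled across the
    22 autosomes at 1 kb spacing.

    Returns the intensity table and the :class:`SimTruth` behind it.
    Deterministic given ``seed``.
    """
    if n_spiked > n_snps:
        raise ValueError(f"n_spiked ({n_spiked}) exceeds n_snps ({n_snps})")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 <= delta_f <= 1.0:
        raise ValueError("delta_f must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = _rng(seed, _STREAM_POOLED)
    snp_ids = np.array([f"snp{i + 1}" for i in range(n_snps)])
    chroms = np.array([AUTOSOMES[i % len(AUTOSOMES)] for i in range(n_snps)])
    pos = np.array([1 + (i // len(AUTOSOMES)) * 1000 for i in range(n_snps)], dtype=np.int64)

    f_control = rng.uniform(0.05, 0.95, size=n_snps)
    spiked = np.zeros(n_snps, dtype=bool)
    spiked[:n_spiked] = True
    f_case = np.where(spiked, np.clip(f_control + delta_f, 0.0, 1.0), f_control)

    frames = []
    for pool, f_true, n_ind in (("case", f_case, n_case), ("control", f_control, n_control)):
        # pool composition: one binomial draw over the 2N chromosomes
        realized = rng.binomial(2 * n_ind, f_true) / (2.0 * n_ind)
        for rep in range(1, n_reps + 1):
            raf = realized + rng.normal(0.0, noise_sd, size=n_snps) if noise_sd > 0 else realized.copy()
            raf = np.clip(raf, 0.0, 1.0)
            u = rng.normal(0.0, CHANNEL_NOISE_SD, size=n_snps)
            bright = np.maximum(1.0 + u, 1e-6)
            green = intensity_scale * raf * bright
            red = intensity_scale * (1.0 - raf) * bright
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": snp_ids,
                        "chrom": chroms,
                        "pos": pos,
                        "pool": pool,
                        "replicate": rep,
                        "green_raw": green,
                        "red_raw": red,
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    data["failed"] = (data["green_raw"] == 0.0) & (data["red_raw"] == 0.0)

    truth = SimTruth(
        seed=seed,
        pool_truth=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chroms,
                "pos": pos,
                "f_case": f_case,
                "f_control": f_control,
                "spiked": spiked,
            }
        ),
        spiked_ids=list(snp_ids[spiked]),
        delta_f=delta_f,
    )
    return PooledIntensityTable(data), truth


def simulate_case_control_genotypes(
    n_cases: int = DEFAULT_N_CASES_COHORT,
    n_controls: int = DEFAULT_N_CONTROLS_COHORT,
    maf_control: float | dict[str, float] = 0.05,
    or_allelic: float | dict[str, float] = 1.0,
    seed: int = 0,
) -> tuple[GenotypeCohort, SimTruth]:
    """Simulate an individually genotyped case/control cohort under HWE.

    ``maf_control`` and ``or_allelic`` may be scalars (one SNP, id 'snp1')
    or dicts keyed by SNP id.  Within each group genotypes are drawn as
    Binomial(2, p) — Hardy-Weinberg proportions at the group's allele
    frequency.  Deterministic given ``seed``.
    """
    if np.isscalar(maf_control):
        maf_control = {"snp1": float(maf_control)}
    if np.isscalar(or_allelic):
        or_allelic = {snp: float(or_allelic) for snp in maf_control}
    for snp, q in maf_control.items():
        if not 0.0 < q <= 0.5:
            raise ValueError(f"maf_control for {snp} must be in (0, 0.5]")
        if or_allelic[snp] <= 0:
            raise ValueError(f"or_allelic for {snp} must be > 0")

    rng = _rng(seed, _STREAM_COHORT)
    subjects = [f"case{i + 1}" for i in range(n_cases)] + [
        f"ctrl{i + 1}" for i in range(n_controls)
    ]
    group = pd.Series(
        ["case"] * n_cases + ["control"] * n_controls,
        index=pd.Index(subjects, name="subject"),
        name="group",
    )
    cols = {}
    snp_maf = {}
    for snp, q in maf_control.items():
        p_case = case_frequency_from_or(q, or_allelic[snp])
        dosage_case = rng.binomial(2, p_case, size=n_cases)
        dosage_ctrl = rng.binomial(2, q, size=n_controls)
        cols[snp] = np.concatenate([dosage_case, dosage_ctrl])
        snp_maf[snp] = (p_case, q)
    genotypes = pd.DataFrame(cols, index=group.index).astype("Int64")

    truth = SimTruth(
        seed=seed,
        maf_control=next(iter(maf_control.values())),
        or_allelic=next(iter(or_allelic.values())),
        snp_maf=snp_maf,
    )
    return GenotypeCohort(genotypes=genotypes, group=group), truth


@dataclass
class TrajectoryParams:
    """Logistic platelet-recovery trajectory under glucocorticoid treatment.

    Counts rise from a thrombocytopenic baseline (< 30e9/L) toward a
    dosage-dependent plateau: plateau_carrier applies to minor-allele
    carriers (dosage >= 1), plateau_ref to non-carriers.  Units 1e9/L.
    """

    plateau_ref: float = 80.0
    plateau_carrier: float = 150.0
    baseline_low: float = 5.0
    baseline_high: float = 25.0
    rate: float = 0.6
    midpoint_day: float = 5.0
    noise_sd: float = 15.0


def simulate_treatment_response(
    cohort: GenotypeCohort,
    snp_id: str,
    response_prob_by_dosage: dict[int, float] | None = None,
    trajectory_params: TrajectoryParams | None = None,
    seed: int = 0,
    days: tuple[int, ...] = RESPONSE_DAYS,
) -> GenotypeCohort:
    """Attach a response label and platelet series linked to one SNP.

    ``response_prob_by_dosage`` gives P(response) for dosage 0 and for
    dosage >= 1 (keys 0 and 1).  The default emulates a cohort where about
    two thirds respond overall and minor-allele carriers respond more often.
    Missing dosage is treated as 0 for label/trajectory purposes.
    """
    if snp_id not in cohort.genotypes.columns:
        raise KeyError(f"unknown snp_id: {snp_id}")
    probs = {0: 0.60, 1: 0.85} if response_prob_by_dosage is None else response_prob_by_dosage
    params = trajectory_params or TrajectoryParams()

    rng = _rng(seed, _STREAM_RESPONSE)
    dosage = cohort.genotypes[snp_id].fillna(0).to_numpy(dtype=int)
    carrier = dosage >= 1
    p_resp = np.where(carrier, probs[1], probs[0])
    responded = rng.random(len(dosage)) < p_resp

    baseline = rng.uniform(params.baseline_low, params.baseline_high, size=len(dosage))
    plateau = np.where(carrier, params.plateau_carrier, params.plateau_ref)
    # non-responders stay near baseline
    plateau = np.where(responded, plateau, baseline * 1.2)
    day_arr = np.asarray(days, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-params.rate * (day_arr[None, :] - params.midpoint_day)))
    series = baseline[:, None] + (plateau - baseline)[:, None] * rise
    if params.noise_sd > 0:
        series = series + rng.normal(0.0, params.noise_sd, size=series.shape)
    series = np.maximum(series, 0.0)

    plt = pd.DataFrame(series, index=cohort.subjects, columns=[f"day_{d}" for d in days])
    return GenotypeCohort(
        genotypes=cohort.genotypes,
        group=cohort.group,
        baseline_plt=pd.Series(baseline, index=cohort.subjects, name="baseline"),
        plt=plt,
        response=pd.Series(
            np.where(responded, "response", "nonresponse"),
            index=cohort.subjects,
            name="response",
        ),
    )


def synthetic_gene_annotation(
    pool_truth: pd.DataFrame, gene_span: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Tile synthetic genes over the simulated SNP coordinates.

    Within each chromosome, every other SNP gets a gene overlapping it; the
    rest fall between genes so nearest-flank mapping is exercised.
    Synthetic stand-in for a real annotation download.
    """
    n_chroms = pool_truth["chrom"].nunique()
    rows = []
    for i, rec in enumerate(pool_truth.itertuples(index=False)):
        if (i // max(n_chroms, 1)) % 2 == 0:
            start = max(1, rec.pos - gene_span // 2)
            rows.append((f"GENE_{rec.snp_id}", rec.chrom, start, start + gene_span, "+"))
    ann = pd.DataFrame(rows, columns=["gene_symbol", "chrom", "start", "end", "strand"])
    return ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def synthetic_pathways(
    genes: list[str], n_pathways: int = 10, set_size: int = 20, seed: int = 0
) -> dict[str, frozenset[str]]:
    """Random gene sets over a synthetic gene universe (stand-in for KEGG)."""
    rng = _rng(seed, _STREAM_POOLED + 10)
    genes = list(genes)
    size = min(set_size, len(genes))
    return {
        f"pathway_{k + 1}": frozenset(rng.choice(genes, size=size, replace=False))
        for k in range(n_pathways)
    }
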