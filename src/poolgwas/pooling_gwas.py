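"""QC, RAF estimation and the combined Z-test over pooled-array intensities.

The discovery-stage statistic compares mean relative allele frequencies
(RAF, f = G/(G+R)) between a case pool and a control pool, accounting for
two variance components:

* v_k = f_k(1-f_k) / (2 N_k) — binomial sampling variance of the pool's
  allele frequency over the 2 N_k chromosomes it contains, and
* eps_k^2 = 1/(n_k(n_k-1)) * sum_i (f_ik - f_k)^2 — the squared standard
  error of the mean RAF over the n_k replicate arrays.

The combined statistic

    T_comb = (f1 - f2)^2 / (v1 + v2 + eps1^2 + eps2^2)

is referred to a chi-square distribution with 1 df (it is a squared
standardized difference of proportions); T1 drops the replicate-error terms
and Z = (f1 - f2) / sqrt(eps1^2 + eps2^2) tests the replicate means alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AUTOSOMES, PooledIntensityTable

GENOMEWIDE_ALPHA = 1.0e-7
MIN_REPLICATES = 3

#: smallest reportable p-value when all variance terms vanish but the means differ
P_FLOOR = np.nextafter(0.0, 1.0)


def compute_raf(green_raw, red_raw):
    """Relative allele frequency G/(G+R); NaN where both channels are zero."""
    green = np.asarray(green_raw, dtype=float)
    red = np.asarray(red_raw, dtype=float)
    total = green + red
    with np.errstate(invalid="ignore", divide="ignore"):
        raf = np.where(total > 0, green / np.where(total > 0, total, 1.0), np.nan)
    if raf.ndim == 0:
        return float(raf)
    return raf


@dataclass
class QCReport:
    """Row/SNP counts removed by each QC rule."""

    n_rows_in: int = 0
    n_failed_rows: int = 0
    n_snps_in: int = 0
    n_non_autosomal: int = 0
    n_insufficient_replicates: int = 0
    n_snps_out: int = 0
    dropped: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rows_in": self.n_rows_in,
            "failed_rows_removed": self.n_failed_rows,
            "snps_in": self.n_snps_in,
            "non_autosomal_snps_removed": self.n_non_autosomal,
            "insufficient_replicate_snps_removed": self.n_insufficient_replicates,
            "snps_out": self.n_snps_out,
        }


def qc_filter(
    table: PooledIntensityTable, min_replicates: int = MIN_REPLICATES
) -> tuple[PooledIntensityTable, QCReport]:
    """Apply the three pooled-array QC rules.

    1. failed hybridizations (both channels zero) are deleted;
    2. a SNP is dropped entirely if either pool retains fewer than
       ``min_replicates`` replicates;
    3. SNPs on X, Y and MT are dropped (pooling mixes male and female DNA,
       so sex-chromosome and mitochondrial intensities are uninterpretable).
    """
    df = table.data
    report = QCReport(n_rows_in=len(df), n_snps_in=df["snp_id"].nunique())

    failed = df["failed"] if "failed" in df.columns else (
        (df["green_raw"] == 0) & (df["red_raw"] == 0)
    )
    report.n_failed_rows = int(failed.sum())
    df = df.loc[~failed]

    non_auto = ~df["chrom"].isin(AUTOSOMES)
    non_auto_snps = set(df.loc[non_auto, "snp_id"])
    for snp in non_auto_snps:
        report.dropped[snp] = "non-autosomal"
    report.n_non_autosomal = len(non_auto_snps)
    df = df.loc[~df["snp_id"].isin(non_auto_snps)]

    reps = df.groupby(["snp_id", "pool"], sort=False).size().unstack(fill_value=0)
    for pool in ("case", "control"):
        if pool not in reps.columns:
            reps[pool] = 0
    low = reps.index[(reps["case"] < min_replicates) | (reps["control"] < min_replicates)]
    for snp in low:
        report.dropped[snp] = "insufficient replicates"
    report.n_insufficient_replicates = len(low)
    df = df.loc[~df["snp_id"].isin(set(low))]

    report.n_snps_out = df["snp_id"].nunique()
    return PooledIntensityTable(df.reset_index(drop=True)), report


def summarize_pools(
    table: PooledIntensityTable, n_case: int, n_control: int
) -> pd.DataFrame:
    """Per-SNP RAF summary: mean, replicate count, v_k and eps_k^2 per pool.

    Index: snp_id.  Columns: chrom, pos, f1/f2 (case/control mean RAF),
    n1/n2 (replicates), v1/v2 (binomial sampling variance over 2N
    chromosomes), eps2_1/eps2_2 (squared standard error of the mean).
    Requires >= 2 replicates per pool (guaranteed after QC at the default
    minimum of 3).
    """
    df = table.data.copy()
    df["raf"] = compute_raf(df["green_raw"].to_numpy(), df["red_raw"].to_numpy())
    df = df.dropna(subset=["raf"])

    g = df.groupby(["snp_id", "pool"])["raf"]
    mean = g.mean().unstack()
    count = g.count().unstack()
    # eps^2 = sample variance / n = sum((f_i - fbar)^2) / (n (n-1))
    var = g.var(ddof=1).unstack()

    for pool in ("case", "control"):
        if pool not in mean.columns:
            raise ValueError(f"pool '{pool}' absent from intensity table")
    if (count < 2).any().any():
        bad = count.index[(count < 2).any(axis=1)][0]
        raise ValueError(f"SNP {bad}: fewer than 2 replicates; eps^2 undefined")

    meta = df.groupby("snp_id")[["chrom", "pos"]].first()
    summary = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "f1": mean["case"],
            "f2": mean["control"],
            "n1": count["case"].astype(int),
            "n2": count["control"].astype(int),
            "N1": n_case,
            "N2": n_control,
        }
    )
    summary["v1"] = summary["f1"] * (1.0 - summary["f1"]) / (2.0 * n_case)
    summary["v2"] = summary["f2"] * (1.0 - summary["f2"]) / (2.0 * n_control)
    summary["eps2_1"] = var["case"] / count["case"]
    summary["eps2_2"] = var["control"] / count["control"]
    summary.index.name = "snp_id"
    # preserve input SNP order
    order = table.data["snp_id"].drop_duplicates()
    return summary.loc[order[order.isin(summary.index)]]


def combined_z_test(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP T1, T_comb, Z and chi-square(1) p-value from a RAF summary.

    Degenerate SNPs whose four variance terms are all zero get p = 1 when
    the pool means agree, and the smallest representable p (flagged) when
    they differ.  Symmetric under pool exchange: T1 and T_comb are
    invariant, Z and delta_raf change sign.
    """
    delta = summary["f1"] - summary["f2"]
    v_sum = summary["v1"] + summary["v2"]
    eps_sum = summary["eps2_1"] + summary["eps2_2"]

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(v_sum > 0, delta**2 / v_sum, np.where(delta == 0, 0.0, np.inf))
        tcomb = np.where(
            v_sum + eps_sum > 0,
            delta**2 / (v_sum + eps_sum),
            np.where(delta == 0, 0.0, np.inf),
        )
        z = np.where(eps_sum > 0, delta / np.sqrt(eps_sum), np.where(delta == 0, 0.0, np.nan))

    p = stats.chi2.sf(tcomb, df=1)
    flagged = ~np.isfinite(tcomb)
    p = np.where(flagged, P_FLOOR, p)

    out = pd.DataFrame(
        {
            "snp_id": summary.index,
            "chrom": summary["chrom"].to_numpy(),
            "pos": summary["pos"].to_numpy(),
            "t1": t1,
            "tcomb": tcomb,
            "z": z,
            "p_value": p,
            "delta_raf": delta.to_numpy(),
            "flagged_infinite": flagged,
        }
    ).reset_index(drop=True)
    out["genomewide"] = out["p_value"] < GENOMEWIDE_ALPHA
    return out


def genomewide_hits(results: pd.DataFrame, alpha: float = GENOMEWIDE_ALPHA) -> pd.DataFrame:
    """SNPs with p strictly below the genome-wide line, sorted ascending by p."""
    hits = results.loc[results["p_value"] < alpha]
    return hits.sort_values("p_value", kind="stable").reset_index(drop=True)


def qq_points(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) pairs for a quantile-quantile plot.

    Expected quantiles are -log10((i - 0.5)/m) for rank i of m; observed
    values are the sorted -log10(p).  p = 0 is clamped to the smallest
    positive float (with a warning via numpy); p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return pd.DataFrame({"expected": [], "observed": []})
    p = np.where(p <= 0, P_FLOOR, p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.sort(p))  # descending, matching expected
    return pd.DataFrame({"expected": expected, "observed": observed})


def manhattan_points(
    results: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Cumulative genome coordinate and -log10(p) per SNP.

    ``chrom_lengths`` supplies chromosome sizes for the cumulative offset;
    by default the largest observed position per chromosome is used.
    """
    df = results.copy()
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom")["pos"].max().to_dict()
    order = [c for c in AUTOSOMES if c in set(df["chrom"])]
    offsets = {}
    cum = 0
    for c in order:
        offsets[c] = cum
        cum += int(chrom_lengths[c])
    df = df.loc[df["chrom"].isin(offsets)]
    coord = df["pos"].to_numpy() + np.array([offsets[c] for c in df["chrom"]])
    p = np.where(df["p_value"].to_numpy() <= 0, P_FLOOR, df["p_value"].to_numpy())
    return pd.DataFrame(
        {
            "snp_id": df["snp_id"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "genome_coord": coord,
            "neg_log10_p": -np.log10(p),
        }
    )


def raf_correlation(case_raf, control_raf) -> float:
    """Squared Pearson correlation between case and control mean RAFs."""
    x = np.asarray(case_raf, dtype=float)
    y = np.asarray(control_raf, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
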