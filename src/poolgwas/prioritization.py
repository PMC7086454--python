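"""Post-GWAS hit annotation: odds ratios from pooled frequencies, FPRP,
SNP-to-gene mapping and gene-level selection.

The false-positive report probability (FPRP) is the posterior probability
that a reported association is a false positive, given the observed
p-value, the study's power to detect a stated alternative odds ratio, and a
prior probability that the association is real:

    FPRP = p (1 - pi) / [ p (1 - pi) + (1 - beta) pi ]

with power 1 - beta = Phi( ln(OR_alt)/SE(ln OR) - z_{1-p/2} ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

WINDOW_BP = 20_000
GENESET_ALPHA = 1.0e-5
#: default priors at which FPRP is reported, and the alternative OR at which
#: power is evaluated
FPRP_PRIORS = (0.25, 0.1, 0.01, 0.001)
FPRP_OR_ALT = 1.5


@dataclass
class OddsRatioEstimate:
    or_: float
    ci_low: float
    ci_high: float
    se_log_or: float


def or_from_raf(f1: float, f2: float, n1: int, n2: int) -> OddsRatioEstimate:
    """Allelic odds ratio and 95% CI from pooled mean RAFs.

    OR = f1(1-f2) / [f2(1-f1)]; the standard error of ln(OR) uses the
    allele-count approximation from the pooled frequencies:
    SE = sqrt(1/(2 N1 f1 (1-f1)) + 1/(2 N2 f2 (1-f2))).
    """
    for name, f in (("f1", f1), ("f2", f2)):
        if not 0.0 < f < 1.0:
            raise ValueError(
                f"{name}={f} lies on the boundary; apply a continuity "
                "correction upstream before computing an odds ratio"
            )
    or_ = (f1 * (1.0 - f2)) / (f2 * (1.0 - f1))
    se = np.sqrt(
        1.0 / (2.0 * n1 * f1 * (1.0 - f1)) + 1.0 / (2.0 * n2 * f2 * (1.0 - f2))
    )
    log_or = np.log(or_)
    return OddsRatioEstimate(
        or_=float(or_),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        se_log_or=float(se),
    )


def fprp(
    p_value: float,
    se_log_or: float,
    prior_pi: float,
    or_alt: float = FPRP_OR_ALT,
) -> float:
    """False-positive report probability for one association."""
    if not 0.0 <= prior_pi <= 1.0:
        raise ValueError("prior_pi must be in [0, 1]")
    if or_alt <= 0:
        raise ValueError("or_alt must be > 0")
    if se_log_or <= 0:
        raise ValueError("se_log_or must be > 0")
    z_crit = stats.norm.isf(p_value / 2.0)
    power = stats.norm.cdf(np.log(or_alt) / se_log_or - z_crit)
    power = min(max(float(power), 0.0), 1.0)
    num = p_value * (1.0 - prior_pi)
    den = num + power * prior_pi
    if den == 0.0:
        return 1.0  # limit convention: no power, no prior mass on truth
    return float(num / den)


def map_snps_to_genes(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Assign SNPs to genes within a window, else to the nearest flanks.

    ``snps`` needs columns snp_id, chrom, pos (1-based) and optionally
    p_value; ``annotation`` is the sorted 1-based gene table from
    :func:`poolgwas.io_formats.read_gene_annotation`.

    A gene whose span, widened by ``window_bp`` on each side (closed
    interval: a gene ending exactly ``window_bp`` away is included), covers
    the SNP is assigned with relation 'within_window'; all such genes are
    kept.  If none qualifies, the nearest gene on each side is assigned with
    relation 'nearest_flank' (ties within a side broken by smaller start,
    then symbol).  SNPs on chromosomes absent from the annotation are left
    unassigned with a warning.
    """
    rows = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in annotation.groupby("chrom")}
    for snp in snps.itertuples(index=False):
        genes = by_chrom.get(snp.chrom)
        p_value = getattr(snp, "p_value", np.nan)
        if genes is None or genes.empty:
            logger.warning(
                "SNP %s: chromosome %s absent from annotation; unassigned",
                snp.snp_id, snp.chrom,
            )
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        within = (start - window_bp <= snp.pos) & (snp.pos <= end + window_bp)
        if within.any():
            for idx in np.flatnonzero(within):
                dist = 0
                if snp.pos < start[idx]:
                    dist = int(start[idx] - snp.pos)
                elif snp.pos > end[idx]:
                    dist = int(snp.pos - end[idx])
                rows.append(
                    (snp.snp_id, snp.chrom, snp.pos,
                     genes.loc[idx, "gene_symbol"], "within_window", dist, p_value)
                )
            continue
        # gene desert: nearest gene on each side
        for side_mask, gap in (
            (end < snp.pos, snp.pos - end),
            (start > snp.pos, start - snp.pos),
        ):
            if not side_mask.any():
                continue
            gaps = np.where(side_mask, gap, np.iinfo(np.int64).max)
            best = gaps.min()
            cand = genes.loc[np.flatnonzero(gaps == best)]
            cand = cand.sort_values(["start", "gene_symbol"], kind="stable")
            rows.append(
                (snp.snp_id, snp.chrom, snp.pos,
                 cand.iloc[0]["gene_symbol"], "nearest_flank", int(best), p_value)
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "gene_symbol", "relation", "distance_bp", "p_value"],
    )


def gene_label(assignments: pd.DataFrame, snp_id: str) -> str:
    """Report label for one SNP's genes, slash-joined (e.g. 'SYN3/TIMP3')."""
    symbols = assignments.loc[assignments["snp_id"] == snp_id, "gene_symbol"]
    return "/".join(symbols.tolist())


def gene_level_best(assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse SNP-gene assignments to one record per gene at minimum p.

    When several SNPs map to a gene the smallest p-value wins; ties are
    broken by smaller position.  A SNP shared by several genes contributes
    its p-value to each of them.
    """
    df = assignments.sort_values(["p_value", "pos"], kind="stable")
    best = df.groupby("gene_symbol", sort=False).first().reset_index()
    return best[["gene_symbol", "snp_id", "chrom", "pos", "p_value"]]


def select_gene_set(gene_records: pd.DataFrame, alpha: float = GENESET_ALPHA) -> list[str]:
    """Genes with p strictly below ``alpha``, ordered by ascending p."""
    sel = gene_records.loc[gene_records["p_value"] < alpha]
    sel = sel.sort_values("p_value", kind="stable")
    return sel["gene_symbol"].tolist()
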