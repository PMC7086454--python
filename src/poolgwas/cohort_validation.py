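"""Validation-cohort statistics for individually genotyped subjects.

Covers the second study stage: Hardy-Weinberg equilibrium checks, 2x3
genotype association between groups, allelic odds ratios with Woolf
confidence intervals (Haldane-Anscombe correction for empty cells),
genotype-frequency reporting, glucocorticoid-response classification, and
per-timepoint platelet-count comparison between genotype groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeCohort

logger = logging.getLogger(__name__)

#: platelet thresholds (1e9/L) for glucocorticoid-response categories
COMPLETE_RESPONSE_PLT = 100.0
RESPONSE_PLT_MIN = 30.0

RESPONSE_CATEGORIES = ("complete_response", "response", "nonresponse")


def genotype_counts(
    cohort: GenotypeCohort, snp_id: str, groups: tuple[str, str] | None = None
) -> dict[str, tuple[int, int, int]]:
    """Collapse one SNP to per-group (n0, n1, n2) dosage counts.

    Missing dosages are excluded per SNP (pairwise), not per subject.
    ``groups`` restricts and orders the group labels; default is the sorted
    labels present.
    """
    if snp_id not in cohort.genotypes.columns:
        raise KeyError(f"unknown snp_id: {snp_id}")
    dosage = cohort.genotypes[snp_id]
    labels = cohort.group
    if groups is None:
        groups = tuple(sorted(labels.unique()))
    out = {}
    for g in groups:
        d = dosage[(labels == g) & dosage.notna()].astype(int)
        out[g] = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
    return out


def hwe_test(n0: int, n1: int, n2: int, method: str = "chi2") -> tuple[float, float]:
    """Hardy-Weinberg equilibrium test on (n0, n1, n2) dosage counts.

    ``method='chi2'`` (default): 1-df goodness of fit of observed counts to
    (n(1-q)^2, 2nq(1-q), nq^2) at the sample allele frequency
    q = (n1 + 2 n2)/(2n).  An expected cell of 0 with observed 0 contributes
    nothing.  A monomorphic sample (q in {0,1}) fits trivially: (0, 1).

    ``method='exact'``: conditional exact test — the two-sided
    probability-ordering p-value over heterozygote counts given the minor
    allele count (chi2 is returned as NaN).
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one subject")
    q = (n1 + 2 * n2) / (2.0 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    if method == "exact":
        return float("nan"), _hwe_exact_p(n0, n1, n2)
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q * q])
    observed = np.array([n0, n1, n2], dtype=float)
    mask = ~((expected == 0) & (observed == 0))
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p-value: sum of heterozygote configurations no more
    probable than the observed one, conditional on the allele counts
    (Levene's conditional distribution)."""
    from math import lgamma, log

    n = n0 + n1 + n2
    n_minor = n1 + 2 * n2

    def log_prob(het: int) -> float:
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        if hom_minor < 0 or hom_major < 0:
            return -np.inf
        return (
            lgamma(n + 1)
            - lgamma(hom_major + 1) - lgamma(het + 1) - lgamma(hom_minor + 1)
            + het * log(2)
            + lgamma(n_minor + 1) + lgamma(2 * n - n_minor + 1) - lgamma(2 * n + 1)
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    probs = {h: float(np.exp(log_prob(h))) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n1] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= p_obs + 1e-12))


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability (for df=2 equals exp(-x/2))."""
    if x < 0 or df < 1:
        raise ValueError("need x >= 0 and df >= 1")
    return float(stats.chi2.sf(x, df))


def genotype_assoc_2x3(
    case_counts: tuple[int, int, int], control_counts: tuple[int, int, int]
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2 x genotype contingency table.

    Genotype columns with zero total are dropped first (e.g. no dosage-2
    subjects anywhere collapses the table to 2x2, df=1).  Returns
    (chi2, df, p).
    """
    table = np.array([case_counts, control_counts], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("degenerate table: only one genotype class present")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a group has no subjects")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class AllelicOR:
    or_: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    haldane_applied: bool = False


def allelic_or(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
    correction: str = "zero-cell",
) -> AllelicOR:
    """Allelic (allele-count) odds ratio with Woolf 95% CI.

    Minor-allele counts a (cases) and c (controls) are n1 + 2*n2; major
    counts b, d are 2*n0 + n1.  ``correction`` controls the
    Haldane-Anscombe +0.5: 'zero-cell' (default) adds it to all four cells
    only when some cell is zero; 'always' is the Gart smoothed estimator,
    nearly unbiased for ln(OR) at rare-allele counts and used by the
    simulator-recovery checks; 'none' never corrects (raises on a zero
    cell).  The allelic chi-square always uses the uncorrected 2x2 table.
    """
    a = case_counts[1] + 2 * case_counts[2]
    b = 2 * case_counts[0] + case_counts[1]
    c = control_counts[1] + 2 * control_counts[2]
    d = 2 * control_counts[0] + control_counts[1]
    if a == 0 and c == 0:
        raise ValueError("minor allele absent from both groups; OR undefined")
    cells = np.array([a, b, c, d], dtype=float)
    has_zero = bool((cells == 0).any())
    if correction == "always":
        haldane = True
    elif correction == "zero-cell":
        haldane = has_zero
    elif correction == "none":
        if has_zero:
            raise ValueError("zero cell with correction='none'")
        haldane = False
    else:
        raise ValueError(f"unknown correction: {correction}")
    if haldane:
        if has_zero:
            logger.info("allelic_or: zero cell; Haldane-Anscombe +0.5 applied")
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log(or_)
    chi2, _, p = _pearson_2x2(a, b, c, d)
    return AllelicOR(
        or_=float(or_),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        chi2=chi2,
        p=p,
        haldane_applied=haldane,
    )


def _pearson_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    table = np.array([[a, b], [c, d]], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 0, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def genotype_frequencies(counts: tuple[int, int, int]) -> tuple[float, ...]:
    """Genotype percentages rounded half-up to one decimal place."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    return tuple(
        float(Decimal(100 * n / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        for n in counts
    )


def classify_response(baseline_plt: float, post_plt: float, rule: str = "strict") -> str:
    """Glucocorticoid-response category from baseline and post-treatment
    platelet counts (1e9/L).

    * complete_response: post > 100;
    * response: post >= 30 AND post >= 2x baseline (default 'strict' rule);
    * nonresponse: otherwise.

    ``rule='inclusive'`` uses the alternative reading in which reaching
    30-100 OR doubling suffices for a partial response.
    """
    if baseline_plt < 0 or post_plt < 0:
        raise ValueError("platelet counts must be >= 0")
    if post_plt > COMPLETE_RESPONSE_PLT:
        return "complete_response"
    doubled = post_plt >= 2.0 * baseline_plt
    in_range = RESPONSE_PLT_MIN <= post_plt <= COMPLETE_RESPONSE_PLT
    if rule == "strict":
        responded = post_plt >= RESPONSE_PLT_MIN and doubled
    elif rule == "inclusive":
        responded = in_range or doubled
    else:
        raise ValueError(f"unknown rule: {rule}")
    return "response" if responded else "nonresponse"


def response_assoc(
    response_counts: tuple[int, int, int], nonresponse_counts: tuple[int, int, int]
) -> tuple[float, int, float]:
    """Genotype association between response and nonresponse groups."""
    return genotype_assoc_2x3(response_counts, nonresponse_counts)


def timepoint_compare(
    series_a: pd.DataFrame, series_b: pd.DataFrame, days: list | None = None
) -> pd.DataFrame:
    """Welch t-test of platelet counts between two groups at each timepoint.

    ``series_a``/``series_b`` are subjects x days frames with ``day_<d>``
    columns.  Zero variance in both groups with equal means yields p = 1.
    Output columns: day, mean_a, mean_b, t, p, sig_05, sig_01.
    """
    cols = [f"day_{d}" for d in days] if days is not None else list(series_a.columns)
    rows = []
    for col in cols:
        a = series_a[col].dropna().to_numpy(dtype=float)
        b = series_b[col].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{col}: need >= 2 subjects per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        day = int(col.removeprefix("day_"))
        rows.append((day, float(a.mean()), float(b.mean()), t, p, p < 0.05, p < 0.01))
    return pd.DataFrame(
        rows, columns=["day", "mean_a", "mean_b", "t", "p", "sig_05", "sig_01"]
    )
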