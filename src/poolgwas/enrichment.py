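"""Hypergeometric over-representation of a gene set against pathway sets.

For a study set of n genes drawn from a reference universe of N genes, a
pathway containing K of the N genes is expected to contribute K*n/N study
genes; over-representation is the exact upper tail P(X >= k_obs) of
Hypergeom(N, K, n).  The enrichment ratio (E-ratio) is observed/expected.
Benjamini-Hochberg step-up adjustment controls the FDR across pathways; the
total test count m may be overridden when the analysis reproduces results
from a run whose category count is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PathwayDB


@dataclass
class EnrichmentResult:
    pathway_name: str
    total: int           # K: reference genes in the category
    observed: int        # k_obs: study-set genes in the category
    expected: float      # K * n / N
    e_ratio: float
    p_hyper: float
    adj_p: float | None = None


def hypergeometric_overrep(
    study_set, pathway_set, reference_size: int, pathway_name: str = ""
) -> EnrichmentResult:
    """Exact one-sided over-representation of ``study_set`` in ``pathway_set``."""
    study = set(study_set)
    pathway = set(pathway_set)
    n = len(study)
    big_k = len(pathway)
    big_n = int(reference_size)
    if big_n < max(n, big_k):
        raise ValueError("reference_size smaller than study or pathway set")
    k_obs = len(study & pathway)
    assert k_obs <= min(big_k, n)
    # P(X >= k_obs) with X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k_obs - 1, big_n, big_k, n))
    p = min(p, 1.0)
    expected = big_k * n / big_n if big_n > 0 else 0.0
    e_ratio = k_obs / expected if expected > 0 else np.nan
    return EnrichmentResult(
        pathway_name=pathway_name,
        total=big_k,
        observed=k_obs,
        expected=expected,
        e_ratio=e_ratio,
        p_hyper=p,
    )


def bh_adjust(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m_total`` overrides the number of tests (must be at least the number
    of p-values supplied); adj(i) = min over j >= i of min(1, p(j)*m/j) on
    the ascending-sorted list.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total ({m}) smaller than the number of p-values ({p.size})")
    if p.size == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    return adj


def enrich_all(
    study_set, db: PathwayDB, m_total: int | None = None
) -> pd.DataFrame:
    """Over-representation of ``study_set`` against every pathway in ``db``.

    BH adjustment runs over the pathways with at least one observed
    study-set gene; by default m_total is that count.  Pathways with no
    overlap keep p_hyper (=1) as adj_p.  Output sorted by raw p.
    """
    results = [
        hypergeometric_overrep(study_set, genes, db.reference_size, pathway_name=name)
        for name, genes in db.pathways.items()
    ]
    df = pd.DataFrame(
        {
            "pathway_name": [r.pathway_name for r in results],
            "total": [r.total for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "e_ratio": [r.e_ratio for r in results],
            "p_hyper": [r.p_hyper for r in results],
        }
    )
    tested = df["observed"] >= 1
    df["adj_p"] = df["p_hyper"]
    if tested.any():
        m = int(tested.sum()) if m_total is None else int(m_total)
        df.loc[tested, "adj_p"] = bh_adjust(df.loc[tested, "p_hyper"].to_numpy(), m_total=m)
    return df.sort_values("p_hyper", kind="stable").reset_index(drop=True)
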