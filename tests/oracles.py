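"""Independent, deliberately naive reference implementations used only to
cross-check the package.  Pure-python `math` throughout; no shared code with
the implementation under test."""

import math


def combined_z_oracle(f1, f2, n_case, n_control, eps2_1, eps2_2):
    """Plain transcription of the pooled-test definitions:
    v_k = fk(1-fk)/(2Nk); T1 = d^2/(v1+v2); Tcomb = d^2/(v1+v2+e1+e2);
    Z = d/sqrt(e1+e2)."""
    v1 = f1 * (1 - f1) / (2 * n_case)
    v2 = f2 * (1 - f2) / (2 * n_control)
    d = f1 - f2
    t1 = d * d / (v1 + v2)
    tcomb = d * d / (v1 + v2 + eps2_1 + eps2_2)
    z = d / math.sqrt(eps2_1 + eps2_2)
    return t1, tcomb, z


def mean_and_eps2(replicates):
    """f-bar and eps^2 = sum (f_i - fbar)^2 / (n(n-1)) by direct summation."""
    n = len(replicates)
    fbar = sum(replicates) / n
    ss = sum((f - fbar) ** 2 for f in replicates)
    return fbar, ss / (n * (n - 1))


def norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def norm_sf(x):
    # erfc keeps full relative precision in the upper tail
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def norm_isf(p):
    """Upper-tail inverse normal by bisection on the survival function."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if norm_sf(mid) > p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def fprp_oracle(p_value, se_log_or, prior_pi, or_alt):
    power = norm_cdf(math.log(or_alt) / se_log_or - norm_isf(p_value / 2.0))
    power = min(max(power, 0.0), 1.0)
    num = p_value * (1.0 - prior_pi)
    den = num + power * prior_pi
    return 1.0 if den == 0 else num / den


def pearson_chi2_oracle(table):
    """r x c Pearson chi-square by explicit expected counts."""
    rows = len(table)
    cols = len(table[0])
    row_tot = [sum(table[i]) for i in range(rows)]
    col_tot = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    grand = sum(row_tot)
    chi2 = 0.0
    for i in range(rows):
        for j in range(cols):
            e = row_tot[i] * col_tot[j] / grand
            if e > 0:
                chi2 += (table[i][j] - e) ** 2 / e
    df = (rows - 1) * (cols - 1)
    return chi2, df


def hypergeom_upper_tail(k_obs, big_n, big_k, n):
    """P(X >= k_obs) by full enumeration with math.comb."""
    denom = math.comb(big_n, n)
    total = 0
    for k in range(k_obs, min(big_k, n) + 1):
        total += math.comb(big_k, k) * math.comb(big_n - big_k, n - k)
    return total / denom


def bh_oracle(p_values, m_total):
    """BH step-up by the textbook definition, quadratic scan."""
    idx = sorted(range(len(p_values)), key=lambda i: p_values[i])
    adj = [None] * len(p_values)
    for rank_i, i in enumerate(idx, start=1):
        best = min(
            min(1.0, p_values[j] * m_total / rank_j)
            for rank_j, j in enumerate(idx, start=1)
            if rank_j >= rank_i
        )
        adj[i] = best
    return adj
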