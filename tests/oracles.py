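"""Independent brute-force implementations used as test oracles.

Everything here is written from first principles (explicit loops, exact
combinatorics) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def welch_oracle(a, b):
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist  # p-value needs the t CDF

    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def bh_oracle(p_values):
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def hypergeom_pmf_exact(k, r1, r2, c1):
    """P(X = k) for a 2x2 table with row sums r1, r2 and column sum c1."""
    if k < max(0, c1 - r2) or k > min(r1, c1):
        return 0.0
    return (math.comb(r1, k) * math.comb(r2, c1 - k)
            / math.comb(r1 + r2, c1))


def fisher_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf_exact(a, r1, r2, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = hypergeom_pmf_exact(k, r1, r2, c1)
        if pk <= p_obs * (1.0 + 1e-7):  # same tie convention as scipy
            total += pk
    return min(total, 1.0)


def chisq_2x2_oracle(table):
    t = [[float(v) for v in row] for row in table]
    n = sum(sum(row) for row in t)
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            exp = sum(t[i]) * (t[0][j] + t[1][j]) / n
            chi2 += (t[i][j] - exp) ** 2 / exp
    from scipy.stats import chi2 as chi2dist

    return chi2, float(chi2dist.sf(chi2, 1))


def pearson_oracle(x, y):
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sx = math.sqrt(sum((v - mx) ** 2 for v in x))
    sy = math.sqrt(sum((v - my) ** 2 for v in y))
    r = cov / (sx * sy)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    from scipy.stats import t as tdist

    return r, 2.0 * tdist.sf(abs(t), n - 2)


def km_oracle(times, events):
    """Product-limit estimate: (event_times, survival) by explicit loop."""
    pairs = sorted(zip(map(float, times), map(int, events)))
    n = len(pairs)
    out_t, out_s = [], []
    s = 1.0
    i = 0
    while i < n:
        t0 = pairs[i][0]
        d = sum(1 for t, e in pairs if t == t0 and e == 1)
        at_risk = sum(1 for t, _ in pairs if t >= t0)
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(t0)
            out_s.append(s)
        while i < n and pairs[i][0] == t0:
            i += 1
    return out_t, out_s


def logrank_oracle(groups, times, events, strata=None):
    """Two-group log-rank chi-square by explicit risk-set bookkeeping."""
    groups = list(groups)
    times = list(map(float, times))
    events = list(map(int, events))
    strata = [0] * len(times) if strata is None else list(strata)
    levels = sorted(set(groups))
    assert len(levels) == 2
    ome = 0.0
    var = 0.0
    for s in sorted(set(strata)):
        idx = [i for i in range(len(times)) if strata[i] == s]
        for t0 in sorted({times[i] for i in idx if events[i] == 1}):
            at_risk = [i for i in idx if times[i] >= t0]
            n = len(at_risk)
            n1 = sum(1 for i in at_risk if groups[i] == levels[0])
            d = sum(1 for i in at_risk if times[i] == t0 and events[i] == 1)
            d1 = sum(1 for i in at_risk
                     if times[i] == t0 and events[i] == 1
                     and groups[i] == levels[0])
            ome += d1 - d * n1 / n
            if n > 1:
                var += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    from scipy.stats import chi2 as chi2dist

    chi2 = ome ** 2 / var if var > 0 else 0.0
    return chi2, float(chi2dist.sf(chi2, 1))


def mann_whitney_auc(marker, positive):
    """Empirical AUC of `marker` for the binary labels, ties count 0.5."""
    marker = list(map(float, marker))
    positive = list(map(bool, positive))
    pos = [m for m, y in zip(marker, positive) if y]
    neg = [m for m, y in zip(marker, positive) if not y]
    total = 0.0
    for mp in pos:
        for mn in neg:
            if mp > mn:
                total += 1.0
            elif mp == mn:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumerate_null_rank_products(n_genes, k):
    """Exhaustively enumerate all (n_genes!)^k null rank configurations.

    Returns an array of shape (n_configurations, n_genes) holding each
    configuration's per-gene rank-product value, computed as the geometric
    mean of the gene's ranks. Every permutation draw of the estimator under
    test is a uniform sample from these rows, so moments over the rows are
    the exact expectation of the permutation scheme.
    """
    import itertools

    base = list(range(1, n_genes + 1))
    rows = []
    for cfgs in itertools.product(itertools.permutations(base), repeat=k):
        ranks = np.array(cfgs, dtype=float)  # k x n_genes
        rows.append(np.exp(np.mean(np.log(ranks), axis=0)))
    return np.array(rows)
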