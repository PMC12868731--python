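"""Independent, deliberately naive reference implementations.

Everything here is coded straight from the defining formulas with explicit
Python loops, independent of the package's vectorized implementations, and is
used only to generate expected values in tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ssgsea_es_bruteforce(expr_col, gene_ids, members, alpha):
    """Enrichment score of one sample by the literal running-sum definition."""
    G = len(gene_ids)
    # descending expression, ties broken by input order (stable)
    order = sorted(range(G), key=lambda i: (-expr_col[i], i))
    in_set = [gene_ids[i] in members for i in order]
    rho = [G - pos for pos in range(G)]  # ascending-expression rank, top gene = G
    weights = [rho[pos] ** alpha if in_set[pos] else 0.0 for pos in range(G)]
    total_w = sum(weights)
    n_out = G - sum(in_set)
    es = 0.0
    cum_w = 0.0
    cum_out = 0
    for pos in range(G):
        if in_set[pos]:
            cum_w += weights[pos]
        else:
            cum_out += 1
        es += cum_w / total_w - cum_out / n_out
    return es


def tmm_factors_oracle(counts: np.ndarray):
    """TMM factors computed from the definition (30%/5% double trim,
    inverse-asymptotic-variance weights, upper-quartile reference,
    geometric-mean-1 rescale)."""
    G, S = counts.shape
    lib = [sum(counts[g][j] for g in range(G)) for j in range(S)]
    uq = [np.quantile([counts[g][j] / lib[j] for g in range(G)], 0.75) * 1e6
          for j in range(S)]
    mean_uq = sum(uq) / S
    ref = min(range(S), key=lambda j: abs(uq[j] - mean_uq))

    def rank_avg(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and values[order[j]] == values[order[i]]:
                j += 1
            avg = (i + 1 + j) / 2.0
            for t in range(i, j):
                ranks[order[t]] = avg
            i = j
        return ranks

    factors = []
    for j in range(S):
        if j == ref:
            factors.append(1.0)
            continue
        m, a, w = [], [], []
        for g in range(G):
            y, yr = counts[g][j], counts[g][ref]
            if y > 0 and yr > 0:
                p, pr = y / lib[j], yr / lib[ref]
                m.append(math.log2(p / pr))
                a.append(0.5 * math.log2(p * pr))
                w.append((lib[j] - y) / (lib[j] * y)
                         + (lib[ref] - yr) / (lib[ref] * yr))
        n = len(m)
        if n == 0:
            factors.append(1.0)
            continue
        rm, ra = rank_avg(m), rank_avg(a)
        lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        num = den = 0.0
        kept = 0
        for g in range(n):
            if lo_m <= rm[g] <= hi_m and lo_a <= ra[g] <= hi_a:
                num += m[g] / w[g]
                den += 1.0 / w[g]
                kept += 1
        factors.append(2.0 ** (num / den) if kept else 1.0)
    log_mean = sum(math.log(f) for f in factors) / S
    return [f / math.exp(log_mean) for f in factors], ref


def log_cpm_oracle(counts: np.ndarray, factors, prior_count):
    """log2 CPM with the library-size-scaled prior count, elementwise."""
    G, S = counts.shape
    lib = [sum(counts[g][j] for g in range(G)) for j in range(S)]
    eff = [lib[j] * factors[j] for j in range(S)]
    mean_eff = sum(eff) / S
    out = np.zeros((G, S))
    for j in range(S):
        pc = prior_count * eff[j] / mean_eff
        for g in range(G):
            out[g, j] = math.log2((counts[g][j] + pc) / (eff[j] + 2 * pc) * 1e6)
    return out


def bh_oracle(p):
    """Step-up Benjamini-Hochberg by the textbook recursion."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def km_oracle(times, events):
    """Product-limit estimate as (event_time, survival) pairs."""
    pairs = sorted(zip(times, events))
    n = len(pairs)
    out = []
    surv = 1.0
    i = 0
    while i < n:
        t = pairs[i][0]
        at_risk = n - i
        d = 0
        j = i
        while j < n and pairs[j][0] == t:
            d += pairs[j][1]
            j += 1
        if d:
            surv *= 1 - d / at_risk
            out.append((t, surv))
        i = j
    return out


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square by explicit O/E/V summation."""
    t = list(times_a) + list(times_b)
    e = list(events_a) + list(events_b)
    g = [0] * len(times_a) + [1] * len(times_b)
    event_times = sorted({tt for tt, ee in zip(t, e) if ee})
    o = ex = v = 0.0
    for tt in event_times:
        n_risk = sum(1 for x in t if x >= tt)
        n1 = sum(1 for x, gg in zip(t, g) if x >= tt and gg == 0)
        d = sum(1 for x, ee in zip(t, e) if x == tt and ee)
        d1 = sum(1 for x, ee, gg in zip(t, e, g) if x == tt and ee and gg == 0)
        o += d1
        ex += d * n1 / n_risk
        if n_risk > 1:
            v += d * (n1 / n_risk) * (1 - n1 / n_risk) * (n_risk - d) / (n_risk - 1)
    return (o - ex) ** 2 / v


def bray_curtis_oracle(p, q):
    num = 2 * sum(min(a, b) for a, b in zip(p, q))
    den = sum(p) + sum(q)
    return 1 - num / den


def permanova_f_oracle(d, groups):
    """Pseudo-F from squared distances (definition form)."""
    n = len(groups)
    labels = sorted(set(groups))
    a = len(labels)
    ss_total = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for lab in labels:
        idx = [i for i in range(n) if groups[i] == lab]
        ss_within += sum(
            d[i][j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_oracle(d, groups):
    """Exhaustive-permutation p-value: fraction of distinct label
    arrangements with pseudo-F >= observed (identity included)."""
    n = len(groups)
    f_obs = permanova_f_oracle(d, groups)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(range(n)):
        arr = tuple(groups[i] for i in perm)
        if arr in seen:
            continue
        seen.add(arr)
        total += 1
        if permanova_f_oracle(d, list(arr)) >= f_obs - 1e-12:
            count += 1
    return count / total, f_obs


def wilcoxon_signflip_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Ranks of |d| (average ties), statistic = min(W+, W-); p = fraction of the
    2^n sign assignments with min(W+, W-) <= observed.
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    absd = [abs(x) for x in d]
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[order[j]] == absd[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[order[t]] = avg
        i = j
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    w_minus = sum(r for r, x in zip(ranks, d) if x < 0)
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        wm = sum(ranks) - wp
        if min(wp, wm) <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2**n
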