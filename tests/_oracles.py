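"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions (pair enumeration, direct
summation, step-up rules) and deliberately shares no code with the
package, so agreement is a real cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def weighted_mse_loop(y, yhat):
    total = 0.0
    for yi, yh in zip(y, yhat):
        total += yi * (yi - yh) ** 2
    return total


def gini_pairwise(x):
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    s = 0.0
    for a in x:
        for b in x:
            s += abs(a - b)
    return s / (2 * n * n * mu)


def pair_counts(a, b):
    """(together-in-both, together-A-only, together-B-only, neither)."""
    tp = fa = fb = tn = 0
    for i, j in combinations(range(len(a)), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        if sa and sb:
            tp += 1
        elif sa:
            fa += 1
        elif sb:
            fb += 1
        else:
            tn += 1
    return tp, fa, fb, tn


def ari_pairs(a, b):
    tp, fa, fb, tn = pair_counts(a, b)
    denom = (tp + fa) * (fa + tn) + (tp + fb) * (fb + tn)
    if denom == 0:
        return 1.0
    return 2.0 * (tp * tn - fa * fb) / denom


def fmi_pairs(a, b):
    tp, fa, fb, _ = pair_counts(a, b)
    denom = math.sqrt((tp + fa) * (tp + fb))
    return tp / denom if denom > 0 else 0.0


def _contingency(a, b):
    ua = sorted(set(a))
    ub = sorted(set(b))
    table = np.zeros((len(ua), len(ub)), dtype=int)
    for x, y in zip(a, b):
        table[ua.index(x), ub.index(y)] += 1
    return table


def mutual_information(a, b):
    """Direct summation of sum_ij P(i,j) log(P(i,j) / (P(i) P(j)))."""
    table = _contingency(a, b)
    n = table.sum()
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij * n * n / (table[i].sum() * table[:, j].sum()))
    return mi


def entropy(labels):
    n = len(labels)
    h = 0.0
    for lab in set(labels):
        p = labels.count(lab) if isinstance(labels, list) else int(np.sum(np.asarray(labels) == lab))
        p = p / n
        h -= p * math.log(p)
    return h


def expected_mutual_information(a, b):
    """Exact EMI under the permutation (hypergeometric) model."""
    table = _contingency(a, b)
    n = int(table.sum())
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    emi = 0.0
    for ai in row:
        for bj in col:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * math.log(n * nij / (ai * bj))
                prob = (
                    math.comb(bj, nij)
                    * math.comb(n - bj, ai - nij)
                    / math.comb(n, ai)
                )
                emi += term * prob
    return emi


def ami_direct(a, b):
    """AMI with arithmetic-mean normalisation, from MI, EMI and entropies."""
    a = list(a)
    b = list(b)
    if len(set(a)) == len(set(b)) == 1:
        return 1.0
    mi = mutual_information(a, b)
    emi = expected_mutual_information(a, b)
    h = (entropy(a) + entropy(b)) / 2.0
    denom = h - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    p = list(map(float, pvals))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def ks_scan(x, y):
    """Max ECDF gap over the pooled sample points."""
    x = sorted(map(float, x))
    y = sorted(map(float, y))
    best = 0.0
    for t in x + y:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best
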