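"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — plain loops and textbook definitions —
kept free of any braintx internals so they can arbitrate correctness.
"""

import numpy as np


def bh_oracle(p_values):
    """Benjamini-Hochberg step-up, straight from the definition:
    q_(i) = min over j >= i of p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p[i] * m / (pos + 1))
        adjusted[i] = running_min
    return adjusted


def gsea_es_oracle(rho_sorted, member, weight_exponent):
    """Weighted KS running sum by explicit loop."""
    n = len(rho_sorted)
    m = int(member.sum())
    weights = np.abs(rho_sorted) ** weight_exponent
    total = weights[member].sum()
    curve = []
    s = 0.0
    for i in range(n):
        if member[i]:
            s += weights[i] / total if total > 0 else 1.0 / m
        else:
            s -= 1.0 / (n - m)
        curve.append(s)
    curve = np.array(curve)
    es = curve[int(np.argmax(np.abs(curve)))]
    return float(es), curve


def recovery_auc_oracle(ranks_of_set, n_total, auc_max_fraction):
    """Step-curve AUC by explicit x = 1..R loop."""
    R = int(np.ceil(auc_max_fraction * n_total))
    y_sum = 0
    for x in range(1, R + 1):
        y_sum += int(np.sum(np.asarray(ranks_of_set) <= x))
    return y_sum / (len(ranks_of_set) * R)


def spearman_oracle(x, y):
    """Pearson correlation of average ranks, via a naive rank assignment."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
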