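"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value from first principles (enumeration,
closed form, direct rule application) without calling the implementation
path it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import comb
from statistics import median

import numpy as np


def brute_force_hrd(records, focal: bool) -> dict:
    """Direct re-application of the five printed HRD criteria.

    ``records`` are (sv_type, size_bp_or_None) pairs; ``focal`` is taken as
    given. Written independently of the package implementation.
    """
    n = len(records)
    counts = Counter(t for t, _ in records)
    qualifying = counts["DEL"] + counts["DUP"] + counts["TRA"]

    c1 = n > 50
    c2 = n > 0 and qualifying / n > 0.70
    c3 = not focal

    del_sizes = [s for t, s in records if t == "DEL" and s is not None]
    dup_sizes = [s for t, s in records if t == "DUP" and s is not None]
    med_del = median(del_sizes) / 1000 if del_sizes else None
    med_dup = median(dup_sizes) / 1000 if dup_sizes else None

    best = max(counts["DEL"], counts["DUP"], counts["TRA"])
    del_tra = best > 0 and (counts["DEL"] == best or counts["TRA"] == best)
    dup = best > 0 and counts["DUP"] == best

    c4 = del_tra and med_del is not None and med_del < 10
    c5 = dup and med_dup is not None and med_dup < 50
    return {
        "criteria": {1: c1, 2: c2, 3: c3, 4: c4, 5: c5},
        "positive": c1 and c2 and c3 and (c4 or c5),
    }


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of label assignments.

    For tie-free data: p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|) over all
    C(n1+n2, n1) assignments of the pooled values to the two groups.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in group_a for b in group_b
        )

    mu = n1 * len(y) / 2
    u_obs = u_stat(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def fisher_exact_two_sided_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration: sum the probabilities
    of all tables (with the observed margins) no more probable than observed."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(k):
        return comb(row1, k) * comb(row2, col1 - k) / comb(n, col1)

    support = range(max(0, col1 - row2), min(row1, col1) + 1)
    p_obs = prob(a)
    return sum(prob(k) for k in support if prob(k) <= p_obs * (1 + 1e-9))


def nnls_subset_enumeration(signature_matrix: np.ndarray, counts: np.ndarray):
    """Exact NNLS by enumerating active sets (feasible for a handful of columns).

    For each subset of columns, solve the unconstrained least squares on that
    subset; keep the best solution whose coefficients are all nonnegative.
    Returns (exposures, objective).
    """
    m, k = signature_matrix.shape
    best_obj, best_e = float(np.sum(counts**2)), np.zeros(k)
    for r in range(1, k + 1):
        for cols in itertools.combinations(range(k), r):
            sub = signature_matrix[:, cols]
            coef, *_ = np.linalg.lstsq(sub, counts, rcond=None)
            if (coef < -1e-12).any():
                continue
            resid = counts - sub @ coef
            obj = float(resid @ resid)
            if obj < best_obj:
                best_obj = obj
                best_e = np.zeros(k)
                best_e[list(cols)] = np.maximum(coef, 0.0)
    return best_e, best_obj
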