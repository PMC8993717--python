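"""Independent brute-force reference implementations used as test oracles.

Deliberately written as plain double loops, straight from the defining
formulas, with no shared code with the package under test.
"""

import math


def apen_bruteforce(x, m, r):
    """O(N^2) approximate entropy: -(N-m)^-1 * sum_i ln(C_m1[i]/C_m[i]).

    C_m[i] counts j in 0..N-m-1 with max_k |x[i+k]-x[j+k]| <= r for
    k < m (self match included); C_m1[i] additionally requires the
    (m+1)-th elements to be within tolerance.
    """
    x = list(map(float, x))
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short")
    total = 0.0
    for i in range(n - m):
        c_m = 0
        c_m1 = 0
        for j in range(n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                c_m += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    c_m1 += 1
        total += math.log(c_m1 / c_m)
    return -total / (n - m)


def auc_by_pairs(scores, labels):
    """AUC by explicit concordant-pair enumeration (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def serpentine_bruteforce(values, mask):
    """Serpentine scan by explicit row walking; mask rows may be empty."""
    rows = [i for i, row in enumerate(mask) if any(row)]
    top = rows[0]
    out = []
    for i in rows:
        cols = range(len(mask[i]))
        if (i - top) % 2 == 1:
            cols = reversed(list(cols))
        for j in cols:
            if mask[i][j]:
                out.append(values[i][j])
    return out
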