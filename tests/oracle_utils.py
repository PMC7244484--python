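"""Independent brute-force oracles, computed from first principles.

These deliberately avoid the package's vectorized implementations: step
fitting is re-derived by enumerating every boundary and recomputing segment
means and squared errors with plain Python loops, BH adjustment follows the
step-up definition literally, and the hypergeometric tail is summed from
binomial coefficients.
"""

import math

from scipy import stats


def brute_force_step(values, m, min_segment):
    """Enumerate every admissible boundary; return the best fit.

    Returns (boundary, left_mean, right_mean, sse, f_stat, p_value) with the
    boundary minimizing the residual sum of squares (ties to the smallest
    boundary).
    """
    values = list(map(float, values))
    n = len(values)
    best = None
    for b in range(min_segment, n - min_segment + 1):
        left = values[:b]
        right = values[b:]
        lm = sum(left) / len(left)
        rm = sum(right) / len(right)
        sse = sum((x - lm) ** 2 for x in left) + sum((x - rm) ** 2 for x in right)
        if best is None or sse < best[3] - 0.0:
            if best is None or sse < best[3]:
                best = (b, lm, rm, sse)
    b, lm, rm, sse = best
    grand = sum(values) / n
    fitted = [lm] * b + [rm] * (n - b)
    ss_fit = sum((f - grand) ** 2 for f in fitted)
    if sse == 0.0:
        f_stat = math.inf if ss_fit > 0 else 0.0
    else:
        f_stat = (ss_fit / (m - 1)) / (sse / (n - m))
    if f_stat == math.inf:
        p = 0.0
    elif f_stat == 0.0:
        p = 1.0
    else:
        p = float(stats.f.sf(f_stat, m - 1, n - m))
    return b, lm, rm, sse, f_stat, p


def brute_force_bh(p_values):
    """Benjamini–Hochberg step-up from the definition, in input order."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [None] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * n / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total
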