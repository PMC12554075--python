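"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
double loops for template matching and naive direct summation for the Rényi
entropy, so they can serve as cross-checks.
"""

import math


def brute_force_match_counts(series, m, r):
    """O(N^2) double-loop template pair counts (B at length m, A at m+1)."""
    x = [float(v) for v in series]
    n = len(x)

    def count(k):
        total = 0
        for i in range(n - k):
            for j in range(i + 1, n - k):
                for t in range(k):
                    if abs(x[i + t] - x[j + t]) > r:
                        break
                else:
                    total += 1
        return total

    return count(m), count(m + 1)


def brute_force_sampen(series, m, r):
    """-ln(A/B) from the double-loop counts (no small-sample correction)."""
    b, a = brute_force_match_counts(series, m, r)
    return -math.log(a / b)


def naive_renyi(p, alpha):
    """Direct summation of the order-alpha entropy in plain Python floats."""
    p = [float(v) for v in p]
    if alpha == math.inf:
        return -math.log(max(p))
    if alpha == 0:
        return math.log(sum(1 for v in p if v > 0))
    if alpha == 1:
        return -sum(v * math.log(v) for v in p if v > 0)
    return math.log(sum(v**alpha for v in p)) / (1.0 - alpha)
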