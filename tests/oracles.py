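"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the classifier
oracle is a linear scan over every breakpoint, and the binomial oracle is a
full outcome enumeration under the minimum-likelihood two-tailed rule.
"""
import math

import numpy as np


def brute_force_classify(score, table):
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "NoScore"
    satisfied_path = [s for s, bp in table.pathogenic.items() if score >= bp]
    satisfied_ben = [s for s, bp in table.benign.items() if score <= bp]
    order = ["Supporting", "Moderate", "Strong", "VeryStrong"]
    if satisfied_path:
        return "PP3_" + max(satisfied_path, key=order.index)
    if satisfied_ben:
        return "BP4_" + max(satisfied_ben, key=order.index)
    return "Indeterminate"


def brute_force_two_tailed(k, n, p0):
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-9))
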