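"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the package's own code paths: mutual information
is computed by explicit cell counting, the greedy MID ranking by exhaustive
step-wise recomputation, and the binary MCC by its classical closed form.
"""

import math
from collections import Counter

import numpy as np


def mi_oracle(x, y):
    """Plug-in mutual information in bits via explicit counting."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return total


def greedy_mid_oracle(X, y):
    """Exhaustive step-wise recomputation of the greedy MID selection path."""
    cols = list(range(X.shape[1]))
    selected = []
    while cols:
        best, best_v = None, -np.inf
        for j in cols:
            rel = mi_oracle(X[:, j].tolist(), list(y))
            red = (np.mean([mi_oracle(X[:, j].tolist(), X[:, s].tolist())
                            for s in selected]) if selected else 0.0)
            v = rel - red
            if v > best_v + 1e-12:
                best, best_v = j, v
        selected.append(best)
        cols.remove(best)
    return selected


def binary_mcc_closed_form(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0
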