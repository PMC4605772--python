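"""Independent brute-force oracles used by the estimator tests.

These deliberately avoid the package's code paths: histograms go through
numpy's histogramming on explicitly shifted edge grids, and the information
measures are direct evaluations of their defining sums over enumerated
symbol combinations.
"""

import itertools
from collections import Counter

import numpy as np


def ash_oracle(cols, ranges, bins, shifts):
    """Average of all shifted plain histograms, via np.histogramdd."""
    n = len(cols[0])
    sample = np.column_stack(cols)
    total = np.zeros([b + 1 for b in bins])
    combos = list(itertools.product(*[range(m) for m in shifts]))
    for combo in combos:
        edges = []
        for (lo, hi), b, m, k in zip(ranges, bins, shifts, combo):
            w = (hi - lo) / b
            edges.append(lo - k * w / m + np.arange(b + 2) * w)
        h, _ = np.histogramdd(sample, bins=edges)
        total += h / n
    return total / len(combos)


def mi_oracle(samples_x, samples_y):
    """Plug-in MI by exhaustive enumeration over observed symbol pairs."""
    n = len(samples_x)
    pxy = Counter(zip(samples_x, samples_y))
    px = Counter(samples_x)
    py = Counter(samples_y)
    total = 0.0
    for (x, y), c in pxy.items():
        p = c / n
        total += p * np.log2(p / ((px[x] / n) * (py[y] / n)))
    return total


def cmi_oracle(xs, ys, zs):
    """I(X;Y|Z) by exhaustive enumeration."""
    n = len(xs)
    pxyz = Counter(zip(xs, ys, zs))
    pxz = Counter(zip(xs, zs))
    pyz = Counter(zip(ys, zs))
    pz = Counter(zs)
    total = 0.0
    for (x, y, z), c in pxyz.items():
        p = c / n
        total += p * np.log2(
            (c / n) * (pz[z] / n) / ((pxz[(x, z)] / n) * (pyz[(y, z)] / n))
        )
    return total


def si_oracle(samples_s, samples_r, s_value):
    """Specific information by direct evaluation of the defining sum."""
    n = len(samples_s)
    ps = Counter(samples_s)
    pr = Counter(samples_r)
    psr = Counter(zip(samples_s, samples_r))
    total = 0.0
    for r, c_r in pr.items():
        joint = psr.get((s_value, r), 0)
        if joint == 0:
            continue
        p_r_given_s = joint / ps[s_value]
        p_s_given_r = joint / c_r
        total += p_r_given_s * (
            np.log2(1.0 / (ps[s_value] / n)) - np.log2(1.0 / p_s_given_r)
        )
    return total
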