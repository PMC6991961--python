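"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's test
implementations) so they can serve as second routes to the same numbers.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

from scipy.stats import chi2


def midranks(values: list[float]) -> list[float]:
    """Mid-ranks with ties, computed by explicit enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        rank = (i + j) / 2 + 1  # average of positions i..j (1-based)
        for k in range(i, j + 1):
            ranks[order[k]] = rank
        i = j + 1
    return ranks


def kruskal_wallis_oracle(groups: list[list[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p from the textbook
    rank formula: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), divided by
    1 - sum(t^3 - t)/(N^3 - N)."""
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    df = len(groups) - 1
    if len(set(pooled)) == 1:
        return 0.0, 1.0
    ranks = midranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos : pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    tie_sum = sum(t**3 - t for t in Counter(pooled).values())
    h /= 1.0 - tie_sum / (n_total**3 - n_total)
    return h, float(chi2.sf(h, df))


def small_kw_instances():
    """Exhaustive small rank-test instances: every dataset of <= 5
    observations over a small value alphabet, split into 2 (and for n = 5,
    3) non-empty groups."""
    instances = []
    for n in (3, 4, 5):
        for values in itertools.product((1, 2, 3), repeat=n):
            for labels in itertools.product((0, 1), repeat=n):
                if len(set(labels)) < 2:
                    continue
                groups = [
                    [v for v, l in zip(values, labels) if l == g] for g in (0, 1)
                ]
                instances.append(groups)
    for values in itertools.product((1, 2), repeat=5):
        for labels in itertools.product((0, 1, 2), repeat=5):
            if len(set(labels)) < 3:
                continue
            groups = [
                [v for v, l in zip(values, labels) if l == g] for g in (0, 1, 2)
            ]
            instances.append(groups)
    return instances
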