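"""Independent brute-force oracles used to cross-check the spatial code.

Everything here is a direct O(N^2) transcription of the definitions, kept
free of spatial indexing so it can never share a bug with the library.
"""

import numpy as np


def brute_neighbour_counts(xy, labels, types, radius):
    """Ordered-pair encounter counts by exhaustive pairwise distances."""
    K = len(types)
    idx = {t: k for k, t in enumerate(types)}
    C = np.zeros((K, K), dtype=int)
    n = len(xy)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(*(xy[i] - xy[j])) <= radius:
                C[idx[labels[i]], idx[labels[j]]] += 1
    return C


def brute_composition(xy, labels, types, radius):
    """Per-cell neighbour-type fractions by exhaustive distances."""
    K = len(types)
    idx = {t: k for k, t in enumerate(types)}
    n = len(xy)
    counts = np.zeros((n, K), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.hypot(*(xy[i] - xy[j])) <= radius:
                counts[i, idx[labels[j]]] += 1
    totals = counts.sum(axis=1)
    comp = np.zeros((n, K))
    ok = totals > 0
    comp[ok] = counts[ok] / totals[ok, None]
    return comp, totals


def brute_radial_counts(cell_xy, mol_xy, k_max):
    """Per-annulus molecule incidences by exhaustive cell-molecule distances."""
    counts = np.zeros(k_max, dtype=int)
    for c in cell_xy:
        for m in mol_xy:
            d = np.hypot(*(c - m))
            if d < k_max:
                counts[int(np.floor(d))] += 1
    return counts


def paired_t(a, b):
    """Textbook paired t statistic and two-sided p (Student t, df = n-1)."""
    from scipy import stats

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return t, p
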