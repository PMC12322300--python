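"""Independent brute-force re-derivations used as test oracles.

Each oracle restates its rule from first principles with naive loops and
exact arithmetic, independently of the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def brute_force_missingness_labels(
    observed: np.ndarray,
    tissue_of_sample: list[str],
    reliable: Fraction = Fraction(4, 5),
    mode: str = "all",
) -> np.ndarray:
    """Label each cell of a protein x sample grid.

    For every protein and tissue pair (T, other): when the other tissue's
    detection fraction is at least ``reliable`` and T's missing fraction
    strictly exceeds ``1 - reliable``, T's missing cells are below-LOD.
    Everything else missing is missing-at-random.
    """
    n_prot, n_samp = observed.shape
    labels = np.full(observed.shape, "", dtype=object)
    tissues = ("cNF", "skin")
    cols = {t: [j for j in range(n_samp) if tissue_of_sample[j] == t] for t in tissues}
    for i in range(n_prot):
        det = {}
        for t in tissues:
            n_det = sum(1 for j in cols[t] if observed[i, j])
            det[t] = Fraction(n_det, len(cols[t]))
        for t, other in (("cNF", "skin"), ("skin", "cNF")):
            missing_frac = Fraction(1) - det[t]
            if det[other] >= reliable and missing_frac > Fraction(1) - reliable:
                miss = [j for j in cols[t] if not observed[i, j]]
                if mode == "excess":
                    allowance = int((Fraction(1) - reliable) * len(cols[t]))
                    miss = miss[: len(miss) - allowance]
                for j in miss:
                    labels[i, j] = "impute_lod"
        for j in range(n_samp):
            if not observed[i, j] and labels[i, j] == "":
                labels[i, j] = "leave_mar"
    return labels


def brute_force_complete_linkage(points: np.ndarray):
    """Naive O(n^3) agglomerative complete-linkage clustering.

    Returns a list of merges (frozenset_left, frozenset_right, height) and
    the partition after each merge, using Euclidean distances.
    """
    n = len(points)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    merges = []
    partitions = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], h))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        partitions.append([set(c) for c in clusters])
    return merges, partitions
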