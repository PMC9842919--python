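"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Naive O(n^3) Ward agglomerator from raw points (ESS-increase definition)
# ---------------------------------------------------------------------------


def naive_ward_merges(points: np.ndarray):
    """Reference Ward merge sequence computed directly from point clouds.

    At each step the pair of clusters with minimal increase in total
    within-cluster sum of squares is merged:
    ``delta(A, B) = |A||B|/(|A|+|B|) * ||mean(A) - mean(B)||^2``.
    Ties break toward the lexicographically lowest pair of cluster
    representatives (smallest original member indices). Returns the list of
    (rep_a, rep_b) merge pairs, rep_a < rep_b.
    """
    pts = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(pts))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                ma = pts[ca].mean(axis=0)
                mb = pts[cb].mean(axis=0)
                delta = (
                    len(ca) * len(cb) / (len(ca) + len(cb))
                ) * float(((ma - mb) ** 2).sum())
                key = (delta, min(ca), min(cb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ra, rb = min(clusters[a]), min(clusters[b])
        merges.append((min(ra, rb), max(ra, rb)))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


# ---------------------------------------------------------------------------
# Brute-force BH step-up definition
# ---------------------------------------------------------------------------


def brute_force_bh(pvalues, alpha):
    """Literal step-up definition: find the largest k with p_(k) <= k/m*alpha
    and reject exactly the k smallest p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


# ---------------------------------------------------------------------------
# Brute-force maximum bipartite matching under an ICV tolerance
# ---------------------------------------------------------------------------


def brute_max_matching_size(men_icv, women_icv, tolerance):
    """Maximum number of disjoint pairs with |delta ICV| < tolerance
    (augmenting-path bipartite matching)."""
    men_icv = np.asarray(men_icv, dtype=float)
    women_icv = np.asarray(women_icv, dtype=float)
    compat = np.abs(men_icv[:, None] - women_icv[None, :]) < tolerance
    match_w = [-1] * len(women_icv)

    def try_augment(i, seen):
        for j in range(len(women_icv)):
            if compat[i, j] and not seen[j]:
                seen[j] = True
                if match_w[j] == -1 or try_augment(match_w[j], seen):
                    match_w[j] = i
                    return True
        return False

    size = 0
    for i in range(len(men_icv)):
        if try_augment(i, [False] * len(women_icv)):
            size += 1
    return size
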