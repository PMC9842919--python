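"""Multi-subject streamline bundle clustering with consensus labeling.

The procedure mirrors the subset-and-consensus scheme used for
population-scale tractography segmentation: streamlines from all subjects are
pooled, linearly resampled to a fixed number of points, randomly partitioned
into subsets of manageable size, Ward-clustered within each subset on
pairwise streamline distances, label-matched across subsets against a global
reference via optimal assignment on cluster representatives, and the whole
step is repeated with fresh random partitions; each streamline's consensus
label is the modal label across repetitions and its stability the agreement
fraction.

Distances are corresponding-point mean Euclidean distances minimized over the
two point orderings (flip-invariant). Ward clustering runs on the
precomputed distance matrix via the Lance-Williams recurrence on squared
distances; all ties (merge choice, assignment, modal labels) break toward the
lowest index so results are bit-reproducible under a fixed seed.

Labels are 0-based integers in ``0..k-1`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import mode as _mode

N_POINTS_DEFAULT = 25


# ---------------------------------------------------------------------------
# Resampling and distances
# ---------------------------------------------------------------------------


def resample(streamline: np.ndarray, n: int = N_POINTS_DEFAULT) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing.

    Endpoints are preserved exactly. Rejects degenerate (zero total length
    or single-point) inputs.
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("streamline must be an (m>=2, 3) array")
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seglen.sum()
    if total <= 0:
        raise ValueError("zero-length streamline cannot be resampled")
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, total, n)
    out = np.stack([np.interp(targets, arc, pts[:, d]) for d in range(3)], axis=1)
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def streamline_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Flip-invariant corresponding-point mean Euclidean distance (mm).

    ``d(a, b) = min(mean_i |a_i - b_i|, mean_i |a_i - b_rev(i)|)`` over the
    two point orderings of ``b``. Both inputs must share the same point
    count (normally 25 after :func:`resample`).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("streamlines must have equal point counts")
    direct = np.linalg.norm(a - b, axis=1).mean()
    flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
    return float(min(direct, flipped))


def cross_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flip-invariant distance matrix between two sets of resampled curves.

    ``a`` is (n, p, 3) and ``b`` (m, p, 3); returns (n, m). Equivalent to
    calling :func:`streamline_distance` on every pair.
    """
    from scipy.spatial.distance import cdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = a.shape[1]
    direct = np.zeros((a.shape[0], b.shape[0]))
    flipped = np.zeros_like(direct)
    for i in range(p):
        direct += cdist(a[:, i], b[:, i])
        flipped += cdist(a[:, i], b[:, p - 1 - i])
    return np.minimum(direct, flipped) / p


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Full flip-invariant distance matrix for (n, p, 3) resampled curves."""
    out = cross_distances(points, points)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Ward agglomeration on a precomputed distance matrix
# ---------------------------------------------------------------------------


def ward_linkage(distances: np.ndarray) -> List[Tuple[int, int, float, int]]:
    """Full Ward merge sequence on a precomputed distance matrix.

    Treats the distances as Euclidean and applies the Lance-Williams
    recurrence on squared distances:

        d2(i u j, m) = ((s_i + s_m) d2(i,m) + (s_j + s_m) d2(j,m)
                        - s_m d2(i,j)) / (s_i + s_j + s_m)

    Each merge is recorded as ``(rep_a, rep_b, d2, size)`` where the
    representatives are the smallest original indices of the two clusters
    (rep_a < rep_b) and ``size`` is the merged cluster's cardinality. Exact
    ties merge the lexicographically lowest pair.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")

    d2 = d.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    size = np.ones(n)
    active = np.ones(n, dtype=bool)
    # cluster in slot i is represented by its smallest member index, which
    # stays equal to i when merges always land in the lower slot
    merges: List[Tuple[int, int, float, int]] = []
    work = d2.copy()
    for _ in range(n - 1):
        # symmetric matrix with inf diagonal/retired slots: the row-major
        # argmin lands on (i, j) with i < j, and among exact ties picks the
        # lexicographically lowest pair (flat index i*n+j orders pairs
        # lexicographically for i < j)
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        dij = work[i, j]
        si, sj = size[i], size[j]
        merges.append((i, j, float(dij), int(si + sj)))
        m = active.copy()
        m[i] = m[j] = False
        sm = size[m]
        work[i, m] = work[m, i] = (
            (si + sm) * work[i, m] + (sj + sm) * work[j, m] - sm * dij
        ) / (si + sj + sm)
        size[i] = si + sj
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
    return merges


def labels_from_merges(
    merges: Sequence[Tuple[int, int, float, int]], n: int, k: int
) -> np.ndarray:
    """Cut a merge sequence at ``k`` clusters; labels ordered by cluster rep."""
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _, _ in merges[: n - k]:
        parent[find(j)] = find(i)
    roots = np.array([find(a) for a in range(n)])
    uniq = np.unique(roots)  # sorted ascending = by smallest member
    lookup = {r: lab for lab, r in enumerate(uniq)}
    return np.array([lookup[r] for r in roots])


def ward_cluster(distances: np.ndarray, k: int) -> np.ndarray:
    """Ward-cluster a distance matrix into ``k`` groups (labels 0..k-1)."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n)
    merges = ward_linkage(d)
    return labels_from_merges(merges, n, k)


# ---------------------------------------------------------------------------
# Subsets, matching, consensus
# ---------------------------------------------------------------------------


def partition(
    n_pool: int, subset_size: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Random disjoint cover of ``range(n_pool)`` in blocks of ``subset_size``.

    The last block holds the remainder; a remainder smaller than 2 is folded
    into the previous block.
    """
    if n_pool < 1:
        raise ValueError("pool must be non-empty")
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    perm = rng.permutation(n_pool)
    blocks = [perm[i : i + subset_size] for i in range(0, n_pool, subset_size)]
    if len(blocks) > 1 and len(blocks[-1]) < 2:
        blocks[-2] = np.concatenate([blocks[-2], blocks[-1]])
        blocks.pop()
    return blocks


def cluster_representatives(
    points: np.ndarray, labels: np.ndarray, k: int
) -> np.ndarray:
    """Mean resampled streamline per cluster, with flip alignment.

    Each member is aligned to the cluster's first member (flipped when the
    reversed ordering is closer) before averaging, so the representative is
    not washed out by arbitrary point orderings.
    """
    x = np.asarray(points, dtype=float)
    reps = np.empty((k,) + x.shape[1:])
    for lab in range(k):
        members = x[labels == lab]
        if len(members) == 0:
            raise ValueError(f"cluster {lab} is empty")
        ref = members[0]
        aligned = []
        for s in members:
            direct = np.linalg.norm(s - ref, axis=1).mean()
            flipped = np.linalg.norm(s[::-1] - ref, axis=1).mean()
            aligned.append(s if direct <= flipped else s[::-1])
        reps[lab] = np.mean(aligned, axis=0)
    return reps


def match_labels(reference_reps: np.ndarray, other_reps: np.ndarray) -> np.ndarray:
    """Optimal one-to-one label mapping between two clusterings.

    Minimizes the total flip-invariant distance between cluster
    representatives (Hungarian assignment). Returns ``mapping`` such that a
    streamline labeled ``lab`` in the other clustering gets reference label
    ``mapping[lab]``. Ties resolve to the lowest-index assignment.
    """
    ref = np.asarray(reference_reps, dtype=float)
    oth = np.asarray(other_reps, dtype=float)
    if ref.shape != oth.shape:
        raise ValueError("clusterings must have the same number of clusters")
    k = ref.shape[0]
    cost = cross_distances(oth, ref)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(k, dtype=int)
    mapping[rows] = cols
    return mapping


@dataclass
class ConsensusSegmentation:
    """Per-streamline modal label plus agreement fraction across repetitions."""

    labels: np.ndarray  # (n,) int
    stability: np.ndarray  # (n,) float in [0, 1]
    n_repetitions: int
    k: int

    def __post_init__(self) -> None:
        if ((self.stability < 0) | (self.stability > 1)).any():
            raise ValueError("stability must lie in [0, 1]")


def consensus(assignments: np.ndarray, k: Optional[int] = None) -> ConsensusSegmentation:
    """Modal label per streamline over repetitions; ties to the lowest label.

    ``assignments`` has shape (r, n): one row of labels per repetition, all
    in a common label space (after :func:`match_labels`).
    """
    a = np.asarray(assignments)
    if a.ndim != 2 or a.shape[0] < 1:
        raise ValueError("need an (r>=1, n) assignment matrix")
    r = a.shape[0]
    modal = _mode(a, axis=0, keepdims=False)
    labels = np.atleast_1d(modal.mode).astype(int)
    counts = np.atleast_1d(modal.count).astype(float)
    return ConsensusSegmentation(
        labels=labels,
        stability=counts / r,
        n_repetitions=r,
        k=int(k if k is not None else a.max() + 1),
    )


def consensus_cluster(
    streamlines: Sequence[np.ndarray],
    k: int,
    subset_size: int = 10_000,
    n_repetitions: int = 100,
    seed: int = 0,
    n_points: int = N_POINTS_DEFAULT,
    return_reference: bool = False,
):
    """Full subset-and-consensus clustering of a pooled streamline set.

    Streamlines are resampled, and for each repetition the pool is randomly
    partitioned into subsets of ``subset_size``; each subset is
    Ward-clustered into ``k`` clusters and label-matched to the global
    reference (the first subset of the first repetition). The consensus over
    repetitions is returned.

    With ``return_reference=True`` also returns the reference cluster
    representatives (k, n_points, 3), which can classify held-out subjects'
    streamlines via :func:`assign_to_clusters`.
    """
    resampled = np.stack([resample(s, n_points) for s in streamlines])
    n = resampled.shape[0]
    if subset_size < k:
        raise ValueError("subset_size must be at least k")
    rng = np.random.default_rng(seed)
    all_assignments = np.empty((n_repetitions, n), dtype=int)
    reference_reps: Optional[np.ndarray] = None
    for rep in range(n_repetitions):
        for subset in partition(n, subset_size, rng):
            if len(subset) < k:
                # remainder too small to carve k clusters: classify directly
                if reference_reps is None:
                    raise ValueError("first subset smaller than k")
                all_assignments[rep, subset] = assign_to_clusters(
                    resampled[subset], reference_reps
                )
                continue
            d = pairwise_distances(resampled[subset])
            labels = ward_cluster(d, k)
            reps = cluster_representatives(resampled[subset], labels, k)
            if reference_reps is None:
                reference_reps = reps
                mapping = np.arange(k)
            else:
                mapping = match_labels(reference_reps, reps)
            all_assignments[rep, subset] = mapping[labels]
    seg = consensus(all_assignments, k=k)
    if return_reference:
        return seg, reference_reps
    return seg


def assign_to_clusters(points: np.ndarray, representatives: np.ndarray) -> np.ndarray:
    """Nearest-representative label for each resampled streamline."""
    dists = cross_distances(points, representatives)
    return np.argmin(dists, axis=1)


def extract_tract(
    segmentation: ConsensusSegmentation,
    streamlines: Sequence[np.ndarray],
    label_set: Set[int],
    stability_min: float = 0.5,
) -> List[int]:
    """Indices of streamlines in the given clusters passing the stability cut.

    Mirrors the pruning step of tract extraction: a streamline joins the
    tract when its consensus label is in ``label_set`` and its stability is
    at least ``stability_min``. An empty result is returned with a warning
    (tracts can drop out of individual subjects).
    """
    if any(lab < 0 or lab >= segmentation.k for lab in label_set):
        raise ValueError("label_set contains labels outside the segmentation")
    keep = [
        i
        for i in range(len(segmentation.labels))
        if segmentation.labels[i] in label_set
        and segmentation.stability[i] >= stability_min
    ]
    if not keep:
        warnings.warn("tract extraction produced an empty tract", stacklevel=2)
    return keep
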