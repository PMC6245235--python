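"""Partitioning algorithms and consensus over resampled clusterings.

The consensus step follows the co-clustering-evidence recipe: cluster many
resampled versions of the cohort, count for every pair of patients how often
they land in the same cluster, normalize by how often they were jointly
sampled, and cluster the rows of that agreement matrix to obtain a single
consensus partition. Pairs that repeatedly co-cluster are rewarded; pairs
that rarely do are pushed apart.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import cohen_kappa_score


# ---------------------------------------------------------------------------
# Seed management
# ---------------------------------------------------------------------------

class RngStream:
    """Named, reproducible random substreams from one master seed.

    The same ``(master_seed, label)`` pair always yields an identical draw
    sequence, independent of how many other substreams were created and in
    what order — so pipeline stages can be reordered without silently
    changing each other's randomness.
    """

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed)

    def generator(self, label: str) -> np.random.Generator:
        key = zlib.crc32(label.encode("utf-8"))
        return np.random.default_rng(
            np.random.SeedSequence([self.master_seed, key])
        )

    def seed_int(self, label: str) -> int:
        """A derived integer seed (< 2^31) for libraries wanting one."""
        return int(self.generator(label).integers(2**31))


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Assignment of item indices to cluster labels 0..k-1."""

    item_ids: np.ndarray
    labels: np.ndarray
    k: int
    allow_empty: bool = False
    medoids: np.ndarray | None = None  # set by medoid-based algorithms

    def __post_init__(self) -> None:
        self.item_ids = np.asarray(self.item_ids)
        self.labels = np.asarray(self.labels)
        if self.item_ids.shape != self.labels.shape:
            raise ValueError("item_ids and labels must align")
        if len(np.unique(self.item_ids)) != len(self.item_ids):
            raise ValueError("item_ids must be unique")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.k
        ):
            raise ValueError("labels outside 0..k-1")
        if not self.allow_empty:
            present = np.unique(self.labels)
            if len(present) != self.k:
                raise ValueError(
                    f"partition has empty clusters ({len(present)} of {self.k} used)"
                )

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def members(self, label: int) -> np.ndarray:
        return self.item_ids[self.labels == label]


def write_partition(p: Partition, path) -> None:
    import pandas as pd

    pd.DataFrame({"id": p.item_ids, "label": p.labels}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_indices(
    n: int,
    fraction: float = 0.8,
    with_replacement: bool = False,
    b: int = 10,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Draw ``b`` index collections of ``round(fraction * n)`` items each.

    Collections are returned sorted: the clustering algorithms downstream
    are run on rows in index order, so at ``fraction=1.0`` without
    replacement every collection is exactly ``0..n-1`` and a single-resample
    consensus coincides with one plain clustering of the data.
    """
    if n < 3:
        raise ValueError("need at least 3 items to resample")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    size = int(round(fraction * n))
    if size < 2:
        raise ValueError("resample size must be at least 2")
    if rng is None:
        rng = np.random.default_rng()
    out = []
    for _ in range(b):
        idx = rng.choice(n, size=size, replace=with_replacement)
        out.append(np.sort(idx))
    return out


# ---------------------------------------------------------------------------
# K-means (Lloyd, ++-style seeding, best of several restarts)
# ---------------------------------------------------------------------------

def _kmeanspp_centers(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    m = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    first = int(rng.integers(m))
    centers[0] = points[first]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a center; pick any
            idx = int(rng.integers(m))
        else:
            idx = int(rng.choice(m, p=d2 / total))
        centers[c] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centers[c]) ** 2, axis=1))
    return centers


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin breaks ties toward the lowest cluster index
    return np.argmin(cdist(points, centers, "sqeuclidean"), axis=1)


def _sse(points: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((points - centers[labels]) ** 2))


def lloyd_kmeans(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator | None = None,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Partition:
    """Best-of-``restarts`` Lloyd iteration with distance-weighted seeding.

    Within a restart the within-cluster sum of squares (SSE) is
    non-increasing; an empty cluster is repaired by reseeding its centroid
    at the point farthest from its current centroid. The restart with the
    lowest final SSE wins.
    """
    points = np.asarray(points, float)
    m = points.shape[0]
    if k < 1 or k > m:
        raise ValueError(f"k={k} incompatible with {m} points")
    if rng is None:
        rng = np.random.default_rng()

    best_labels, best_sse = None, np.inf
    for _ in range(restarts):
        centers = _kmeanspp_centers(points, k, rng)
        labels = _assign(points, centers)
        prev = np.inf
        for _ in range(max_iter):
            for c in range(k):
                mask = labels == c
                if mask.any():
                    centers[c] = points[mask].mean(axis=0)
                else:  # empty-cluster repair
                    far = int(np.argmax(np.sum((points - centers[labels] ) ** 2, axis=1)))
                    centers[c] = points[far]
            labels = _assign(points, centers)
            cur = _sse(points, centers, labels)
            if prev - cur <= tol:
                break
            prev = cur
        cur = _sse(points, centers, labels)
        if cur < best_sse - 1e-12:
            best_sse, best_labels = cur, labels.copy()
    labels = _canonical_labels(best_labels, k)
    return Partition(item_ids=np.arange(m), labels=labels, k=k, allow_empty=True)


def _canonical_labels(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters by order of first appearance (stable, seed-robust)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    # unused labels (empty clusters) keep indices above nxt implicitly
    return out


def kmeans_sse(points: np.ndarray, p: Partition) -> float:
    """SSE of a partition under per-cluster mean centroids."""
    points = np.asarray(points, float)
    total = 0.0
    for c in range(p.k):
        mem = points[p.labels == c]
        if len(mem):
            total += float(np.sum((mem - mem.mean(axis=0)) ** 2))
    return total


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)
# ---------------------------------------------------------------------------

def pam_partition(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator | None = None,
    max_swaps: int = 500,
    restarts: int = 5,
) -> Partition:
    """Partitioning Around Medoids: BUILD then best-improvement SWAP.

    Medoids are data points — the most centrally located member of each
    cluster. Total distance to the nearest medoid is non-increasing across
    accepted swaps; a SWAP pass stops when no single swap improves or
    ``max_swaps`` is reached. Because single-swap local search can stall
    (reaching the optimum may require a temporarily worse intermediate),
    the search is multi-start: the deterministic greedy BUILD start plus
    ``restarts - 1`` random initial medoid sets, keeping the lowest-cost
    result.
    """
    points = np.asarray(points, float)
    m = points.shape[0]
    if k < 1 or k > m:
        raise ValueError(f"k={k} incompatible with {m} points")
    if rng is None:
        rng = np.random.default_rng()
    D = cdist(points, points)

    def build() -> list[int]:
        # first medoid minimizes total distance; then greedy additions
        meds = [int(np.argmin(D.sum(axis=1)))]
        nearest = D[:, meds[0]].copy()
        while len(meds) < k:
            best_gain, best_j = -np.inf, -1
            for j in range(m):
                if j in meds:
                    continue
                gain = float(np.sum(np.maximum(nearest - D[:, j], 0.0)))
                if gain > best_gain:
                    best_gain, best_j = gain, j
            meds.append(best_j)
            nearest = np.minimum(nearest, D[:, best_j])
        return meds

    def cost(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    def swap(meds: list[int]) -> tuple[list[int], float]:
        cur = cost(meds)
        for _ in range(max_swaps):
            best_delta, best_pair = 1e-12, None
            for mi in range(k):
                for j in range(m):
                    if j in meds:
                        continue
                    trial = list(meds)
                    trial[mi] = j
                    delta = cur - cost(trial)
                    if delta > best_delta:
                        best_delta, best_pair = delta, (mi, j)
            if best_pair is None:
                break
            meds[best_pair[0]] = best_pair[1]
            cur -= best_delta
        return meds, cur

    starts = [build()]
    for _ in range(max(0, restarts - 1)):
        starts.append(list(rng.choice(m, size=k, replace=False)))
    best_meds, best_cost = None, np.inf
    for s in starts:
        meds, c = swap([int(v) for v in s])
        if c < best_cost - 1e-12:
            best_meds, best_cost = meds, c
    medoids = best_meds
    labels = np.argmin(D[:, medoids], axis=1)
    return Partition(
        item_ids=np.arange(m), labels=_canonical_labels(labels, k), k=k,
        allow_empty=True, medoids=np.array(medoids),
    )


def pam_cost(points: np.ndarray, medoid_idx) -> float:
    """Total Euclidean distance of every point to its nearest medoid."""
    points = np.asarray(points, float)
    D = cdist(points, points[list(medoid_idx)])
    return float(D.min(axis=1).sum())


# ---------------------------------------------------------------------------
# Agglomerative clustering
# ---------------------------------------------------------------------------

def agglomerative_partition(points: np.ndarray, k: int, linkage: str = "average") -> Partition:
    """Deterministic bottom-up merging until ``k`` clusters remain.

    ``linkage`` is one of single / complete / average (Euclidean).
    """
    points = np.asarray(points, float)
    m = points.shape[0]
    if k < 1 or k > m:
        raise ValueError(f"k={k} incompatible with {m} points")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if k == m:
        return Partition(np.arange(m), np.arange(m), k)
    Z = scipy_linkage(pdist(points), method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    kk = int(labels.max()) + 1
    return Partition(np.arange(m), _canonical_labels(labels, kk), kk)


# ---------------------------------------------------------------------------
# Agreement matrix + consensus
# ---------------------------------------------------------------------------

@dataclass
class AgreementMatrix:
    """Pairwise co-clustering evidence over resampled clusterings.

    ``co_cluster[i, j]`` counts resamples in which i and j were both drawn
    and shared a cluster; ``co_present[i, j]`` counts resamples in which
    both were drawn at all. ``ratio`` normalizes the first by the second
    (0 where a pair was never jointly sampled), so rarely co-sampled pairs
    are not penalized for lack of evidence.
    """

    n: int
    co_cluster: np.ndarray
    co_present: np.ndarray
    ratio: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        cc, cp = np.asarray(self.co_cluster), np.asarray(self.co_present)
        if cc.shape != (self.n, self.n) or cp.shape != (self.n, self.n):
            raise ValueError("matrix shapes must be (n, n)")
        if not np.array_equal(cc, cc.T) or not np.array_equal(cp, cp.T):
            raise ValueError("agreement matrices must be symmetric")
        if (cc < 0).any() or (cc > cp).any():
            raise ValueError("need 0 <= co_cluster <= co_present")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(cp > 0, cc / np.maximum(cp, 1), 0.0)
        self.ratio = r

    def to_csv(self, path) -> None:
        import pandas as pd

        idx = [str(i) for i in range(self.n)]
        pd.DataFrame(self.ratio, index=idx, columns=idx).to_csv(path)


def build_agreement_matrix(
    partitions: list[Partition],
    index_collections: list[np.ndarray],
    n: int,
) -> AgreementMatrix:
    """Accumulate co-cluster / co-presence counts over resampled partitions.

    ``partitions[b]`` must be defined exactly on ``index_collections[b]``
    (its ``item_ids`` are positions 0..len(collection)-1 within the
    collection, as produced by running a clusterer on the resampled rows).
    """
    if len(partitions) != len(index_collections):
        raise ValueError("one index collection per partition required")
    co_cluster = np.zeros((n, n), dtype=np.int64)
    co_present = np.zeros((n, n), dtype=np.int64)
    for p, idx in zip(partitions, index_collections):
        idx = np.asarray(idx)
        if p.n_items != len(idx):
            raise ValueError("partition does not cover its index collection")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError("index collection outside 0..n-1")
        uniq = np.unique(idx)
        co_present[np.ix_(uniq, uniq)] += 1
        for c in np.unique(p.labels):
            mem = np.unique(idx[p.labels == c])
            co_cluster[np.ix_(mem, mem)] += 1
    return AgreementMatrix(n=n, co_cluster=co_cluster, co_present=co_present)


def consensus_partition(
    A: AgreementMatrix,
    k: int,
    rng: np.random.Generator | None = None,
    use_ratio: bool = True,
    restarts: int = 10,
) -> Partition:
    """K-means over agreement profiles: each object's row of the (normalized)
    agreement matrix is its feature vector, so objects that keep similar co-clustering
    company end up together."""
    M = A.ratio if use_ratio else A.co_cluster.astype(float)
    return lloyd_kmeans(M, k, rng=rng, restarts=restarts)


# ---------------------------------------------------------------------------
# Partition agreement (aligned Cohen's kappa)
# ---------------------------------------------------------------------------

def align_labels(p: Partition, q: Partition) -> np.ndarray:
    """Relabel ``q`` to best match ``p`` by maximum-overlap assignment.

    Returns q's label vector (aligned, in p's label space where matched;
    unmatched q clusters get fresh labels above p.k).
    """
    if not np.array_equal(np.sort(p.item_ids), np.sort(q.item_ids)):
        raise ValueError("partitions must cover identical item sets")
    order_p = np.argsort(p.item_ids)
    order_q = np.argsort(q.item_ids)
    lp = p.labels[order_p]
    lq = q.labels[order_q]
    cont = np.zeros((p.k, q.k), dtype=np.int64)
    np.add.at(cont, (lp, lq), 1)
    row, col = linear_sum_assignment(-cont)
    mapping = {int(c): int(r) for r, c in zip(row, col)}
    nxt = p.k
    out = np.empty_like(lq)
    for i, lab in enumerate(lq):
        if int(lab) not in mapping:
            mapping[int(lab)] = nxt
            nxt += 1
        out[i] = mapping[int(lab)]
    return out


def kappa_agreement(p: Partition, q: Partition) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Cluster labels are nominal and arbitrary, so q's labels are first
    aligned to p's by optimal one-to-one matching on the contingency
    table; Cohen's kappa of the aligned label vectors is returned
    (range -1..+1, ~0 for independent partitions, 1 for identical ones).
    """
    order_p = np.argsort(p.item_ids)
    lp = p.labels[order_p]
    lq = align_labels(p, q)
    if np.array_equal(lp, lq):
        return 1.0
    return float(cohen_kappa_score(lp, lq))
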