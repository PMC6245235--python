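import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nearestcc.clustering import (
    AgreementMatrix,
    Partition,
    RngStream,
    agglomerative_partition,
    build_agreement_matrix,
    consensus_partition,
    kappa_agreement,
    kmeans_sse,
    lloyd_kmeans,
    pam_cost,
    pam_partition,
    resample_indices,
)


# -- rng streams -------------------------------------------------------------

def test_rng_substreams_are_label_stable_and_independent():
    a = RngStream(42).generator("alpha").random(5)
    b = RngStream(42).generator("alpha").random(5)
    c = RngStream(42).generator("beta").random(5)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


# -- resampling --------------------------------------------------------------

def test_resample_full_fraction_without_replacement_is_everything():
    cols = resample_indices(10, fraction=1.0, b=3,
                            rng=np.random.default_rng(0))
    for idx in cols:
        np.testing.assert_array_equal(idx, np.arange(10))


def test_resample_sizes_and_distinctness():
    cols = resample_indices(10, fraction=0.8, b=10,
                            rng=np.random.default_rng(1))
    assert len(cols) == 10
    for idx in cols:
        assert len(idx) == 8 == len(set(idx.tolist()))


def test_resample_deterministic_under_seed():
    a = resample_indices(20, rng=RngStream(7).generator("resample"))
    b = resample_indices(20, rng=RngStream(7).generator("resample"))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_resample_rejects_tiny_cohorts():
    with pytest.raises(ValueError):
        resample_indices(2, rng=np.random.default_rng(0))


# -- k-means -----------------------------------------------------------------

def test_kmeans_k1_is_total_deviation_from_mean():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 3))
    p = lloyd_kmeans(pts, 1, rng=rng)
    assert p.k == 1 and len(set(p.labels.tolist())) == 1
    np.testing.assert_allclose(
        kmeans_sse(pts, p), np.sum((pts - pts.mean(axis=0)) ** 2)
    )


def test_kmeans_separated_pairs_recovered():
    pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
    p = lloyd_kmeans(pts, 2, rng=np.random.default_rng(3), restarts=5)
    assert p.labels[0] == p.labels[1] != p.labels[2] == p.labels[3]


def _exhaustive_k2_sse(pts: np.ndarray) -> float:
    """Minimum SSE over every nonempty bipartition (independent oracle)."""
    m = len(pts)
    best = np.inf
    for bits in range(1, 2 ** (m - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(m)], dtype=bool)
        sse = 0.0
        for part in (pts[mask], pts[~mask]):
            if len(part):
                sse += float(np.sum((part - part.mean(axis=0)) ** 2))
        best = min(best, sse)
    return best


def test_kmeans_matches_exhaustive_optimum_on_small_instances():
    rng = np.random.default_rng(4)
    for _ in range(25):
        m = int(rng.integers(3, 9))
        pts = rng.normal(size=(m, int(rng.integers(1, 4))))
        p = lloyd_kmeans(pts, 2, rng=rng, restarts=50)
        np.testing.assert_allclose(
            kmeans_sse(pts, p), _exhaustive_k2_sse(pts), rtol=1e-9, atol=1e-9
        )


def test_kmeans_rejects_k_above_m():
    with pytest.raises(ValueError):
        lloyd_kmeans(np.zeros((3, 2)), 4)


# -- PAM ---------------------------------------------------------------------

def test_pam_k_equals_m_gives_zero_cost():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(6, 2))
    p = pam_partition(pts, 6)
    assert len(set(p.labels.tolist())) == 6


def test_pam_separated_pairs():
    pts = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0]])
    p = pam_partition(pts, 2)
    assert p.labels[0] == p.labels[1] != p.labels[2] == p.labels[3]


def test_pam_matches_brute_force_medoid_search():
    rng = np.random.default_rng(6)
    for i in range(20):
        pts = rng.normal(size=(7, 2))
        p = pam_partition(pts, 2, rng=np.random.default_rng(i), restarts=20)
        best = min(
            pam_cost(pts, meds)
            for meds in itertools.combinations(range(7), 2)
        )
        np.testing.assert_allclose(pam_cost(pts, p.medoids), best, rtol=1e-12)


def _same_partition(a, b) -> bool:
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


# -- agglomerative -----------------------------------------------------------

def _naive_agglomerative(pts: np.ndarray, k: int, linkage: str) -> list[set]:
    """Independent O(n^3) bottom-up merge oracle."""
    clusters = [{i} for i in range(len(pts))]
    D = cdist(pts, pts)

    def cdistance(a: set, b: set) -> float:
        vals = [D[i, j] for i in a for j in b]
        if linkage == "single":
            return min(vals)
        if linkage == "complete":
            return max(vals)
        return float(np.mean(vals))

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdistance(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


@pytest.mark.parametrize("linkage", ["single", "complete", "average"])
def test_agglomerative_matches_naive_merge_oracle(linkage):
    rng = np.random.default_rng(8)
    for _ in range(5):
        pts = rng.normal(size=(10, 2))
        p = agglomerative_partition(pts, 3, linkage=linkage)
        oracle = _naive_agglomerative(pts, 3, linkage)
        got = [set(np.flatnonzero(p.labels == c)) for c in range(p.k)]
        assert sorted(map(sorted, got)) == sorted(map(sorted, oracle))


def test_agglomerative_trivial_cases():
    pts = np.array([[0.0], [1.0], [10.0], [11.0]])
    p = agglomerative_partition(pts, 2, linkage="single")
    assert p.labels[0] == p.labels[1] != p.labels[2] == p.labels[3]
    singles = agglomerative_partition(pts, 4, linkage="single")
    assert len(set(singles.labels.tolist())) == 4


# -- agreement matrix --------------------------------------------------------

def test_identical_full_partitions_give_saturated_agreement():
    n, B = 6, 4
    labels = np.array([0, 0, 1, 1, 2, 2])
    parts = [Partition(np.arange(n), labels, 3) for _ in range(B)]
    cols = [np.arange(n)] * B
    A = build_agreement_matrix(parts, cols, n)
    assert (A.co_present == B).all()
    same = labels[:, None] == labels[None, :]
    np.testing.assert_array_equal(A.co_cluster, np.where(same, B, 0))
    np.testing.assert_array_equal(A.ratio, same.astype(float))


def test_never_cosampled_pair_has_zero_ratio():
    parts = [Partition(np.arange(2), np.array([0, 1]), 2)]
    A = build_agreement_matrix(parts, [np.array([0, 1])], 4)
    assert A.co_present[2, 3] == 0 and A.ratio[2, 3] == 0.0
    assert A.ratio[0, 0] == 1.0


def _brute_force_agreement(parts, cols, n):
    cc = np.zeros((n, n), dtype=int)
    cp = np.zeros((n, n), dtype=int)
    for p, idx in zip(parts, cols):
        # double loop over the distinct item set of this resample
        items = sorted(set(idx.tolist()))
        pos = {v: np.flatnonzero(idx == v) for v in items}
        for i in items:
            for j in items:
                cp[i, j] += 1
                li = {p.labels[a] for a in pos[i]}
                lj = {p.labels[a] for a in pos[j]}
                if li & lj:
                    cc[i, j] += 1
    return cc, cp


def test_agreement_matrix_matches_brute_force_pair_count():
    rng = np.random.default_rng(9)
    n, B = 12, 5
    cols = resample_indices(n, fraction=0.8, b=B, rng=rng)
    parts = [
        Partition(np.arange(len(idx)), rng.integers(0, 3, len(idx)), 3,
                  allow_empty=True)
        for idx in cols
    ]
    A = build_agreement_matrix(parts, cols, n)
    cc, cp = _brute_force_agreement(parts, cols, n)
    np.testing.assert_array_equal(A.co_cluster, cc)
    np.testing.assert_array_equal(A.co_present, cp)


def test_agreement_matrix_invariants_enforced():
    with pytest.raises(ValueError, match="symmetric"):
        AgreementMatrix(2, np.array([[1, 1], [0, 1]]), np.ones((2, 2), int))
    with pytest.raises(ValueError, match="co_cluster"):
        AgreementMatrix(2, np.full((2, 2), 3), np.full((2, 2), 2))


# -- consensus ---------------------------------------------------------------

def test_consensus_recovers_block_diagonal_ratio():
    blocks = np.repeat([0, 1, 2], [4, 3, 5])
    same = (blocks[:, None] == blocks[None, :]).astype(int)
    A = AgreementMatrix(12, same * 10, np.full((12, 12), 10))
    p = consensus_partition(A, 3, rng=np.random.default_rng(10))
    assert _same_partition(p.labels, blocks)


def test_consensus_single_cluster_when_all_rows_identical():
    A = AgreementMatrix(5, np.full((5, 5), 7), np.full((5, 5), 7))
    p = consensus_partition(A, 1, rng=np.random.default_rng(11))
    assert len(set(p.labels.tolist())) == 1


def test_consensus_invariant_to_partition_order():
    rng = np.random.default_rng(12)
    n = 15
    cols = resample_indices(n, b=6, rng=rng)
    parts = [
        Partition(np.arange(len(idx)), rng.integers(0, 2, len(idx)), 2,
                  allow_empty=True)
        for idx in cols
    ]
    A1 = build_agreement_matrix(parts, cols, n)
    A2 = build_agreement_matrix(parts[::-1], cols[::-1], n)
    p1 = consensus_partition(A1, 2, rng=RngStream(0).generator("c"))
    p2 = consensus_partition(A2, 2, rng=RngStream(0).generator("c"))
    np.testing.assert_array_equal(p1.labels, p2.labels)


def test_single_full_resample_consensus_reproduces_that_clustering():
    rng = np.random.default_rng(13)
    pts = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(8, 1, (7, 2))])
    base = lloyd_kmeans(pts, 2, rng=rng, restarts=5)
    cols = [np.arange(15)]
    A = build_agreement_matrix([base], cols, 15)
    same = (base.labels[:, None] == base.labels[None, :]).astype(float)
    np.testing.assert_array_equal(A.ratio, same)
    p = consensus_partition(A, 2, rng=rng)
    assert _same_partition(p.labels, base.labels)


# -- kappa -------------------------------------------------------------------

def test_kappa_is_one_for_identical_and_permuted_labels():
    rng = np.random.default_rng(14)
    labels = rng.integers(0, 3, 50)
    p = Partition(np.arange(50), labels, 3)
    q = Partition(np.arange(50), (labels + 1) % 3, 3)
    assert kappa_agreement(p, p) == 1.0
    assert kappa_agreement(p, q) == 1.0


def test_kappa_near_zero_for_independent_partitions():
    rng = np.random.default_rng(15)
    p = Partition(np.arange(2000), rng.integers(0, 3, 2000), 3,
                  allow_empty=True)
    q = Partition(np.arange(2000), rng.integers(0, 3, 2000), 3,
                  allow_empty=True)
    assert abs(kappa_agreement(p, q)) < 0.05


def test_kappa_rejects_mismatched_item_sets():
    p = Partition(np.arange(5), np.zeros(5, int), 1)
    q = Partition(np.arange(1, 6), np.zeros(5, int), 1)
    with pytest.raises(ValueError, match="identical item sets"):
        kappa_agreement(p, q)
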