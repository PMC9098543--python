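"""Step-2 inter-subject centroid clustering: distances, affinity, HDBSCAN."""
import numpy as np
import pytest

from aviatract.cluster_inter import (
    CentroidSet,
    InterParams,
    affinity_matrix,
    distance_matrix,
    grid_optimize,
    hdbscan_interclusters,
    normalized_pairwise_distance,
    presence_filter,
    resample_centroid,
)


# ---------------------------------------------------------------- resampling

def test_resample_straight_segment():
    out = resample_centroid(np.array([[0.0, 0, 0], [10.0, 0, 0]]), 21)
    assert out.shape == (21, 3)
    np.testing.assert_allclose(out[:, 0], np.linspace(0, 10, 21), atol=1e-12)
    np.testing.assert_allclose(out[:, 1:], 0.0)


def test_resample_idempotent():
    pts = np.stack([np.linspace(0, 5, 21), np.zeros(21), np.zeros(21)], axis=1)
    out = resample_centroid(pts, 21)
    np.testing.assert_allclose(out, pts, atol=1e-9)


def test_resample_quarter_circle_arc_spacing():
    """Arc-length spacing matches the analytic circle parametrization."""
    r = 10.0
    ang = np.linspace(0, np.pi / 2, 500)
    arc = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros_like(ang)], axis=1)
    out = resample_centroid(arc, 21)
    expected_ang = np.linspace(0, np.pi / 2, 21)
    expected = np.stack(
        [r * np.cos(expected_ang), r * np.sin(expected_ang), np.zeros(21)], axis=1
    )
    np.testing.assert_allclose(out, expected, atol=2e-3)
    seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert seg.std() / seg.mean() < 1e-3
    total = seg.sum()
    assert abs(total - r * np.pi / 2) / (r * np.pi / 2) < 0.01


def test_resample_degenerate_rejected():
    with pytest.raises(ValueError):
        resample_centroid(np.zeros((3, 3)), 21)


# ---------------------------------------------------------------- distances

def _straight(y, length=20.0, n=21):
    return np.stack([np.linspace(0, length, n), np.full(n, y), np.zeros(n)], axis=1)


def test_identical_centroids_hit_distance_floor():
    p = InterParams()
    a = _straight(0.0)
    assert normalized_pairwise_distance(a, a.copy(), p) == pytest.approx(0.01)


def test_parallel_offset_distance_and_length_correction():
    p = InterParams()
    delta = 1.0
    d20 = normalized_pairwise_distance(_straight(0, 20), _straight(delta, 20), p)
    assert d20 == pytest.approx(delta * p.nf / (p.nf + 20.0), rel=1e-12)
    d40 = normalized_pairwise_distance(_straight(0, 40), _straight(delta, 40), p)
    assert d40 < d20  # longer centroids relax the constraint


def test_flip_invariance():
    p = InterParams()
    a, b = _straight(0.0), _straight(1.0)
    assert normalized_pairwise_distance(a, b[::-1], p) == pytest.approx(
        normalized_pairwise_distance(a, b, p), rel=1e-12
    )


def test_distance_matches_brute_force_on_random_pairs():
    rng = np.random.default_rng(0)
    p = InterParams()
    for _ in range(10):
        a = np.cumsum(rng.random((21, 3)), axis=0)
        b = np.cumsum(rng.random((21, 3)), axis=0) + rng.random(3) * 5
        direct = np.linalg.norm(a - b, axis=1).mean()
        flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
        la = np.linalg.norm(np.diff(a, axis=0), axis=1).sum()
        lb = np.linalg.norm(np.diff(b, axis=0), axis=1).sum()
        expected = max(p.d_floor, min(direct, flipped) * p.nf / (p.nf + min(la, lb)))
        assert normalized_pairwise_distance(a, b, p) == pytest.approx(expected, rel=1e-12)


def test_correction_monotone_in_min_length():
    """Corrected distance strictly decreases as the min length grows."""
    p = InterParams()
    d_pw = 1.5
    lengths = np.linspace(0.64, 49.06, 100)
    corrected = np.maximum(p.d_floor, d_pw * p.nf / (p.nf + lengths))
    assert np.all(np.diff(corrected) < 0)
    # and strictly increases with the raw distance at fixed lengths
    vals = [
        normalized_pairwise_distance(_straight(0.0), _straight(y), p)
        for y in (0.5, 1.0, 2.0, 4.0)
    ]
    assert np.all(np.diff(vals) > 0)


# ---------------------------------------------------------------- affinity

def _planted_cohort(
    n_subjects=6, bundles=(0.0, 30.0, 60.0, 90.0), jitter=0.2,
    rare_offset=None, rare_subjects=(), seed=0,
):
    rng = np.random.default_rng(seed)
    pts, subs = [], []
    for s in range(n_subjects):
        for off in bundles:
            pts.append(_straight(off) + rng.normal(0, jitter, (21, 3)))
            subs.append(s)
        if rare_offset is not None and s in rare_subjects:
            pts.append(_straight(rare_offset) + rng.normal(0, jitter, (21, 3)))
            subs.append(s)
    return CentroidSet(np.asarray(pts), np.asarray(subs))


def test_affinity_matrix_structure():
    p = InterParams()
    cs = _planted_cohort(n_subjects=5, bundles=(0.0, 30.0), seed=1)
    a = affinity_matrix(cs, p)
    d = distance_matrix(cs, p)
    assert a.shape == (len(cs), len(cs))
    assert np.allclose(a, a.T)
    assert (a >= 0).all() and (a <= 1).all()
    assert np.allclose(np.diag(a), 1.0)
    assert (a[d > p.camd] == 0).all()
    # kernel arithmetic at the floor distance
    assert np.exp(-(0.01**2) / p.sigma2) == pytest.approx(1.0, abs=1e-7)


# ---------------------------------------------------------------- HDBSCAN

def test_planted_shared_bundles_recovered():
    """6 subjects x 4 shared bundles at 0.2 mm jitter -> exactly 4 clusters."""
    p = InterParams()
    cs = _planted_cohort(seed=2)
    clusters = hdbscan_interclusters(affinity_matrix(cs, p), cs, p)
    kept = presence_filter(clusters, 6, p)
    assert len(kept) == 4
    for c in kept:
        assert len(np.unique(c.subjects)) == 6
        assert c.presence_fraction == 1.0


def test_rare_bundle_rejected_by_presence_filter():
    p = InterParams()
    cs = _planted_cohort(rare_offset=120.0, rare_subjects=(0, 1), seed=3)
    clusters = hdbscan_interclusters(affinity_matrix(cs, p), cs, p)
    kept = presence_filter(clusters, 6, p)
    assert len(kept) == 4
    rare = [i for i, pt in enumerate(cs.points) if pt[0, 1] > 100]
    kept_members = set(np.concatenate([c.member_indices for c in kept]).tolist())
    assert not (set(rare) & kept_members)


def test_all_centroids_beyond_camd_yield_noise():
    p = InterParams()
    pts = np.asarray([_straight(off, length=2.0) for off in np.arange(6) * 50.0])
    cs = CentroidSet(pts, np.arange(6))
    clusters = hdbscan_interclusters(affinity_matrix(cs, p), cs, p)
    assert clusters == []


def test_duplicated_cohort_doubles_membership():
    p = InterParams()
    cs = _planted_cohort(seed=4)
    dup = CentroidSet(
        np.concatenate([cs.points, cs.points]),
        np.concatenate([cs.subject_ids, cs.subject_ids]),
    )
    c1 = presence_filter(hdbscan_interclusters(affinity_matrix(cs, p), cs, p), 6, p)
    c2 = presence_filter(hdbscan_interclusters(affinity_matrix(dup, p), dup, p), 6, p)
    assert len(c2) == len(c1)
    assert sorted(len(c.member_indices) for c in c2) == sorted(
        2 * len(c.member_indices) for c in c1
    )


def test_clustering_invariant_under_rigid_transform():
    p = InterParams()
    cs = _planted_cohort(seed=5)
    theta = 0.7
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    moved = CentroidSet(cs.points @ rot.T + [5.0, -3.0, 2.0], cs.subject_ids)
    np.testing.assert_allclose(
        distance_matrix(cs, p), distance_matrix(moved, p), atol=1e-9
    )
    c1 = hdbscan_interclusters(affinity_matrix(cs, p), cs, p)
    c2 = hdbscan_interclusters(affinity_matrix(moved, p), moved, p)
    assert [c.member_indices.tolist() for c in c1] == [
        c.member_indices.tolist() for c in c2
    ]


def test_presence_filter_threshold():
    p = InterParams()
    from aviatract.cluster_inter import InterCluster

    half = InterCluster(np.arange(3), np.array([0, 1, 2]), 0.5)
    third = InterCluster(np.arange(2), np.array([0, 1]), 1 / 3)
    out = presence_filter([half, third], 6, p)
    assert out == [half]  # 3 of 6 kept (= 50%), 2 of 6 dropped
    strict = InterParams(min_pop_frac=1.0)
    assert presence_filter([half, third], 6, strict) == []


# ---------------------------------------------------------------- grid search

def test_grid_optimum_is_argmax_of_surface():
    cs = _planted_cohort(n_subjects=4, seed=6)
    nf_grid = np.linspace(1.0, 100.0, 5)
    camd_grid = np.linspace(0.1, 4.0, 5)
    (nf, camd), surface = grid_optimize(cs, nf_grid=nf_grid, camd_grid=camd_grid)
    i, j = np.unravel_index(surface.argmax(), surface.shape)
    assert (nf, camd) == (nf_grid[i], camd_grid[j])
    assert surface.shape == (5, 5)


def test_grid_degenerate_camd_column_is_zero():
    """A CAMD below every inter-centroid distance gives zero clusters."""
    cs = _planted_cohort(n_subjects=4, jitter=2.0, seed=7)
    p = InterParams(d_floor=0.001)
    camd_grid = np.array([0.005, 2.0])
    _, surface = grid_optimize(cs, p, nf_grid=np.array([1.0, 4.0]), camd_grid=camd_grid)
    d = distance_matrix(cs, InterParams(nf=1.0, d_floor=0.001))
    off_diag = d[~np.eye(len(d), dtype=bool)]
    assert off_diag.min() > 0.005
    assert (surface[:, 0] == 0).all()
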