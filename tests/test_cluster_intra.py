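"""Step-1 intra-subject clustering operations and planted-bundle recovery."""
import numpy as np
import pytest

import aviatract as av
from aviatract.cluster_intra import (
    FiberCluster,
    assign_fibers,
    cluster_parcels,
    cluster_subject,
    compute_centroid,
    density_mask,
    parcel_connectivity,
    parcellate,
    split_by_length,
    split_by_region,
)
from aviatract.core import Tractogram, mcp_distance, voxel_affine
from aviatract.phantom import REGION_CBL, REGION_LH, REGION_RH, BundleGeometry, PhantomSpec

VS = 0.2
AFF = voxel_affine(VS)


def _line(p0, p1, n=20):
    return np.linspace(p0, p1, n)


# ---------------------------------------------------------------- regions

def _labels(shape=(10, 10, 10)):
    lab = np.zeros(shape, dtype=int)
    lab[:5] = REGION_LH
    lab[5:] = REGION_RH
    lab[:, 8:, :] = REGION_CBL
    return lab


def test_split_by_region_rules():
    lab = _labels()
    t = Tractogram(
        [
            _line([0.1, 0.1, 0.1], [0.8, 0.8, 0.8]),  # fully LH
            _line([0.2, 0.2, 0.2], [1.8, 0.2, 0.2]),  # spans LH and RH -> INT
            _line([0.2, 1.9, 0.2], [0.8, 1.9, 0.8]),  # cerebellar slab
            _line([1.2, 0.1, 0.1], [1.8, 0.8, 0.8]),  # fully RH
        ],
        AFF,
    )
    part = split_by_region(t, lab)
    assert part.subsets["LH"].tolist() == [0]
    assert part.subsets["INT"].tolist() == [1]
    assert part.subsets["CBL"].tolist() == [2]
    assert part.subsets["RH"].tolist() == [3]
    total = sum(len(v) for v in part.subsets.values())
    assert total == len(t)


def test_split_by_region_partitions_random_set():
    rng = np.random.default_rng(0)
    sls = [_line(rng.random(3) * 1.9, rng.random(3) * 1.9) for _ in range(100)]
    part = split_by_region(Tractogram(sls, AFF), _labels())
    assert sum(len(v) for v in part.subsets.values()) == 100


# ---------------------------------------------------------------- lengths

def test_split_by_length_bins():
    lengths = np.array([0.5, 1.5, 7.9, 8.0, 8.5])
    bins, kept = split_by_length(lengths, (0.0, 8.0), 8)
    assert bins.tolist() == [0, 1, 7, 7, -1]  # l_max joins the last bin
    assert kept.tolist() == [True, True, True, True, False]


def test_split_by_length_discard_count_oracle():
    rng = np.random.default_rng(1)
    lengths = rng.random(500) * 100
    window = (10.0, 60.0)
    bins, kept = split_by_length(lengths, window, 8)
    brute = sum(1 for l in lengths if l < window[0] or l > window[1])
    assert (~kept).sum() == brute
    assert (bins[kept] >= 0).all() and (bins[~kept] == -1).all()
    with pytest.raises(ValueError):
        split_by_length(lengths, (5.0, 5.0))


# ---------------------------------------------------------------- density

def test_density_mask_threshold():
    f = _line([0.1, 0.1, 0.1], [1.5, 0.1, 0.1])
    m5 = density_mask([f] * 5, AFF, (10, 10, 10), min_fibers=5)
    assert m5.any()
    m4 = density_mask([f] * 4, AFF, (10, 10, 10), min_fibers=5)
    assert not m4.any()


def test_density_mask_matches_recount_oracle():
    rng = np.random.default_rng(2)
    fibers = [_line(rng.random(3) * 1.9, rng.random(3) * 1.9, 30) for _ in range(40)]
    got = density_mask(fibers, AFF, (10, 10, 10), min_fibers=3)
    counts = np.zeros((10, 10, 10), dtype=int)
    for f in fibers:
        seen = set()
        for p in f:
            v = tuple(np.floor(p / VS).astype(int))
            seen.add(v)
        for v in seen:
            counts[v] += 1
    np.testing.assert_array_equal(got, counts >= 3)


# ---------------------------------------------------------------- parcels

def test_parcellate_sizes():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[...] = True  # 27 voxels
    pm = parcellate(mask, VS, 27, seed=0)
    assert pm.n_parcels == 1
    assert (pm.labels[mask] == 1).all()

    mask10 = np.zeros((27, 10, 1), dtype=bool)
    mask10[...] = True  # 270 voxels
    pm10 = parcellate(mask10, VS, 27, seed=0)
    assert pm10.n_parcels == 10
    sizes = np.bincount(pm10.labels[mask10])[1:]
    assert sizes.sum() == 270
    assert sizes.mean() == 27


def test_parcellate_is_nearest_center_fixed_point():
    rng = np.random.default_rng(3)
    mask = rng.random((8, 8, 8)) > 0.5
    pm = parcellate(mask, VS, 27, seed=1)
    vox = np.argwhere(mask)
    coords = (vox + 0.5) * VS
    lab = pm.labels[mask]
    centers = np.array([coords[lab == p].mean(axis=0) for p in range(1, pm.n_parcels + 1)])
    d = np.linalg.norm(coords[:, None] - centers[None], axis=2)
    np.testing.assert_array_equal(lab, d.argmin(axis=1) + 1)


# ---------------------------------------------------------------- connectivity

def _pm_from_labels(labels):
    from aviatract.cluster_intra import ParcelMap

    return ParcelMap(labels, int(labels.max()), 27)


def test_parcel_connectivity_single_fiber():
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[0:2, 0, 0] = 1
    labels[2:4, 0, 0] = 2
    labels[4:6, 0, 0] = 3
    f = _line([0.05, 0.1, 0.1], [1.15, 0.1, 0.1], 30)
    m = parcel_connectivity([f], _pm_from_labels(labels), AFF)
    assert m[1, 2] == m[2, 3] == m[1, 3] == 1
    assert m[1, 1] == 0 and (m == m.T).all()


def test_parcel_connectivity_matches_brute_force():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 5, (10, 10, 10))
    fibers = [_line(rng.random(3) * 1.9, rng.random(3) * 1.9, 25) for _ in range(30)]
    m = parcel_connectivity(fibers, _pm_from_labels(labels), AFF)
    brute = np.zeros_like(m)
    for f in fibers:
        vis = set()
        for p in f:
            v = tuple(np.floor(p / VS).astype(int))
            if labels[v] > 0:
                vis.add(labels[v])
        for p in vis:
            for q in vis:
                if p != q:
                    brute[p, q] += 1
    np.testing.assert_array_equal(m, brute)


def test_cluster_parcels_block_structure():
    m = np.zeros((5, 5), dtype=float)  # parcels 1..4
    m[1, 2] = m[2, 1] = 10
    m[3, 4] = m[4, 3] = 8
    out = cluster_parcels(m, cut=0.9)
    sets = sorted(sorted(c.tolist()) for c in out)
    assert sets == [[1, 2], [3, 4]]
    assert [c.tolist() for c in cluster_parcels(np.zeros((2, 2)), 0.9)] == [[1]]
    singletons = cluster_parcels(np.zeros((4, 4)), 0.9)
    assert sorted(c.tolist()[0] for c in singletons) == [1, 2, 3]


def test_cluster_parcels_matches_naive_average_linkage():
    """Partition at the cut equals a naive agglomeration on 6 parcels."""
    rng = np.random.default_rng(5)
    m = rng.integers(0, 20, (7, 7))
    m = np.triu(m, 1)
    m = m + m.T
    cut = 0.6

    # naive average-linkage agglomeration on D = 1 - M/max(M)
    d = 1.0 - m[1:, 1:] / m[1:, 1:].max()
    groups = [[i] for i in range(6)]
    heights = {}
    while len(groups) > 1:
        best = None
        for x in range(len(groups)):
            for y in range(x + 1, len(groups)):
                avg = np.mean([d[i, j] for i in groups[x] for j in groups[y]])
                if best is None or avg < best[0]:
                    best = (avg, x, y)
        h, x, y = best
        if h > cut:
            break
        groups = (
            [g for q, g in enumerate(groups) if q not in (x, y)] + [groups[x] + groups[y]]
        )
    expected = sorted(sorted(np.array(g) + 1) for g in groups)
    got = sorted(sorted(c.tolist()) for c in cluster_parcels(m, cut))
    assert [list(map(int, g)) for g in expected] == got


# ---------------------------------------------------------------- assignment

def test_assign_fibers_rules():
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[0:5, :, :] = 1
    labels[5:10, :, :] = 2
    pm = _pm_from_labels(labels)
    inside = _line([0.1, 0.1, 0.1], [0.9, 0.9, 0.9], 20)  # fully parcel 1
    border = _line([0.65, 0.1, 0.1], [1.35, 0.1, 0.1], 20)  # ~50/50
    fibers = [inside] * 5 + [border]
    out = assign_fibers(
        fibers, np.arange(6), [np.array([1])], pm, AFF, min_frac=0.31, min_members=5
    )
    assert len(out) == 1
    assert set(out[0].member_indices) >= {0, 1, 2, 3, 4}

    # 30% overlap everywhere stays unassigned at the 31% rule
    mostly_out = _line([0.9, 0.1, 0.1], [1.9, 0.1, 0.1], 20)  # 3 of 20 pts in parcel 1
    frac = (np.floor(mostly_out[:, 0] / VS) < 5).mean()
    assert frac < 0.31
    out2 = assign_fibers(
        [mostly_out] * 5, np.arange(5), [np.array([1])], pm, AFF, 0.31, 5
    )
    assert out2 == []


def test_assign_fibers_matches_fraction_oracle():
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 5, (10, 10, 10))
    pm = _pm_from_labels(labels)
    pcl = [np.array([1, 2]), np.array([3, 4])]
    fibers = [_line(rng.random(3) * 1.9, rng.random(3) * 1.9, 30) for _ in range(60)]
    out = assign_fibers(fibers, np.arange(60), pcl, pm, AFF, 0.31, 1)
    assigned = {}
    for c_i, c in enumerate(out):
        for f in c.member_indices:
            assigned[f] = c_i
    for fi, f in enumerate(fibers):
        fr = []
        for parcels in pcl:
            hits = 0
            for p in f:
                v = tuple(np.floor(p / VS).astype(int))
                if labels[v] in parcels:
                    hits += 1
            fr.append(hits / len(f))
        best = int(np.argmax(fr))
        if fr[best] >= 0.31:
            assert assigned.get(fi) == best
        else:
            assert fi not in assigned


# ---------------------------------------------------------------- centroids

def test_centroid_of_parallel_fibers_is_middle():
    f0 = _line([0, 0, 0], [10, 0, 0])
    f1 = f0 + [0, 1, 0]
    f2 = f0 + [0, 2, 0]
    cl = FiberCluster(np.array([0, 1, 2]), np.array([1]), "LH", 0)
    c = compute_centroid(cl, [f0, f1, f2])
    assert c.member_index == 1


def test_mcp_distance_metric_properties():
    rng = np.random.default_rng(7)
    a, b = rng.random((12, 3)), rng.random((15, 3))
    assert mcp_distance(a, a) == 0.0
    assert mcp_distance(a, b) == pytest.approx(mcp_distance(b, a), rel=1e-12)


def test_centroid_matches_all_pairs_oracle():
    rng = np.random.default_rng(8)
    fibers = [_line(rng.random(3), rng.random(3) + 5, 15) for _ in range(10)]
    cl = FiberCluster(np.arange(10), np.array([1]), "LH", 0)
    got = compute_centroid(cl, fibers)
    d = np.array([[mcp_distance(x, y) for y in fibers] for x in fibers])
    expected = int((d.sum(axis=1) / 9).argmin())
    assert got.member_index == expected
    # singleton returns itself
    single = compute_centroid(FiberCluster(np.array([3]), np.array([1]), "LH", 0), fibers)
    assert single.member_index == 3


# ---------------------------------------------------------------- end to end

def test_planted_three_bundle_recovery():
    """Step 1 recovers three well-separated planted bundles with high purity."""
    spec = av.default_phantom_spec(seed=0, snr=None)
    spec.bundles = [
        BundleGeometry(b.name, b.centerline, b.radius, 60, b.region)
        for b in spec.bundles
    ]
    truth = av.build_phantom(spec)
    t = truth.streamlines
    lengths = t.lengths()
    window = (0.9 * lengths.min(), 1.1 * lengths.max())
    clusters, centroids = cluster_subject(
        t, truth.region_labels, window, subject_id="s0", seed=0
    )
    assert clusters, "no clusters recovered"
    recovered = set()
    for c in clusters:
        assert len(c.member_indices) >= 5
        planted = truth.bundle_of_streamline[c.member_indices]
        maj = np.bincount(planted).argmax()
        purity = (planted == maj).mean()
        assert purity >= 0.9
        recovered.add(int(maj))
    assert recovered == {0, 1, 2}
    for c, cen in zip(clusters, centroids):
        assert cen.member_index in c.member_indices


def test_pipeline_determinism_of_step1():
    spec = av.default_phantom_spec(seed=4, snr=None)
    truth = av.build_phantom(spec)
    t = truth.streamlines
    window = (0.1, 100.0)
    c1, cent1 = cluster_subject(t, truth.region_labels, window, seed=7)
    c2, cent2 = cluster_subject(t, truth.region_labels, window, seed=7)
    assert [c.member_indices.tolist() for c in c1] == [
        c.member_indices.tolist() for c in c2
    ]
    assert [c.member_index for c in cent1] == [c.member_index for c in cent2]
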