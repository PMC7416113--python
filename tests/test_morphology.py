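"""Morphometrics, hierarchical clustering, tilt, and circular statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from chromarg.morphology import (compute_tilt, hier_cluster, ks_two_sample,
                                 kuiper_two_sample, scale_ipl_depth,
                                 standardize_stats, summarize_morphology,
                                 summary_table, two_stage_cluster)
from chromarg.synthetic import MorphGenConfig, MorphPointCloud, \
    make_morph_cloud, spherical_to_cartesian


def brute_force_hull_area(xy: np.ndarray) -> float:
    """O(n^3)-ish convex-hull-area oracle for small point sets.

    A point is a hull vertex iff it lies strictly inside no triangle of
    other points (checked over all triples); the hull vertices are then
    ordered by angle about their centroid and the polygon area is taken
    with the shoelace formula.  Independent of scipy's Qhull.
    """
    n = xy.shape[0]
    if n < 3:
        return 0.0
    # a point is on the hull iff it is not strictly inside any triangle
    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def in_triangle(p, a, b, c):
        d1 = cross2(b - a, p - a)
        d2 = cross2(c - b, p - b)
        d3 = cross2(a - c, p - c)
        return (d1 > 1e-12) == (d2 > 1e-12) == (d3 > 1e-12) and \
            min(abs(d1), abs(d2), abs(d3)) > 1e-12
    hull_pts = []
    for i in range(n):
        inside = False
        for a in range(n):
            for b in range(a + 1, n):
                for c in range(b + 1, n):
                    if i in (a, b, c):
                        continue
                    if in_triangle(xy[i], xy[a], xy[b], xy[c]):
                        inside = True
                        break
                if inside:
                    break
            if inside:
                break
        if not inside:
            hull_pts.append(xy[i])
    hp = np.array(hull_pts)
    ctr = hp.mean(axis=0)
    ang = np.arctan2(hp[:, 1] - ctr[1], hp[:, 0] - ctr[0])
    hp = hp[np.argsort(ang)]
    x, y = hp[:, 0], hp[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestScaleIplDepth:
    def test_border_endpoints(self):
        pts = np.array([[0, 30.0, 0], [0, 50.0, 0], [0, 40.0, 0]])
        cloud = scale_ipl_depth(pts, soma=[0, 25.0, 0],
                                ipl_inner=30.0, ipl_outer=50.0)
        assert np.allclose(cloud.points[:, 1], [0.0, 10.0, 5.0])

    def test_beyond_border_exceeds_range(self):
        pts = np.array([[0, 55.0, 0]])
        cloud = scale_ipl_depth(pts, soma=[0, 25.0, 0],
                                ipl_inner=30.0, ipl_outer=50.0)
        assert cloud.points[0, 1] > 10

    def test_degenerate_borders_rejected(self):
        with pytest.raises(ValueError):
            scale_ipl_depth(np.zeros((1, 3)), [0, 0, 0], 5.0, 5.0)


class TestSummaries:
    def test_unit_square(self):
        pts = np.array([[0, 2, 0], [1, 2, 0], [1, 2, 1], [0, 2, 1]], float)
        s = summarize_morphology(MorphPointCloud(soma=[0, 0, 0], points=pts))
        assert s.xz_area == 1.0
        assert s.y_span == 0.0
        assert s.num_pts == 4

    def test_collinear_points_zero_area(self):
        pts = np.column_stack([np.arange(5.0), np.ones(5),
                               2 * np.arange(5.0)])
        s = summarize_morphology(MorphPointCloud(soma=[0, 0, 0], points=pts))
        assert s.xz_area == 0.0

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_hull_area_matches_brute_force(self, n, rng):
        for _ in range(10):
            pts = rng.uniform(-5, 5, (n, 3))
            s = summarize_morphology(
                MorphPointCloud(soma=[0, 0, 0], points=pts))
            oracle = brute_force_hull_area(pts[:, [0, 2]])
            assert np.isclose(s.xz_area, oracle, atol=1e-9)

    def test_translation_and_order_invariance(self, rng):
        pts = rng.uniform(0, 10, (30, 3))
        a = summarize_morphology(MorphPointCloud(soma=[0, 0, 0], points=pts))
        shifted = pts + np.array([100.0, 0.0, -40.0])
        b = summarize_morphology(
            MorphPointCloud(soma=[0, 0, 0], points=shifted[::-1]))
        assert np.isclose(a.xz_area, b.xz_area)
        assert np.isclose(a.y_span, b.y_span)


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame(rng.normal(3, 7, (20, 3)),
                          columns=["y_span", "y_mean", "num_pts"])
        z = standardize_stats(df)
        assert np.allclose(z.mean(), 0, atol=1e-9)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-9)

    def test_affine_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)),
                          columns=["y_span", "y_mean", "num_pts"])
        df2 = df.copy()
        df2["y_span"] = 5 * df2["y_span"] - 3
        assert np.allclose(standardize_stats(df).to_numpy(),
                           standardize_stats(df2).to_numpy())

    def test_two_cell_values(self):
        df = pd.DataFrame({"y_span": [1.0, 3.0], "y_mean": [0.0, 2.0],
                           "num_pts": [10, 20]})
        z = standardize_stats(df)
        # with the n-1 convention two cells map to -/+ 1/sqrt(2)
        assert np.allclose(np.abs(z.to_numpy()), 1 / np.sqrt(2))

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"y_span": [1.0, 1.0], "y_mean": [0.0, 2.0],
                           "num_pts": [1, 2]})
        with pytest.raises(ValueError):
            standardize_stats(df)


class TestHierCluster:
    def test_two_blobs_split_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (20, 3)),
                       rng.normal(10, 0.5, (20, 3))])
        df = pd.DataFrame(X, columns=["y_span", "y_mean", "num_pts"])
        labels, ccc, _ = hier_cluster(df, ("y_span", "y_mean", "num_pts"), 2)
        truth = np.repeat([0, 1], 20)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert -1 <= ccc <= 1

    def test_ultrametric_data_ccc_one(self):
        """Distances that are exactly ultrametric are represented
        perfectly by the tree, so CCC = 1; cross-checked with a naive
        cophenetic computation."""
        # isoceles L1 triangle: d01 = 2, d02 = d12 = 6 (ultrametric)
        df = pd.DataFrame({"y_span": [0.0, 2.0, 1.0],
                           "y_mean": [0.0, 0.0, 5.0]})
        _, ccc, _ = hier_cluster(df, ("y_span", "y_mean"), 2)
        d = pdist(df.to_numpy(), metric="cityblock")
        assert np.allclose(sorted(d), [2.0, 6.0, 6.0])
        # naive cophenetic tree: {0,1} merge at 2, join 2 at mean(6,6)=6
        naive = np.array([2.0, 6.0, 6.0])
        expected = np.corrcoef(naive, np.array([2.0, 6.0, 6.0]))[0, 1]
        assert np.isclose(ccc, expected, atol=1e-9)
        assert ccc > 1 - 1e-9

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        df = pd.DataFrame(X, columns=["y_span", "y_mean", "num_pts"])
        a = hier_cluster(df, ("y_span", "y_mean", "num_pts"), 5)
        b = hier_cluster(df, ("y_span", "y_mean", "num_pts"), 5)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_too_many_clusters_rejected(self):
        df = pd.DataFrame({"y_span": [1.0, 2.0]})
        with pytest.raises(ValueError):
            hier_cluster(df, ("y_span",), 5)


def _planted_morph_population(seed=0, n_per=35):
    """Four planted morphology types: narrow-low, narrow-high, diffuse,
    sparse."""
    rng = np.random.default_rng(seed)
    types = [
        dict(y_mean=2.0, y_span=0.8, n=(200, 300)),   # narrow, inner
        dict(y_mean=8.0, y_span=0.8, n=(200, 300)),   # narrow, outer
        dict(y_mean=5.0, y_span=6.0, n=(200, 300)),   # diffuse
        dict(y_mean=5.0, y_span=2.0, n=(20, 40)),     # sparse
    ]
    clouds, labels = [], []
    for i, t in enumerate(types):
        for _ in range(n_per):
            cfg = MorphGenConfig(
                n_points=int(rng.integers(*t["n"])),
                y_mean=t["y_mean"] + float(rng.normal(0, 0.3)),
                y_span=t["y_span"] * float(rng.uniform(0.8, 1.2)),
                tilt_r=float(rng.uniform(2, 8)),
                tilt_theta=float(rng.uniform(0, np.pi / 2)),
                tilt_phi=float(rng.uniform(0, 2 * np.pi)),
                seed=int(rng.integers(2**31)))
            clouds.append(make_morph_cloud(cfg))
            labels.append(i)
    return clouds, np.array(labels)


class TestTwoStage:
    def test_default_splits_give_25_clusters(self):
        clouds, _ = _planted_morph_population()
        res = two_stage_cluster(summary_table(clouds), stage1_k=18)
        assert res.n_total == 25  # 18 - 2 + 6 + 3

    def test_min_members_one_presents_all(self):
        clouds, _ = _planted_morph_population(seed=3, n_per=20)
        res = two_stage_cluster(summary_table(clouds), stage1_k=12,
                                split_spec={}, min_members=1)
        assert res.presentation == list(range(res.n_total))

    def test_planted_types_majority_pure(self):
        clouds, truth = _planted_morph_population(seed=5)
        res = two_stage_cluster(summary_table(clouds), stage1_k=18)
        for t in range(4):
            purities = []
            for c in range(res.n_total):
                members = truth[res.labels == c]
                if members.size:
                    purities.append((members == t).mean())
            assert max(purities) > 0.5

    def test_absent_split_target_rejected(self):
        clouds, _ = _planted_morph_population(n_per=10)
        with pytest.raises(ValueError):
            two_stage_cluster(summary_table(clouds), stage1_k=5,
                              split_spec={99: 3})


class TestTilt:
    def test_pure_y_offset_no_tilt(self):
        cloud = MorphPointCloud(soma=[0, 0, 0], points=[[0, 5.0, 0]])
        t = compute_tilt(cloud)
        assert t.theta == 0.0 and np.isclose(t.r, 5.0)

    def test_in_plane_offset_is_right_angle(self):
        cloud = MorphPointCloud(soma=[0, 0, 0], points=[[5.0, 0, 0]])
        assert np.isclose(compute_tilt(cloud).theta, np.pi / 2)

    def test_opposite_x_phi_differs_by_pi(self):
        a = compute_tilt(MorphPointCloud(soma=[0, 0, 0],
                                         points=[[5.0, 1, 0]]))
        b = compute_tilt(MorphPointCloud(soma=[0, 0, 0],
                                         points=[[-5.0, 1, 0]]))
        assert np.isclose(abs(a.phi - b.phi), np.pi)

    def test_com_at_soma_undefined(self):
        cloud = MorphPointCloud(soma=[1, 2, 3], points=[[1, 2, 3]])
        t = compute_tilt(cloud)
        assert not t.defined and np.isnan(t.theta)

    @given(st.floats(0.5, 20), st.floats(0.01, np.pi - 0.01),
           st.floats(0, 2 * np.pi - 1e-6))
    @settings(max_examples=100, deadline=None)
    def test_spherical_round_trip(self, r, theta, phi):
        pt = spherical_to_cartesian(r, theta, phi)
        t = compute_tilt(MorphPointCloud(soma=[0, 0, 0], points=[pt]))
        assert np.isclose(t.r, r, rtol=1e-9)
        assert np.isclose(t.theta, theta, atol=1e-9)
        # phi undefined at the poles
        if 1e-6 < theta < np.pi - 1e-6:
            dphi = (t.phi - phi) % (2 * np.pi)
            assert min(dphi, 2 * np.pi - dphi) < 1e-6


class TestTwoSampleTests:
    def test_ks_identical_samples(self, rng):
        x = rng.normal(size=50)
        d, p = ks_two_sample(x, x)
        assert d == 0 and p == 1

    def test_ks_disjoint_supports(self, rng):
        d, _ = ks_two_sample(rng.uniform(0, 1, 40), rng.uniform(5, 6, 40))
        assert d == 1

    def test_ks_monotone_transform_invariant(self, rng):
        a, b = rng.normal(size=60), rng.normal(1, 2, 70)
        d1, p1 = ks_two_sample(a, b)
        d2, p2 = ks_two_sample(np.exp(a), np.exp(b))
        assert np.isclose(d1, d2) and np.isclose(p1, p2)

    def test_kuiper_identical_samples(self, rng):
        x = rng.uniform(0, 2 * np.pi, 50)
        v, p = kuiper_two_sample(x, x)
        assert v <= 2 / 50 + 1e-12
        assert p > 0.9

    @given(st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_kuiper_rotation_invariant(self, shift):
        rng = np.random.default_rng(99)
        a = rng.vonmises(1.0, 2.0, 40)
        b = rng.vonmises(2.0, 1.0, 50)
        v1, p1 = kuiper_two_sample(a, b)
        v2, p2 = kuiper_two_sample(a + shift, b + shift)
        assert np.isclose(v1, v2, atol=1e-12)
        assert np.isclose(p1, p2, atol=1e-12)

    def test_kuiper_detects_opposite_von_mises(self):
        rng = np.random.default_rng(4)
        a = rng.vonmises(0.0, 2.0, 60) % (2 * np.pi)
        b = rng.vonmises(np.pi, 2.0, 60) % (2 * np.pi)
        _, p = kuiper_two_sample(a, b)
        assert p < 0.01
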