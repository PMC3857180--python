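import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colonyloc import locstats as ls
from colonyloc import segmentation as seg
from conftest import make_disc_colony, make_ellipse_colony


# ---------------------------------------------------------------------------
# distance_to_centroid
# ---------------------------------------------------------------------------

def test_distance_zero_at_centroid():
    assert ls.distance_to_centroid((3.0, 4.0), (3.0, 4.0)) == 0.0


def test_three_four_five():
    assert ls.distance_to_centroid((13.0, 14.0), (10.0, 10.0)) == 5.0


@given(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
       st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)))
def test_distance_matches_hypot_oracle(p, c):
    expected = np.hypot(p[0] - c[0], p[1] - c[1])
    assert abs(ls.distance_to_centroid(p, c) - expected) <= 1e-12 * max(1, expected)


# ---------------------------------------------------------------------------
# edge_intersection
# ---------------------------------------------------------------------------

def test_disc_edge_distance_is_radius(disc_colony):
    rng = np.random.default_rng(2)
    for _ in range(20):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(1, 15)
        p = (disc_colony.centroid[0] + r * np.cos(ang),
             disc_colony.centroid[1] + r * np.sin(ang))
        b, d_edge = ls.edge_intersection(disc_colony.centroid, p,
                                         disc_colony.boundary)
        assert abs(d_edge - 20.0) <= 1.0


def test_square_diagonal_edge_distance():
    """Oracle: exact ray-square intersection; diagonal hits the corner at a*sqrt(2)."""
    a = 15
    mask = np.zeros((41, 41), bool)
    mask[5:5 + 2 * a + 1, 5:5 + 2 * a + 1] = True
    colony = seg.colony_from_mask(mask)
    c = colony.centroid
    p = (c[0] + 3.0, c[1] + 3.0)  # on the diagonal
    _, d_edge = ls.edge_intersection(c, p, colony.boundary)
    assert abs(d_edge - a * np.sqrt(2)) <= 1.5


def test_edge_point_is_boundary_member(disc_colony):
    p = (disc_colony.centroid[0] + 5, disc_colony.centroid[1] - 2)
    b, _ = ls.edge_intersection(disc_colony.centroid, p, disc_colony.boundary)
    assert any(np.allclose(b, q) for q in disc_colony.boundary)


def test_centroid_ray_undefined(disc_colony):
    with pytest.raises(ValueError):
        ls.edge_intersection(disc_colony.centroid, disc_colony.centroid,
                             disc_colony.boundary)


# ---------------------------------------------------------------------------
# normalize_distance / normalized_distances
# ---------------------------------------------------------------------------

def test_normalize_distance_arithmetic():
    assert ls.normalize_distance(0.0, 4.0) == 0.0
    assert ls.normalize_distance(2.0, 4.0) == 0.5
    assert ls.normalize_distance(4.4, 4.0) == 1.0  # clamped
    with pytest.raises(ValueError):
        ls.normalize_distance(1.0, 0.0)


@pytest.mark.parametrize("ecc", [0.0, 0.3, 0.6])
def test_delta_invariants_on_ellipses(ecc):
    a = 40.0
    colony, shape = make_ellipse_colony(a, a * np.sqrt(1 - ecc**2), rotation=0.6)
    assert ls.normalized_distances(np.array([colony.centroid]), colony)[0] == 0.0
    angs = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    ct, st_ = np.cos(shape.rotation), np.sin(shape.rotation)
    bx = shape.center[0] + ct * a * np.cos(angs) - st_ * shape.semi_axes[1] * np.sin(angs)
    by = shape.center[1] + st_ * a * np.cos(angs) + ct * shape.semi_axes[1] * np.sin(angs)
    deltas = ls.normalized_distances(np.column_stack([bx, by]), colony)
    assert np.all(deltas >= 0.98) and np.all(deltas <= 1.0)


# ---------------------------------------------------------------------------
# truncate_extremes
# ---------------------------------------------------------------------------

def test_truncate_noop_below_cut():
    d = [0.1, 0.5, 0.94]
    assert np.array_equal(ls.truncate_extremes(d, 0.95), d)


def test_truncate_filters_extremes():
    out = ls.truncate_extremes([0.2, 0.96, 0.99], 0.95)
    assert np.array_equal(out, [0.2])


def test_truncate_matches_brute_force_count(rng):
    vals = rng.uniform(0, 1, 1000)
    out = ls.truncate_extremes(vals, 0.9)
    expected = sum(1 for v in vals if v < 0.9)
    assert len(out) == expected


def test_truncate_invalid_cut():
    with pytest.raises(ValueError):
        ls.truncate_extremes([0.5], 1.0)


# ---------------------------------------------------------------------------
# mutual_distances
# ---------------------------------------------------------------------------

def test_two_cells_mutual():
    pts = np.array([[0.0, 0.0], [3.0, 4.0]])
    out = ls.mutual_distances(pts, 10.0)
    assert out.shape == (1,)
    assert np.isclose(out[0], 0.5)


def test_pair_count_combinatorics(rng):
    pts = rng.uniform(0, 50, (5, 2))
    assert len(ls.mutual_distances(pts, 30.0)) == 10


def test_mutual_matches_all_pairs_loop(rng):
    """Oracle: O(n^2) recomputation."""
    pts = rng.uniform(0, 100, (12, 2))
    m = 40.0
    got = sorted(ls.mutual_distances(pts, m))
    expected = sorted(
        np.hypot(*(pts[i] - pts[j])) / m
        for i in range(12) for j in range(i + 1, 12))
    assert np.allclose(got, expected)


def test_single_cell_empty():
    assert len(ls.mutual_distances(np.array([[1.0, 2.0]]), 10.0)) == 0


# ---------------------------------------------------------------------------
# generate_null_points
# ---------------------------------------------------------------------------

def test_null_count_and_containment(disc_colony):
    null = ls.generate_null_points(disc_colony, n_real=37, multiplier=10, seed=5)
    assert len(null.points) == 370
    px = null.points[:, 0].astype(int)
    py = null.points[:, 1].astype(int)
    assert disc_colony.mask[py, px].all()


def test_null_single_pixel_colony():
    mask = np.zeros((9, 9), bool)
    mask[3, 5] = True
    colony = seg.colony_from_mask(mask)
    null = ls.generate_null_points(colony, n_real=4, multiplier=10, seed=1)
    assert len(null.points) == 40
    assert np.all(null.points[:, 0].astype(int) == 5)
    assert np.all(null.points[:, 1].astype(int) == 3)


def test_null_determinism(disc_colony):
    a = ls.generate_null_points(disc_colony, 10, 10, seed=7)
    b = ls.generate_null_points(disc_colony, 10, 10, seed=7)
    c = ls.generate_null_points(disc_colony, 10, 10, seed=8)
    assert np.array_equal(a.points, b.points)
    assert not np.array_equal(a.points, c.points)


def test_null_uniformity_chi_square():
    """Oracle: accepted rejection-sampling draws are uniform over the disc."""
    from scipy import stats

    colony = make_disc_colony(30)
    cx, cy = (int(colony.centroid[0]), int(colony.centroid[1]))
    mask = colony.mask
    # expected quadrant masses from the mask pixel counts themselves
    exp = np.array([mask[:cy, :cx].sum(), mask[:cy, cx:].sum(),
                    mask[cy:, :cx].sum(), mask[cy:, cx:].sum()], dtype=float)
    passes = 0
    for s in range(100):
        pts = ls.generate_null_points(colony, 400, 10, seed=s).points
        q = [
            np.sum((pts[:, 0] < cx) & (pts[:, 1] < cy)),
            np.sum((pts[:, 0] >= cx) & (pts[:, 1] < cy)),
            np.sum((pts[:, 0] < cx) & (pts[:, 1] >= cy)),
            np.sum((pts[:, 0] >= cx) & (pts[:, 1] >= cy)),
        ]
        if stats.chisquare(q, exp / exp.sum() * 4000).pvalue > 0.01:
            passes += 1
    assert passes >= 95


def test_null_invalid_args(disc_colony):
    with pytest.raises(ValueError):
        ls.generate_null_points(disc_colony, 0, 10, seed=0)


# ---------------------------------------------------------------------------
# ks_two_sample
# ---------------------------------------------------------------------------

def brute_force_ks_d(a, b):
    pooled = np.concatenate([a, b])
    d = 0.0
    for t in pooled:
        fa = np.mean(np.asarray(a) <= t)
        fb = np.mean(np.asarray(b) <= t)
        d = max(d, abs(fa - fb))
    return d


def test_identical_samples():
    r = ls.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_disjoint_supports():
    r = ls.ks_two_sample([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert r.statistic == 1.0
    assert r.p_value < 0.15


def test_ks_matches_brute_force(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(0.5, 1.2, 35)
    r = ls.ks_two_sample(a, b)
    assert abs(r.statistic - brute_force_ks_d(a, b)) <= 1e-12


def test_ks_matches_scipy_statistic(rng):
    from scipy import stats

    for _ in range(10):
        a = rng.uniform(0, 1, rng.integers(5, 50))
        b = rng.uniform(0, 1, rng.integers(5, 50))
        r = ls.ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert abs(r.statistic - ref.statistic) <= 1e-12


def test_ks_empty_sample_raises():
    with pytest.raises(ValueError):
        ls.ks_two_sample([], [1.0])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10),
       st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10))
def test_ks_oracle_property(a, b):
    r = ls.ks_two_sample(a, b)
    assert abs(r.statistic - brute_force_ks_d(a, b)) <= 1e-12
    assert 0.0 <= r.p_value <= 1.0


# ---------------------------------------------------------------------------
# smooth_distribution
# ---------------------------------------------------------------------------

def test_smooth_constant_unchanged():
    assert np.allclose(ls.smooth_distribution([2.0] * 7, 3), 2.0)


def test_smooth_shrinking_window_edges():
    out = ls.smooth_distribution([0.0, 3.0, 0.0], 3)
    assert np.allclose(out, [1.5, 1.0, 1.5])


def test_smooth_interior_matches_windowed_mean(rng):
    h = rng.uniform(0, 10, 20)
    out = ls.smooth_distribution(h, 3)
    for i in range(1, 19):
        assert np.isclose(out[i], h[i - 1:i + 2].mean())


def test_smooth_even_window_rejected():
    with pytest.raises(ValueError):
        ls.smooth_distribution([1.0, 2.0], 2)


# ---------------------------------------------------------------------------
# classify_location
# ---------------------------------------------------------------------------

def test_identical_real_and_null_is_non_preferential(rng):
    deltas = rng.uniform(0, 0.9, 200)
    mhat = rng.uniform(0, 1, 150)
    rep = ls.classify_location(deltas, deltas.copy(), mhat, mhat.copy())
    assert rep.label_location == "NON_PREFERENTIAL"
    assert rep.label_radial == "NONE"
    assert rep.label_cluster == "NON_CLUSTERED"
    assert rep.centroid_ks.statistic == 0.0


def test_radial_sublabel_requires_preferential(rng):
    real = rng.uniform(0, 0.3, 400)
    null = rng.uniform(0, 0.9, 4000)
    rep = ls.classify_location(real, null, rng.uniform(0, 0.3, 300),
                               rng.uniform(0, 1, 3000))
    assert rep.label_location == "PREFERENTIAL"
    assert rep.label_radial == "INNER"
    assert rep.label_cluster == "CLUSTERED"


def test_small_sample_warning(rng):
    rep = ls.classify_location(rng.uniform(0, 1, 10), rng.uniform(0, 1, 100),
                               rng.uniform(0, 1, 10), rng.uniform(0, 1, 100))
    assert any("30" in w or "few hundred" in w for w in rep.warnings)


def test_report_serializable(rng):
    import json

    rep = ls.classify_location(rng.uniform(0, 1, 50), rng.uniform(0, 1, 500),
                               rng.uniform(0, 1, 40), rng.uniform(0, 1, 400))
    s = json.dumps(rep.to_dict())
    assert "label_location" in s
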