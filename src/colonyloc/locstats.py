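"""Intra-colony location statistics and the Monte-Carlo null classification.

Each detected cell is mapped to a normalized centroid distance delta in
[0, 1]: its Euclidean distance to the colony centroid divided by the
centroid-to-edge distance along the same ray (0 at the centre, 1 on the
edge).  Mutual distances between cells of one colony are normalized by the
colony major axis.  Both observed distributions are compared, via two-sample
Kolmogorov-Smirnov tests, against a null model in which each colony is
repopulated uniformly at random (rejection sampling in its bounding box)
with ten times the observed number of points; the test outcomes yield the
labels PREFERENTIAL / NON_PREFERENTIAL, INNER / OUTER and CLUSTERED /
NON_CLUSTERED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .segmentation import Colony

__all__ = [
    "KSResult", "NullSample", "LocationReport",
    "distance_to_centroid", "edge_intersection", "normalize_distance",
    "normalized_distances", "truncate_extremes", "mutual_distances",
    "generate_null_points", "ks_two_sample", "smooth_distribution",
    "classify_location",
]

DEFAULT_ALPHA = 0.001
DEFAULT_NULL_MULTIPLIER = 10
DEFAULT_LOWER_CUT = 0.95
DEFAULT_SMOOTH_WINDOW = 3


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_real: int
    n_null: int


@dataclass
class NullSample:
    colony_label: int
    points: np.ndarray  # (n, 2) float array of (x, y)
    multiplier: int
    seed: int


@dataclass
class LocationReport:
    alpha: float
    centroid_ks: KSResult
    mutual_ks: KSResult | None
    mean_delta_real: float
    mean_delta_null: float
    mean_mhat_real: float | None
    mean_mhat_null: float | None
    label_location: str
    label_radial: str
    label_cluster: str
    truncation_lower_cut: float = DEFAULT_LOWER_CUT
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def ks(r):
            if r is None:
                return None
            return {"statistic": r.statistic, "p_value": r.p_value,
                    "n_real": r.n_real, "n_null": r.n_null}
        return {
            "alpha": self.alpha,
            "centroid_ks": ks(self.centroid_ks),
            "mutual_ks": ks(self.mutual_ks),
            "mean_delta_real": self.mean_delta_real,
            "mean_delta_null": self.mean_delta_null,
            "mean_mhat_real": self.mean_mhat_real,
            "mean_mhat_null": self.mean_mhat_null,
            "label_location": self.label_location,
            "label_radial": self.label_radial,
            "label_cluster": self.label_cluster,
            "truncation_lower_cut": self.truncation_lower_cut,
            "smoothing_window": self.smoothing_window,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# normalized centroid distance
# ---------------------------------------------------------------------------

def distance_to_centroid(point: tuple[float, float],
                         centroid: tuple[float, float]) -> float:
    return math.hypot(point[0] - centroid[0], point[1] - centroid[1])


def edge_intersection(centroid: tuple[float, float], point: tuple[float, float],
                      boundary: np.ndarray) -> tuple[tuple[float, float], float]:
    """Edge point on the centroid->point ray and its distance to the centroid.

    The winner is the boundary point whose direction from the centroid has
    maximal cosine similarity with (point - centroid); ties go to the
    outermost candidate.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.size == 0:
        raise ValueError("boundary set is empty")
    ux, uy = point[0] - centroid[0], point[1] - centroid[1]
    un = math.hypot(ux, uy)
    if un == 0:
        raise ValueError("point coincides with the centroid: ray undefined")
    v = boundary - np.asarray(centroid, dtype=float)
    vn = np.hypot(v[:, 0], v[:, 1])
    vn_safe = np.maximum(vn, 1e-12)
    cos = (v[:, 0] * ux + v[:, 1] * uy) / (vn_safe * un)
    best_cos = cos.max()
    tied = np.nonzero(cos >= best_cos - 1e-12)[0]
    winner = tied[np.argmax(vn[tied])]
    b = (float(boundary[winner, 0]), float(boundary[winner, 1]))
    return b, float(vn[winner])


def normalize_distance(d: float, d_edge: float) -> float:
    """delta = min(d / D, 1); D = 0 denotes a degenerate colony."""
    if d_edge <= 0:
        raise ValueError("degenerate colony: centroid-to-edge distance is zero")
    return min(d / d_edge, 1.0)


def normalized_distances(points: np.ndarray, colony: Colony) -> np.ndarray:
    """Vectorized delta for many (x, y) points in one colony.

    Points exactly at the centroid get delta = 0 without a ray search.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(colony.centroid, dtype=float)
    u = points - c
    un = np.hypot(u[:, 0], u[:, 1])
    v = colony.boundary - c
    vn = np.hypot(v[:, 0], v[:, 1])
    vn_safe = np.maximum(vn, 1e-12)
    # cosine similarity matrix (n_points x n_boundary)
    cos = (u @ v.T) / (np.maximum(un, 1e-12)[:, None] * vn_safe[None, :])
    best = cos.max(axis=1, keepdims=True)
    tied = cos >= best - 1e-12
    radii = np.where(tied, vn[None, :], -np.inf)
    d_edge = radii.max(axis=1)
    delta = np.where(un == 0, 0.0, np.minimum(un / np.maximum(d_edge, 1e-12), 1.0))
    return delta


def truncate_extremes(deltas, lower_cut: float = DEFAULT_LOWER_CUT) -> np.ndarray:
    """Drop normalized distances >= lower_cut (unreliable segmentation fringe)."""
    if not (0.0 < lower_cut < 1.0):
        raise ValueError("lower_cut must be in (0, 1)")
    deltas = np.asarray(deltas, dtype=float)
    return deltas[deltas < lower_cut]


# ---------------------------------------------------------------------------
# mutual distances
# ---------------------------------------------------------------------------

def mutual_distances(points: np.ndarray, major_axis_px: float) -> np.ndarray:
    """All n(n-1)/2 pairwise distances, normalized by the colony major axis.

    Fewer than 2 points yields an empty array.
    """
    if major_axis_px <= 0:
        raise ValueError("major_axis_px must be > 0")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        return np.empty(0)
    return pdist(points) / major_axis_px


# ---------------------------------------------------------------------------
# Monte-Carlo null model
# ---------------------------------------------------------------------------

def generate_null_points(colony: Colony, n_real: int,
                         multiplier: int = DEFAULT_NULL_MULTIPLIER,
                         seed: int = 0) -> NullSample:
    """Uniform rejection sampling in the colony bounding box.

    Continuous coordinate pairs are drawn uniformly in the bbox; a draw is
    kept iff its containing pixel is on the colony mask, until exactly
    ``multiplier * n_real`` points are retained.  Deterministic for a seed.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    mask = colony.mask
    if not mask.any():
        raise ValueError("colony mask is empty")
    x_min, y_min, x_max, y_max = colony.bbox
    target = multiplier * n_real
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    n_acc = 0
    drawn = 0
    budget = max(int(target / 1e-3), 10000)
    while n_acc < target:
        batch = max(target - n_acc, 256) * 2
        if drawn > budget:
            raise RuntimeError(
                f"null sampling acceptance rate below 1e-3 after {drawn} draws: "
                f"pathological colony mask (label {colony.label})")
        xs = rng.uniform(x_min, x_max + 1.0, size=batch)
        ys = rng.uniform(y_min, y_max + 1.0, size=batch)
        drawn += batch
        px = np.clip(xs.astype(int), 0, mask.shape[1] - 1)
        py = np.clip(ys.astype(int), 0, mask.shape[0] - 1)
        ok = mask[py, px]
        pts = np.column_stack([xs[ok], ys[ok]])
        accepted.append(pts)
        n_acc += len(pts)
    points = np.vstack(accepted)[:target]
    return NullSample(colony_label=colony.label, points=points,
                      multiplier=multiplier, seed=seed)


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_two_sample(sample_a, sample_b) -> KSResult:
    """Two-sample KS statistic and asymptotic p-value.

    D is the supremum over pooled sample points of the ECDF difference; the
    p-value uses the Kolmogorov series with the small-sample correction
    lambda = (sqrt(n_eff) + 0.12 + 0.11/sqrt(n_eff)) * D,
    n_eff = n_a*n_b/(n_a+n_b), truncated at 100 terms and clamped to [0, 1].
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())

    n_eff = a.size * b.size / (a.size + b.size)
    lam = (math.sqrt(n_eff) + 0.12 + 0.11 / math.sqrt(n_eff)) * d
    if lam < 1e-2:
        p = 1.0
    else:
        k = np.arange(1, 101)
        terms = 2.0 * (-1.0) ** (k - 1) * np.exp(-2.0 * (k * lam) ** 2)
        p = float(np.clip(terms.sum(), 0.0, 1.0))
    return KSResult(statistic=d, p_value=p, n_real=int(a.size), n_null=int(b.size))


def smooth_distribution(histogram, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges.

    Display-only smoothing of density curves; statistical tests always run on
    the raw samples.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    h = np.asarray(histogram, dtype=float)
    half = window // 2
    out = np.empty_like(h)
    for i in range(h.size):
        lo, hi = max(0, i - half), min(h.size, i + half + 1)
        out[i] = h[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_location(real_deltas, null_deltas, real_mhat, null_mhat,
                      alpha: float = DEFAULT_ALPHA,
                      lower_cut: float = DEFAULT_LOWER_CUT,
                      smoothing_window: int = DEFAULT_SMOOTH_WINDOW) -> LocationReport:
    """Three-way location labeling of pooled samples against their null.

    PREFERENTIAL iff the centroid-distance KS p-value is below alpha; then
    INNER/OUTER by comparing the real and null delta means.  CLUSTERED iff
    the mutual-distance KS p-value is below alpha AND the real mean mutual
    distance is smaller than the null one.  Delta samples are expected to be
    truncated already (identically for real and null).
    """
    real_deltas = np.asarray(real_deltas, dtype=float)
    null_deltas = np.asarray(null_deltas, dtype=float)
    warnings: list[str] = []
    if real_deltas.size < 30:
        warnings.append(
            f"only {real_deltas.size} pooled real observations; KS reliability "
            "requires on the order of a few hundred samples")

    centroid_ks = ks_two_sample(real_deltas, null_deltas)
    preferential = centroid_ks.p_value < alpha
    label_location = "PREFERENTIAL" if preferential else "NON_PREFERENTIAL"
    mean_real = float(real_deltas.mean())
    mean_null = float(null_deltas.mean())
    if preferential:
        label_radial = "INNER" if mean_real < mean_null else "OUTER"
    else:
        label_radial = "NONE"

    real_mhat = np.asarray(real_mhat, dtype=float)
    null_mhat = np.asarray(null_mhat, dtype=float)
    if real_mhat.size == 0 or null_mhat.size == 0:
        mutual_ks = None
        mean_mhat_real = mean_mhat_null = None
        label_cluster = "NON_CLUSTERED"
        warnings.append("no mutual-distance pairs available; cluster test skipped")
    else:
        mutual_ks = ks_two_sample(real_mhat, null_mhat)
        mean_mhat_real = float(real_mhat.mean())
        mean_mhat_null = float(null_mhat.mean())
        if mutual_ks.p_value < alpha and mean_mhat_real < mean_mhat_null:
            label_cluster = "CLUSTERED"
        else:
            label_cluster = "NON_CLUSTERED"
            if mutual_ks.p_value < alpha:
                warnings.append(
                    "mutual distances differ significantly from the null but the "
                    "real mean is larger (over-dispersion): labeled NON_CLUSTERED")

    return LocationReport(
        alpha=alpha,
        centroid_ks=centroid_ks,
        mutual_ks=mutual_ks,
        mean_delta_real=mean_real,
        mean_delta_null=mean_null,
        mean_mhat_real=mean_mhat_real,
        mean_mhat_null=mean_mhat_null,
        label_location=label_location,
        label_radial=label_radial,
        label_cluster=label_cluster,
        truncation_lower_cut=lower_cut,
        smoothing_window=smoothing_window,
        warnings=warnings,
    )
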