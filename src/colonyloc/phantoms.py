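"""Synthetic colony images and point patterns with controllable spatial structure.

Phantoms render quasi-circular (elliptical) colonies on a flat background and
populate them with roughly circular marked-cell spots whose radial placement
follows one of three laws: ``uniform`` over the colony, ``inner_clustered``
(density decaying with normalized centroid distance) or ``edge_biased``
(density decaying towards the centre).  Every generated object is recorded in
a :class:`GroundTruth` so downstream stages can be scored exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PhantomSpec",
    "ColonyShape",
    "GroundTruth",
    "PhantomPlacementError",
    "make_colony_phantom",
    "make_point_phantom",
    "ground_truth_colony_mask",
    "exact_normalized_distance",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
]

_PLACEMENTS = ("uniform", "inner_clustered", "edge_biased")
_POLARITIES = ("dark", "bright")

#: attempts allowed per colony / per spot before placement is declared infeasible
PLACEMENT_RETRY_BUDGET = 1000


class PhantomPlacementError(RuntimeError):
    """Raised when rejection placement exhausts its retry budget."""


@dataclass(frozen=True)
class ColonyShape:
    """One generated colony: an ellipse in pixel coordinates (x = column)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b), a >= b
    rotation: float  # radians, major-axis angle w.r.t. +x


@dataclass
class GroundTruth:
    """Exact record of what a phantom image contains."""

    colonies: list[ColonyShape] = field(default_factory=list)
    spots: list[tuple[int, tuple[float, float], float]] = field(default_factory=list)
    # each spot: (colony_index, (x, y), radius)


@dataclass
class PhantomSpec:
    image_height_px: int = 256
    image_width_px: int = 256
    n_colonies: int = 3
    colony_radius_range_px: tuple[float, float] = (30.0, 45.0)
    colony_eccentricity_max: float = 0.4
    n_spots_per_colony: int = 4
    spot_radius_range_px: tuple[float, float] = (6.0, 8.0)
    spot_polarity: str = "dark"
    placement: str = "uniform"
    placement_concentration: float = 3.0
    #: minimum centre-to-centre distance between spots of one colony
    #: (0 = overlap allowed; required for dense placements like n=200)
    spot_min_separation_px: float = 0.0
    background_level: float = 200.0
    colony_level: float = 130.0
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px < 8 or self.image_width_px < 8:
            raise ValueError("image dimensions must be >= 8 px")
        if self.n_colonies < 0 or self.n_spots_per_colony < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.colony_radius_range_px
        if not (0 < lo <= hi):
            raise ValueError("colony_radius_range_px must satisfy 0 < lo <= hi")
        slo, shi = self.spot_radius_range_px
        if not (0 < slo <= shi):
            raise ValueError("spot_radius_range_px must satisfy 0 < lo <= hi")
        if shi >= lo:
            raise ValueError("spot radii must lie strictly inside the colony radius lower bound")
        if not (0.0 <= self.colony_eccentricity_max < 1.0):
            raise ValueError("colony_eccentricity_max must be in [0, 1)")
        if self.spot_polarity not in _POLARITIES:
            raise ValueError(f"spot_polarity must be one of {_POLARITIES}")
        if self.placement not in _PLACEMENTS:
            raise ValueError(f"placement must be one of {_PLACEMENTS}")
        if self.placement_concentration <= 0:
            raise ValueError("placement_concentration must be > 0")
        for name in ("background_level", "colony_level"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must be in [0, 255]")
        if self.noise_sd < 0 or self.illumination_gradient < 0:
            raise ValueError("noise_sd and illumination_gradient must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["colony_radius_range_px"] = list(self.colony_radius_range_px)
        d["spot_radius_range_px"] = list(self.spot_radius_range_px)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["colony_radius_range_px"] = tuple(d["colony_radius_range_px"])
        d["spot_radius_range_px"] = tuple(d["spot_radius_range_px"])
        spec = cls(**d)
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# ellipse geometry helpers (exact, used both for rendering and as oracle)
# ---------------------------------------------------------------------------

def _ellipse_frame(colony: ColonyShape, x, y):
    """Rotate image coordinates into the colony's principal-axis frame."""
    cx, cy = colony.center
    ct, st = math.cos(colony.rotation), math.sin(colony.rotation)
    dx, dy = np.asarray(x) - cx, np.asarray(y) - cy
    return ct * dx + st * dy, -st * dx + ct * dy


def _radial_coordinate(colony: ColonyShape, x, y):
    """u such that u = 1 on the ellipse boundary, < 1 inside."""
    a, b = colony.semi_axes
    xr, yr = _ellipse_frame(colony, x, y)
    return np.sqrt((xr / a) ** 2 + (yr / b) ** 2)


def exact_normalized_distance(colony: ColonyShape, point: tuple[float, float]) -> float:
    """Normalized centroid distance of ``point`` using exact ellipse geometry.

    Equals |P - C| divided by the distance from C to the ellipse boundary
    along the ray through P; identical to the ellipse radial coordinate.
    """
    return float(_radial_coordinate(colony, point[0], point[1]))


def _centre_to_edge_distance(colony: ColonyShape, ux: float, uy: float) -> float:
    """Distance from the colony centre to its boundary along unit ray (ux, uy)."""
    a, b = colony.semi_axes
    ct, st = math.cos(colony.rotation), math.sin(colony.rotation)
    rx, ry = ct * ux + st * uy, -st * ux + ct * uy
    return 1.0 / math.sqrt((rx / a) ** 2 + (ry / b) ** 2)


def ground_truth_colony_mask(colony: ColonyShape, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the colony ellipse on an image grid of ``shape`` (h, w)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return _radial_coordinate(colony, xx, yy) <= 1.0


# ---------------------------------------------------------------------------
# colony / spot placement
# ---------------------------------------------------------------------------

def _place_colonies(spec: PhantomSpec, rng: np.random.Generator) -> list[ColonyShape]:
    placed: list[ColonyShape] = []
    lo, hi = spec.colony_radius_range_px
    for i in range(spec.n_colonies):
        for _ in range(PLACEMENT_RETRY_BUDGET):
            a = rng.uniform(lo, hi)
            ecc = rng.uniform(0.0, spec.colony_eccentricity_max)
            b = a * math.sqrt(1.0 - ecc**2)
            theta = rng.uniform(0.0, math.pi)
            margin = a + 3.0
            if (2 * margin >= spec.image_width_px - 1) or (2 * margin >= spec.image_height_px - 1):
                continue
            cx = rng.uniform(margin, spec.image_width_px - 1 - margin)
            cy = rng.uniform(margin, spec.image_height_px - 1 - margin)
            ok = True
            for other in placed:
                dist = math.hypot(cx - other.center[0], cy - other.center[1])
                if dist <= a + other.semi_axes[0] + 4.0:
                    ok = False
                    break
            if ok:
                placed.append(ColonyShape((cx, cy), (a, b), theta))
                break
        else:
            raise PhantomPlacementError(
                f"could not place colony {i + 1}/{spec.n_colonies} within "
                f"{PLACEMENT_RETRY_BUDGET} attempts: non-overlapping, border-clear "
                f"placement infeasible for radius range {spec.colony_radius_range_px} "
                f"on a {spec.image_height_px}x{spec.image_width_px} image"
            )
    return placed


def _placement_weight(delta: np.ndarray | float, placement: str, concentration: float):
    if placement == "uniform":
        return np.ones_like(np.asarray(delta, dtype=float))
    if placement == "inner_clustered":
        return np.exp(-concentration * np.asarray(delta, dtype=float))
    if placement == "edge_biased":
        return np.exp(-concentration * (1.0 - np.asarray(delta, dtype=float)))
    raise ValueError(f"unknown placement {placement!r}")


def _sample_spot(colony: ColonyShape, r_spot: float, placement: str,
                 concentration: float, rng: np.random.Generator,
                 existing: list[tuple[float, float]] | None = None,
                 min_separation: float = 0.0) -> tuple[float, float]:
    """One spot centre inside the ellipse, disc fully contained, by rejection."""
    a, b = colony.semi_axes
    cx, cy = colony.center
    ct, st = math.cos(colony.rotation), math.sin(colony.rotation)
    for _ in range(PLACEMENT_RETRY_BUDGET * 10):
        # uniform over the ellipse area via the unit-disc sqrt trick
        rho = math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        xr, yr = a * rho * math.cos(ang), b * rho * math.sin(ang)
        px, py = cx + ct * xr - st * yr, cy + st * xr + ct * yr
        d = math.hypot(px - cx, py - cy)
        if d > 0:
            ux, uy = (px - cx) / d, (py - cy) / d
        else:
            ux, uy = 1.0, 0.0
        t_edge = _centre_to_edge_distance(colony, ux, uy)
        if d + r_spot + 1.0 > t_edge:  # spot disc must fit inside the colony
            continue
        if min_separation > 0 and existing:
            if any(math.hypot(px - ex, py - ey) < min_separation
                   for ex, ey in existing):
                continue
        delta = d / t_edge
        if rng.uniform() <= float(_placement_weight(delta, placement, concentration)):
            return px, py
    raise PhantomPlacementError(
        f"could not place a spot of radius {r_spot:.1f} px inside colony with "
        f"semi-axes {colony.semi_axes}: fit constraint too tight"
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_EDGE_RAMP_PX = 1.5  # soft-edge width for both colonies and spots


def make_colony_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a phantom image and its exact ground truth.

    Returns a float64 image in [0, 255] (row-major, y = row, x = column) and
    a :class:`GroundTruth`.  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    colonies = _place_colonies(spec, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), float(spec.background_level))
    for colony in colonies:
        u = _radial_coordinate(colony, xx, yy)
        # signed pixel distance to the boundary, approximated via the minor axis
        d_px = (1.0 - u) * colony.semi_axes[1]
        alpha = np.clip(d_px / _EDGE_RAMP_PX + 0.5, 0.0, 1.0)
        img += alpha * (spec.colony_level - spec.background_level)

    truth = GroundTruth(colonies=colonies)
    slo, shi = spec.spot_radius_range_px
    if spec.spot_polarity == "dark":
        spot_level = 0.25 * spec.colony_level
    else:
        spot_level = spec.colony_level + 0.7 * (255.0 - spec.colony_level)
    for ci, colony in enumerate(colonies):
        placed: list[tuple[float, float]] = []
        for _ in range(spec.n_spots_per_colony):
            r_spot = rng.uniform(slo, shi)
            px, py = _sample_spot(colony, r_spot, spec.placement,
                                  spec.placement_concentration, rng,
                                  existing=placed,
                                  min_separation=spec.spot_min_separation_px)
            placed.append((px, py))
            truth.spots.append((ci, (px, py), r_spot))
            rho = np.hypot(xx - px, yy - py)
            alpha = np.clip((r_spot - rho) / _EDGE_RAMP_PX + 0.5, 0.0, 1.0)
            img = img * (1.0 - alpha) + spot_level * alpha

    if spec.illumination_gradient > 0:
        img = img + spec.illumination_gradient * (xx / max(w - 1, 1) - 0.5)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0), truth


# ---------------------------------------------------------------------------
# point phantoms (statistics without imaging)
# ---------------------------------------------------------------------------

def _mask_normalized_distance(mask: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-pixel normalized centroid distance for an arbitrary mask.

    The centroid-to-edge distance along each ray is looked up from an angular
    profile of the mask boundary (max boundary radius per angular bin,
    circularly interpolated).  Adequate for star-convex masks, which is all
    the phantom generator produces.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("mask is empty")
    cy, cx = float(ys.mean()), float(xs.mean())
    if ys.size == 1:
        return np.zeros_like(mask, dtype=float), (cx, cy)

    from scipy import ndimage

    interior = ndimage.binary_erosion(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
        border_value=0)
    by, bx = np.nonzero(mask & ~interior)
    ang = np.arctan2(by - cy, bx - cx)
    rad = np.hypot(by - cy, bx - cx)

    nbins = max(36, min(720, by.size))
    bins = ((ang + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins
    profile = np.full(nbins, -np.inf)
    np.maximum.at(profile, bins, rad)
    empty = ~np.isfinite(profile)
    if empty.any():
        idx = np.arange(nbins, dtype=float)
        good = np.nonzero(~empty)[0]
        # circular linear interpolation across empty bins
        profile[empty] = np.interp(idx[empty], good,
                                   profile[good], period=nbins)

    pang = np.arctan2(ys - cy, xs - cx)
    pbin = ((pang + np.pi) / (2 * np.pi) * nbins) % nbins
    i0 = np.floor(pbin).astype(int) % nbins
    frac = pbin - np.floor(pbin)
    d_edge = profile[i0] * (1 - frac) + profile[(i0 + 1) % nbins] * frac
    d_edge = np.maximum(d_edge, 1e-9)
    delta = np.zeros_like(mask, dtype=float)
    delta[ys, xs] = np.clip(np.hypot(ys - cy, xs - cx) / d_edge, 0.0, 1.0)
    return delta, (cx, cy)


def make_point_phantom(colony_mask: np.ndarray, n_points: int, placement: str,
                       concentration: float, seed: int) -> np.ndarray:
    """Sample ``n_points`` (x, y) points on mask pixels under a placement law.

    ``uniform`` draws uniformly over mask pixels; ``inner_clustered`` weights
    pixels by exp(-concentration * delta) and ``edge_biased`` by
    exp(-concentration * (1 - delta)), where delta is the pixel's normalized
    centroid distance.  Returns an (n_points, 2) float array of (x, y).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if placement not in _PLACEMENTS:
        raise ValueError(f"placement must be one of {_PLACEMENTS}")
    mask = np.asarray(colony_mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    if placement == "uniform" or ys.size == 1:
        weights = np.ones(ys.size)
    else:
        delta, _ = _mask_normalized_distance(mask)
        weights = _placement_weight(delta[ys, xs], placement, concentration)
    weights = weights / weights.sum()
    idx = rng.choice(ys.size, size=n_points, p=weights)
    return np.column_stack([xs[idx].astype(float), ys[idx].astype(float)])


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------

def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    """Spot table: colony_id, x, y, radius (0-based pixels, x = column)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["colony_id", "x", "y", "radius"])
        for ci, (x, y), r in truth.spots:
            writer.writerow([ci, f"{x:.3f}", f"{y:.3f}", f"{r:.3f}"])


def read_ground_truth_csv(path: str | Path) -> list[tuple[int, tuple[float, float], float]]:
    spots = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            spots.append((int(row["colony_id"]),
                          (float(row["x"]), float(row["y"])),
                          float(row["radius"])))
    return spots
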