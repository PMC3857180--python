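"""End-to-end orchestration: image -> colonies -> detections -> location report.

Per image: preprocess, level-set segmentation, binary enhancement, watershed
split, nonlinear diffusion, orientation matching, spot detection and colony
assignment.  Location statistics (normalized centroid distances, mutual
distances, Monte-Carlo null, KS tests, labels) are pooled over the whole
image set.  All output coordinates refer to the ORIGINAL image scale.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from . import locstats, segmentation, spotdetect
from .config import PipelineConfig
from .preprocess import run_preprocess
from .segmentation import Colony
from .spotdetect import SpotDetection

logger = logging.getLogger("colonyloc")

__all__ = ["ImageResult", "PipelineResult", "segment_image", "detect_image",
           "analyze_locations", "run_pipeline"]


@dataclass
class ImageResult:
    path: str
    colonies: list[Colony]
    detections: list[SpotDetection]
    resize_factor: float


@dataclass
class PipelineResult:
    images: list[ImageResult]
    report: locstats.LocationReport | None
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _derive_seed(seed: int, *indices: int) -> int:
    """Counter-based per-colony stream so processing order cannot matter."""
    return int(np.random.SeedSequence([seed, *indices]).generate_state(1)[0])


def segment_image(gray: np.ndarray, config: PipelineConfig) -> list[Colony]:
    """Preprocess + level set + binary enhancement + watershed split."""
    pre = run_preprocess(gray, config.preprocess)
    phi0 = segmentation.initialize_level_set(pre.shape, config.levelset.init_mode, pre)
    phi = segmentation.evolve_level_set(pre, phi0, config.levelset)
    mask = segmentation.binarize(phi)
    mask = segmentation.enhance_binary(mask, config.binary.disk_radius_px,
                                       config.binary.min_area_px)
    return segmentation.split_colonies(mask, h_merge=config.binary.h_merge)


def detect_image(gray: np.ndarray, colonies: list[Colony],
                 config: PipelineConfig) -> list[SpotDetection]:
    """Diffusion prefilter + orientation matching + peak extraction."""
    p = config.detect
    smooth = spotdetect.nonlinear_diffusion(gray, p.diffusion_iters,
                                            p.diffusion_kappa, p.diffusion_dt)
    score_map = spotdetect.orientation_matching(smooth, p)
    return spotdetect.detect_spots(score_map, colonies, p)


def analyze_locations(images: list[ImageResult], config: PipelineConfig,
                      seed: int) -> tuple[locstats.LocationReport | None, dict]:
    """Pooled location statistics over all colonies of all images.

    Returns the report plus per-colony detail rows for the CSV writers.
    """
    s = config.stats
    real_deltas, null_deltas = [], []
    real_mhat, null_mhat = [], []
    location_rows, mutual_rows = [], []
    null_acceptance = {}

    colony_counter = 0
    for img_idx, res in enumerate(images):
        det_by_colony: dict[int, list[SpotDetection]] = {}
        for det in res.detections:
            det_by_colony.setdefault(det.colony_label, []).append(det)
        for colony in res.colonies:
            colony_counter += 1
            dets = det_by_colony.get(colony.label, [])
            if not dets:
                continue
            pts = np.array([d.center for d in dets], dtype=float)
            deltas = locstats.normalized_distances(pts, colony)
            for ci, (d, det) in enumerate(zip(deltas, dets)):
                dist = locstats.distance_to_centroid(det.center, colony.centroid)
                location_rows.append((img_idx, colony.label, ci,
                                      det.center[0], det.center[1],
                                      dist, dist / d if d > 0 else 0.0, float(d)))
            real_deltas.append(deltas)
            m = locstats.mutual_distances(pts, colony.major_axis_px)
            real_mhat.append(m)
            pair_idx = 0
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    mutual_rows.append((img_idx, colony.label, i, j,
                                        float(m[pair_idx] * colony.major_axis_px),
                                        float(m[pair_idx])))
                    pair_idx += 1

            null = locstats.generate_null_points(
                colony, n_real=len(dets), multiplier=s.null_multiplier,
                seed=_derive_seed(seed, img_idx, colony.label))
            null_deltas.append(locstats.normalized_distances(null.points, colony))
            null_mhat.append(locstats.mutual_distances(null.points,
                                                       colony.major_axis_px))
            null_acceptance[f"img{img_idx}_colony{colony.label}"] = len(null.points)

    if not real_deltas:
        return None, {"location_rows": location_rows, "mutual_rows": mutual_rows,
                      "null_counts": null_acceptance}

    rd = locstats.truncate_extremes(np.concatenate(real_deltas), s.lower_cut)
    nd = locstats.truncate_extremes(np.concatenate(null_deltas), s.lower_cut)
    rm = np.concatenate(real_mhat) if real_mhat else np.empty(0)
    nm = np.concatenate(null_mhat) if null_mhat else np.empty(0)
    if rd.size == 0 or nd.size == 0:
        return None, {"location_rows": location_rows, "mutual_rows": mutual_rows,
                      "null_counts": null_acceptance}
    report = locstats.classify_location(rd, nd, rm, nm, alpha=s.alpha,
                                        lower_cut=s.lower_cut,
                                        smoothing_window=s.smoothing_window)
    return report, {"location_rows": location_rows, "mutual_rows": mutual_rows,
                    "null_counts": null_acceptance}


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _write_colonies_csv(images: list[ImageResult], path: Path, scale: float) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# coordinates at original image scale"])
        w.writerow(["image", "colony_id", "area_px", "centroid_x", "centroid_y",
                    "major_axis_px", "bbox_x_min", "bbox_y_min", "bbox_x_max",
                    "bbox_y_max"])
        for res in images:
            for c in res.colonies:
                w.writerow([res.path, c.label, c.area_px,
                            f"{c.centroid[0] / scale:.3f}", f"{c.centroid[1] / scale:.3f}",
                            f"{c.major_axis_px / scale:.3f}",
                            *(int(round(v / scale)) for v in c.bbox)])


def _write_detections_csv(images: list[ImageResult], path: Path, scale: float) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# coordinates at original image scale, 0-based, x = column"])
        w.writerow(["image", "colony_id", "x", "y", "radius_px", "score"])
        for res in images:
            for d in res.detections:
                w.writerow([res.path, d.colony_label,
                            f"{d.center[0] / scale:.3f}", f"{d.center[1] / scale:.3f}",
                            f"{d.radius / scale:.3f}", f"{d.score:.6f}"])


def _write_locations_csv(rows, path: Path, scale: float) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# coordinates at original image scale"])
        w.writerow(["image_index", "colony_id", "cell_id", "x", "y",
                    "d_px", "D_px", "delta"])
        for (img, col, cell, x, y, d, big_d, delta) in rows:
            w.writerow([img, col, cell, f"{x / scale:.3f}", f"{y / scale:.3f}",
                        f"{d / scale:.3f}", f"{big_d / scale:.3f}", f"{delta:.6f}"])


def _write_mutual_csv(rows, path: Path, scale: float) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# distances at original image scale; mhat is scale-free"])
        w.writerow(["image_index", "colony_id", "i", "j", "m_px", "mhat"])
        for (img, col, i, j, m, mhat) in rows:
            w.writerow([img, col, i, j, f"{m / scale:.3f}", f"{mhat:.6f}"])


def run_pipeline(config: PipelineConfig, image_paths, out_dir: str | Path,
                 seed: int | None = None, write_overlays: bool = False) -> PipelineResult:
    """Process an image set end to end and write all artifacts under out_dir."""
    config.validate()
    seed = config.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = config.resize_factor

    images: list[ImageResult] = []
    skipped: list[tuple[str, str]] = []
    for path in image_paths:
        try:
            gray = pio.read_image(path, resize_factor=config.resize_factor)
            logger.info("processing %s at working shape %s", path, gray.shape)
            colonies = segment_image(gray, config)
            detections = detect_image(gray, colonies, config)
            logger.info("%s: %d colonies, %d detections", path, len(colonies),
                        len(detections))
            images.append(ImageResult(path=str(path), colonies=colonies,
                                      detections=detections,
                                      resize_factor=config.resize_factor))
            if write_overlays:
                _write_overlay(gray, colonies, detections,
                               out_dir / (Path(path).stem + "_overlay.png"))
        except Exception as exc:  # noqa: BLE001 - stage failure skips the image
            logger.warning("skipping %s: %s", path, exc)
            skipped.append((str(path), str(exc)))

    report, detail = analyze_locations(images, config, seed)

    _write_colonies_csv(images, out_dir / "colonies.csv", scale)
    _write_detections_csv(images, out_dir / "detections.csv", scale)
    _write_locations_csv(detail["location_rows"], out_dir / "locations.csv", scale)
    _write_mutual_csv(detail["mutual_rows"], out_dir / "mutual.csv", scale)

    summary = {
        "n_images": len(images),
        "n_colonies": sum(len(r.colonies) for r in images),
        "n_detections": sum(len(r.detections) for r in images),
        "seed": seed,
        "resize_factor": config.resize_factor,
        "skipped": [{"path": p, "reason": r} for p, r in skipped],
        "null_point_counts": detail["null_counts"],
        "report": report.to_dict() if report is not None else None,
    }
    if not image_paths:
        logger.warning("empty image list: writing an empty report")
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2) + "\n")
    return PipelineResult(images=images, report=report, skipped=skipped)


def _write_overlay(gray: np.ndarray, colonies, detections, path: Path) -> None:
    """Diagnostic overlay: colony outlines, centroids, detection circles and
    centroid-to-cell segments annotated with delta.  Requires matplotlib."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover - plotting is optional
        logger.warning("matplotlib unavailable: skipping overlay %s", path)
        return
    fig, ax = plt.subplots(figsize=(6, 6 * gray.shape[0] / max(gray.shape[1], 1)))
    ax.imshow(gray, cmap="gray", vmin=0, vmax=255)
    by_label = {c.label: c for c in colonies}
    for c in colonies:
        ax.plot(c.boundary[:, 0], c.boundary[:, 1], ".", ms=1)
        ax.plot(*c.centroid, "b*", ms=8)
    for d in detections:
        circ = plt.Circle(d.center, d.radius, fill=False, color="lime", lw=1)
        ax.add_patch(circ)
        colony = by_label.get(d.colony_label)
        if colony is not None:
            delta = float(locstats.normalized_distances(
                np.array([d.center]), colony)[0])
            ax.plot([colony.centroid[0], d.center[0]],
                    [colony.centroid[1], d.center[1]], "-", color="orange", lw=0.8)
            ax.annotate(f"{delta:.2f}", d.center, color="yellow", fontsize=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
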