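"""Nuclei counting by overlapping-ROI scanning.

A nucleus-sized square region of interest (ROI) is slid across the whole
image on a stride lattice; every placement is scored by its
background-subtracted mean intensity, placements above a detection threshold
become candidates, and candidates crowding the same nucleus are collapsed by
greedy non-maximum suppression.  Per-nucleus fluorescence intensity (FI) is
then measured in a centred aperture for downstream live/dead classification.

Only fully interior ROI placements are scored, so nuclei closer than half an
ROI to the image edge may be missed — a documented limitation.  The exact
statistic, stride and deduplication rule of the original counting software
are not public; every choice here is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_imaging import ImageFrame

__all__ = [
    "DetectionConfig",
    "NucleusDetection",
    "GeometryError",
    "estimate_background",
    "scan_rois",
    "threshold_candidates",
    "deduplicate",
    "measure_fi",
    "count_cells",
    "detections_to_frame",
    "write_detections_csv",
]


class GeometryError(ValueError):
    """ROI or aperture does not fit inside the image."""


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the ROI-scanning detector.

    roi_size_px:
        Side of the square ROI; odd, >= 3.  The default 15 px is the nearest
        odd integer to a 10 um nucleus at the default 0.65 um/px pitch.
    stride_px:
        Lattice step between ROI placements; 1 = fully overlapping scan.
    detection_threshold_au:
        Strict lower bound on the ROI score (background-subtracted mean);
        candidates scoring exactly the threshold are rejected.
    background:
        ``"median"`` (global image median, default), ``"local-median"``
        (tile-wise median, for uneven illumination) or a constant value.
    min_separation_px:
        Chebyshev exclusion radius of the non-maximum suppression.
    aperture_px:
        Odd side of the FI-measurement box; ``None`` means the ROI box.
    """

    roi_size_px: int = 15
    stride_px: int = 1
    detection_threshold_au: float = 2.0
    background: Literal["median", "local-median"] | float = "median"
    min_separation_px: int = 15
    aperture_px: int | None = None
    local_median_tile_px: int = 128

    def __post_init__(self) -> None:
        if self.roi_size_px < 3 or self.roi_size_px % 2 == 0:
            raise ValueError("roi_size_px must be an odd integer >= 3")
        if self.stride_px < 1:
            raise ValueError("stride_px must be >= 1")
        if self.detection_threshold_au < 0:
            raise ValueError("detection_threshold_au must be >= 0")
        if self.min_separation_px < 1:
            raise ValueError("min_separation_px must be >= 1")
        if self.aperture_px is not None and (
            self.aperture_px < 1 or self.aperture_px % 2 == 0
        ):
            raise ValueError("aperture_px must be an odd integer >= 1")


@dataclass(frozen=True)
class NucleusDetection:
    """One detected nucleus: ROI-centre position, box, score and measured FI."""

    row_px: int
    col_px: int
    roi_bounds: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    score: float
    fi_au: float = 0.0


def estimate_background(image: ImageFrame, cfg: DetectionConfig) -> np.ndarray | float:
    """Background level: constant, global median, or tile-median map."""
    if isinstance(cfg.background, (int, float)):
        return float(cfg.background)
    px = image.pixels
    if cfg.background == "median":
        return float(np.median(px))
    if cfg.background == "local-median":
        t = cfg.local_median_tile_px
        h, w = px.shape
        nr, nc = max(1, -(-h // t)), max(1, -(-w // t))
        tiles = np.empty((nr, nc))
        for i in range(nr):
            for j in range(nc):
                tiles[i, j] = np.median(px[i * t:(i + 1) * t, j * t:(j + 1) * t])
        zoom = (h / nr, w / nc)
        return ndimage.zoom(tiles, zoom, order=1, grid_mode=True, mode="nearest")
    raise ValueError(f"unknown background mode {cfg.background!r}")


def scan_rois(
    image: ImageFrame,
    cfg: DetectionConfig,
    background: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score every fully interior ROI placement on the stride lattice.

    Returns ``(positions, scores)`` where ``positions`` is an (n, 2) int array
    of ROI-centre (row, col) coordinates in row-major placement order and
    ``scores`` the background-subtracted mean intensity of each ROI.
    """
    k = cfg.roi_size_px
    h, w = image.pixels.shape
    if k > h or k > w:
        raise GeometryError(f"ROI of {k} px does not fit a {h}x{w} image")
    half = k // 2
    # uniform_filter at an interior centre uses exactly the k x k window
    means = ndimage.uniform_filter(image.pixels, size=k, mode="constant")
    rows = np.arange(half, h - half, cfg.stride_px)
    cols = np.arange(half, w - half, cfg.stride_px)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    positions = np.stack([rr.ravel(), cc.ravel()], axis=1)

    bg = estimate_background(image, cfg) if background is None else background
    if np.isscalar(bg):
        scores = means[rr.ravel(), cc.ravel()] - bg
    else:
        scores = means[rr.ravel(), cc.ravel()] - bg[rr.ravel(), cc.ravel()]
    return positions, scores


def threshold_candidates(
    positions: np.ndarray, scores: np.ndarray, threshold_au: float
) -> tuple[np.ndarray, np.ndarray]:
    """Keep candidates with score strictly above the threshold, order preserved."""
    if threshold_au < 0:
        raise ValueError("threshold must be >= 0")
    keep = scores > threshold_au
    return positions[keep], scores[keep]


def deduplicate(
    positions: np.ndarray,
    scores: np.ndarray,
    min_separation_px: int,
    roi_size_px: int,
) -> list[NucleusDetection]:
    """Greedy non-maximum suppression over candidate ROI placements.

    Candidates are visited in descending score order (ties broken by row-major
    position for determinism) and accepted iff their centre lies at Chebyshev
    distance >= ``min_separation_px`` from every already accepted centre.
    """
    n = len(positions)
    if n == 0:
        return []
    positions = np.asarray(positions, dtype=int)
    order = np.lexsort((positions[:, 1], positions[:, 0], -np.asarray(scores)))
    half = roi_size_px // 2
    sep = int(min_separation_px)
    # bin accepted centres on a sep-sized grid: any conflicting accepted point
    # lies in the candidate's own bin or one of its 8 neighbours
    bins: dict[tuple[int, int], list[tuple[int, int]]] = {}
    out: list[NucleusDetection] = []
    for idx in order:
        r, c = int(positions[idx, 0]), int(positions[idx, 1])
        br, bc = r // sep, c // sep
        ok = True
        for dbr in (-1, 0, 1):
            for dbc in (-1, 0, 1):
                for ar, ac in bins.get((br + dbr, bc + dbc), ()):
                    if max(abs(ar - r), abs(ac - c)) < sep:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            bins.setdefault((br, bc), []).append((r, c))
            out.append(
                NucleusDetection(
                    row_px=r, col_px=c,
                    roi_bounds=(r - half, r + half + 1, c - half, c + half + 1),
                    score=float(scores[idx]),
                )
            )
    return out


def measure_fi(
    image: ImageFrame,
    detection: NucleusDetection,
    aperture_px: int | None = None,
    background: float | None = None,
) -> float:
    """Background-subtracted mean intensity in a centred aperture, clamped >= 0.

    The default aperture is the detection's ROI box; ``background`` defaults
    to the global image median.
    """
    if aperture_px is None:
        r0, r1, c0, c1 = detection.roi_bounds
    else:
        if aperture_px < 1 or aperture_px % 2 == 0:
            raise ValueError("aperture_px must be an odd integer >= 1")
        half = aperture_px // 2
        r0, r1 = detection.row_px - half, detection.row_px + half + 1
        c0, c1 = detection.col_px - half, detection.col_px + half + 1
    h, w = image.pixels.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise GeometryError("measurement aperture extends outside the image")
    if background is None:
        background = float(np.median(image.pixels))
    return max(0.0, float(np.mean(image.pixels[r0:r1, c0:c1])) - background)


def count_cells(image: ImageFrame, cfg: DetectionConfig) -> list[NucleusDetection]:
    """Full detection chain: scan -> threshold -> deduplicate -> measure FI."""
    bg = estimate_background(image, cfg)
    positions, scores = scan_rois(image, cfg, background=bg)
    positions, scores = threshold_candidates(
        positions, scores, cfg.detection_threshold_au
    )
    detections = deduplicate(positions, scores, cfg.min_separation_px, cfg.roi_size_px)
    out = []
    for det in detections:
        local_bg = float(bg) if np.isscalar(bg) else float(bg[det.row_px, det.col_px])
        fi = measure_fi(image, det, aperture_px=cfg.aperture_px, background=local_bg)
        out.append(NucleusDetection(det.row_px, det.col_px, det.roi_bounds,
                                    det.score, fi))
    return out


def detections_to_frame(
    detections: list[NucleusDetection], image_id: str | int = 0
) -> pd.DataFrame:
    return pd.DataFrame(
        [(image_id, d.row_px, d.col_px, d.fi_au, d.score) for d in detections],
        columns=["image", "row_px", "col_px", "fi_au", "score"],
    )


def write_detections_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)
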