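"""Ground-truthed synthetic fluorescence micrographs of Hoechst-stained nuclei.

No imaging data accompany the cytotoxicity assay this package quantifies, so
every downstream stage (ROI-scanning detection, live/dead classification,
live-cell-ratio statistics) is exercised against scenes generated here, where
the true nucleus positions, viability labels and fluorescence intensities are
known exactly.

The model is deliberately simple: nuclei are isotropic Gaussian blobs on a
uniform background.  Live nuclei draw their peak fluorescence intensity (FI)
from a low population and dead nuclei from a high one; the two populations are
constructed to be cleanly separable at the 100 a.u. classification threshold
used by :mod:`nbviability.viability_stats`.  The default field geometry
(2048 x 2048 px at 0.65 um/px) gives a per-image area of 1.77 mm^2, matching
the areal-concentration divisor of the assay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Nucleus",
    "SyntheticScene",
    "ImageFrame",
    "FIModel",
    "KineticsParams",
    "KINETICS_PRESETS",
    "PackingError",
    "generate_scene",
    "render_image",
    "simulate_timecourse",
    "write_image_tiff",
    "read_image_tiff",
    "write_ground_truth_csv",
    "DEFAULT_FIELD_UM",
    "DEFAULT_PITCH_UM",
]

# Default geometry: 2048 px * 0.65 um/px = 1.3312 mm per side -> 1.7721 mm^2,
# the per-image field area of the assay.  The alternative 1.3 um/px pitch of
# the paper-grade camera is available through the `pitch_um` arguments.
DEFAULT_PITCH_UM = 0.65
DEFAULT_SHAPE_PX = (2048, 2048)
DEFAULT_FIELD_UM = (DEFAULT_SHAPE_PX[0] * DEFAULT_PITCH_UM,
                    DEFAULT_SHAPE_PX[1] * DEFAULT_PITCH_UM)


class PackingError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested hard-core spacing."""


@dataclass(frozen=True)
class Nucleus:
    """Ground-truth nucleus: position and size in microns, label and peak FI."""

    x_um: float
    y_um: float
    radius_um: float
    label: Literal["live", "dead"]
    peak_fi_au: float


@dataclass
class SyntheticScene:
    """A field of nuclei with known positions and viability labels.

    ``x_um`` runs along image columns, ``y_um`` along rows; the origin is the
    top-left corner of the field.
    """

    nuclei: list[Nucleus]
    field_width_um: float = DEFAULT_FIELD_UM[1]
    field_height_um: float = DEFAULT_FIELD_UM[0]
    seed: int | None = None

    @property
    def n_live(self) -> int:
        return sum(1 for n in self.nuclei if n.label == "live")

    @property
    def n_dead(self) -> int:
        return sum(1 for n in self.nuclei if n.label == "dead")


@dataclass
class ImageFrame:
    """Single-channel intensity raster with physical pixel pitch.

    ``pixels[r, c]`` is the intensity (a.u.) at row ``r``, column ``c``; the
    pixel centre sits at ``((r + 0.5) * pitch, (c + 0.5) * pitch)`` in microns.
    """

    pixels: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return (h * self.pixel_pitch_um) * (w * self.pixel_pitch_um) / 1e6


@dataclass(frozen=True)
class FIModel:
    """Peak-FI populations for live and dead nuclei (arbitrary units).

    Fixture parameters, not measurements: Gaussians at 50 +/- 15 (live) and
    200 +/- 15 (dead) are separable at the 100 a.u. threshold; draws falling
    on the wrong side of ``separation_au`` are rejected and redrawn so the
    ground-truth label is always recoverable from the peak FI alone.
    ``min_fi_au`` floors the draws: a stained nucleus is never dimmer than
    10% of the classification threshold, since a Hoechst-positive nucleus is
    by construction clearly visible above background.
    """

    live_mean_au: float = 50.0
    live_sd_au: float = 15.0
    dead_mean_au: float = 200.0
    dead_sd_au: float = 15.0
    separation_au: float = 100.0
    min_fi_au: float = 10.0

    def draw(self, label: str, rng: np.random.Generator) -> float:
        if label == "live":
            mean, sd = self.live_mean_au, self.live_sd_au
        else:
            mean, sd = self.dead_mean_au, self.dead_sd_au
        for _ in range(10_000):
            fi = rng.normal(mean, sd)
            if fi < self.min_fi_au:
                continue
            if label == "live" and fi < self.separation_au:
                return fi
            if label == "dead" and fi > self.separation_au:
                return fi
        raise RuntimeError("FI rejection sampling failed; check FIModel parameters")


_MAX_PLACEMENT_ATTEMPTS = 10_000


def generate_scene(
    n_live: int,
    n_dead: int,
    *,
    field_width_um: float = DEFAULT_FIELD_UM[1],
    field_height_um: float = DEFAULT_FIELD_UM[0],
    fi_model: FIModel | None = None,
    min_spacing_um: float | None = None,
    margin_um: float = 25.0,
    radius_um: float = 5.0,
    seed: int | None = None,
) -> SyntheticScene:
    """Place ``n_live + n_dead`` nuclei uniformly at random in the field.

    Parameters
    ----------
    min_spacing_um:
        Optional hard-core pairwise centre distance (Euclidean).  Placement
        uses bounded rejection sampling; an infeasible packing raises
        :class:`PackingError`.
    margin_um:
        Nuclei are kept at least this far from every field edge so that a
        detector restricted to fully interior ROI placements can still see
        them.
    """
    if n_live < 0 or n_dead < 0:
        raise ValueError("n_live and n_dead must be non-negative")
    if field_width_um <= 0 or field_height_um <= 0:
        raise ValueError("field dimensions must be positive")
    if margin_um < 0 or 2 * margin_um >= min(field_width_um, field_height_um):
        raise ValueError("margin_um leaves no interior placement area")
    fi_model = fi_model or FIModel()
    rng = np.random.default_rng(seed)

    labels = ["live"] * n_live + ["dead"] * n_dead
    placed: list[tuple[float, float]] = []
    nuclei: list[Nucleus] = []
    min_sq = (min_spacing_um or 0.0) ** 2
    for label in labels:
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            x = rng.uniform(margin_um, field_width_um - margin_um)
            y = rng.uniform(margin_um, field_height_um - margin_um)
            if min_sq and any((x - px) ** 2 + (y - py) ** 2 < min_sq
                              for px, py in placed):
                continue
            break
        else:
            raise PackingError(
                f"could not place nucleus {len(placed) + 1}/{len(labels)} at "
                f"min_spacing_um={min_spacing_um} after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        placed.append((x, y))
        nuclei.append(Nucleus(x, y, radius_um, label, fi_model.draw(label, rng)))

    return SyntheticScene(nuclei, field_width_um, field_height_um, seed)


def render_image(
    scene: SyntheticScene,
    *,
    pitch_um: float = DEFAULT_PITCH_UM,
    psf_sigma_um: float = 2.0,
    background_au: float = 10.0,
    noise_sigma_au: float = 0.0,
    poisson_noise: bool = False,
    seed: int | None = None,
) -> ImageFrame:
    """Render a scene as a noisy fluorescence raster.

    Each nucleus becomes an isotropic Gaussian blob of width ``psf_sigma_um``
    and amplitude equal to its peak FI, evaluated at pixel centres and added
    to a uniform background.  Optional noise: Poisson shot noise on the clean
    signal, then additive Gaussian read noise of SD ``noise_sigma_au``.
    Negative pixels are clamped at zero.  Deterministic under a fixed seed.
    """
    if pitch_um <= 0:
        raise ValueError("pitch_um must be positive")
    if psf_sigma_um < 0:
        raise ValueError("psf_sigma_um must be non-negative")
    h = int(round(scene.field_height_um / pitch_um))
    w = int(round(scene.field_width_um / pitch_um))
    img = np.full((h, w), float(background_au))

    sigma_px = psf_sigma_um / pitch_um
    halfwin = max(1, int(math.ceil(5 * sigma_px)))
    for nuc in scene.nuclei:
        # positions in pixel units; pixel centre i sits at (i + 0.5) * pitch
        cr = nuc.y_um / pitch_um - 0.5
        cc = nuc.x_um / pitch_um - 0.5
        ir, ic = int(round(cr)), int(round(cc))
        if not (0 <= ir < h and 0 <= ic < w):
            warnings.warn(
                f"nucleus at ({nuc.x_um:.1f}, {nuc.y_um:.1f}) um falls outside "
                "the raster; clipped from the image but retained in ground truth",
                stacklevel=2,
            )
            continue
        r0, r1 = max(0, ir - halfwin), min(h, ir + halfwin + 1)
        c0, c1 = max(0, ic - halfwin), min(w, ic + halfwin + 1)
        rr = np.arange(r0, r1)[:, None] - cr
        cc_off = np.arange(c0, c1)[None, :] - cc
        if sigma_px == 0:
            img[ir, ic] += nuc.peak_fi_au
        else:
            img[r0:r1, c0:c1] += nuc.peak_fi_au * np.exp(
                -(rr ** 2 + cc_off ** 2) / (2 * sigma_px ** 2)
            )

    if poisson_noise or noise_sigma_au > 0:
        rng = np.random.default_rng(seed)
        if poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise_sigma_au > 0:
            img += rng.normal(0.0, noise_sigma_au, size=img.shape)
    return ImageFrame(np.clip(img, 0, None), pitch_um)


_DEAD_BASELINE_FRAC = 0.05  # spontaneous dead fraction visible on Day 0


@dataclass(frozen=True)
class KineticsParams:
    """Multi-day count kinetics for one culture condition.

    ``growth_per_day`` multiplies the expected live count each day, so the
    Day-N expectation is ``n0 * growth_per_day**N``.  Dead nuclei remain
    Hoechst-positive; ``dead_persistence`` is the fraction of cumulatively
    lost cells still visible in the field, on top of a small spontaneous
    baseline.  Per-image counts are Poisson around the expectation.
    """

    n0: float = 180.0
    growth_per_day: float = 1.3
    dead_persistence: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.growth_per_day <= 0:
            raise ValueError("growth_per_day must be positive")
        if not 0 <= self.dead_persistence <= 1:
            raise ValueError("dead_persistence must lie in [0, 1]")

    def expected_live(self, day: int) -> float:
        return self.n0 * self.growth_per_day ** day

    def expected_dead(self, day: int) -> float:
        lost = max(0.0, self.n0 - self.expected_live(day))
        return self.dead_persistence * lost + _DEAD_BASELINE_FRAC * self.n0


# Presets reproducing the qualitative orderings of the assay: untreated
# cultures grow; positively charged nanobubbles kill faster than negative.
# The rates themselves are fixture inventions, not measured values.
KINETICS_PRESETS: dict[str, KineticsParams] = {
    "no-nb": KineticsParams(growth_per_day=1.3),
    "nb-pos": KineticsParams(growth_per_day=0.4),
    "nb-neg": KineticsParams(growth_per_day=0.75),
}


def simulate_timecourse(
    kinetics: KineticsParams,
    *,
    days: int = 4,
    images_per_day: int = 10,
    count_noise: bool = True,
    field_width_um: float = DEFAULT_FIELD_UM[1],
    field_height_um: float = DEFAULT_FIELD_UM[0],
    fi_model: FIModel | None = None,
    min_spacing_um: float | None = 15.0,
    margin_um: float = 25.0,
    seed: int | None = None,
) -> tuple[dict[int, list[SyntheticScene]], pd.DataFrame]:
    """Generate per-day scenes for Days ``0 .. days-1`` plus a ground-truth table.

    Returns ``(scenes, truth)`` where ``scenes[day]`` holds ``images_per_day``
    scenes and ``truth`` lists every nucleus (day, image, x_um, y_um, label,
    peak_fi).  With ``count_noise`` the per-image live/dead counts are Poisson
    draws around the kinetics expectation; otherwise they are the rounded
    expectations exactly.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if images_per_day < 1:
        raise ValueError("images_per_day must be >= 1")
    master = np.random.default_rng(seed if seed is not None else kinetics.seed)
    scenes: dict[int, list[SyntheticScene]] = {}
    rows = []
    for day in range(days):
        day_scenes = []
        for i in range(images_per_day):
            exp_live = kinetics.expected_live(day)
            exp_dead = kinetics.expected_dead(day)
            if count_noise:
                n_live = int(master.poisson(exp_live))
                n_dead = int(master.poisson(exp_dead))
            else:
                n_live, n_dead = int(round(exp_live)), int(round(exp_dead))
            scene_seed = int(master.integers(0, 2**31 - 1))
            scene = generate_scene(
                n_live, n_dead,
                field_width_um=field_width_um, field_height_um=field_height_um,
                fi_model=fi_model, min_spacing_um=min_spacing_um,
                margin_um=margin_um, seed=scene_seed,
            )
            day_scenes.append(scene)
            for nuc in scene.nuclei:
                rows.append((day, i, nuc.x_um, nuc.y_um, nuc.label, nuc.peak_fi_au))
        scenes[day] = day_scenes
    truth = pd.DataFrame(
        rows, columns=["day", "image", "x_um", "y_um", "label", "peak_fi"]
    )
    return scenes, truth


def write_image_tiff(frame: ImageFrame, path: str | Path) -> None:
    """Write the raster as single-channel 16-bit TIFF (values rounded/clipped)."""
    data = np.clip(np.round(frame.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_image_tiff(path: str | Path, pixel_pitch_um: float = DEFAULT_PITCH_UM) -> ImageFrame:
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    return ImageFrame(data.astype(float), pixel_pitch_um)


def write_ground_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)
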