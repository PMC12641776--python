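"""Synthetic AO mosaic scenes with ground truth.

The generator emulates the acquisitions the analysis pipeline was designed
for, so that every stage can be exercised against known truth without
clinical data:

* **RPE scenes** — a perturbed hexagonal honeycomb (dim cell centres, bright
  borders), rendered as the distance field to the nearest cell centre.
* **PR scenes** — cones as bright Gaussian dots on a dark background.
* **Vessels** — dark, smooth, elongated ribbons of configurable width.
* **Degradations** — out-of-focus patches whose extent grows linearly with
  age, structureless (non-mosaic) visible patches, and additive sensor noise.

Cell positions are drawn on a jittered hexagonal lattice whose local spacing
follows the configured density field through ``density = 2/(sqrt(3) s²)``;
density may vary with eccentricity (cones decline away from the fovea) and
with age (RPE loss).  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .masking import MaskSet
from .optics import (
    DEFAULT_FOV_DEG,
    DEFAULT_IMAGE_SIZE,
    EyeMeta,
    ImageRecord,
    bennett_littmann_pixel_size,
)

SQRT3 = float(np.sqrt(3.0))


@dataclass
class SyntheticCohortConfig:
    """Cohort structure: participants, demographics, acquisition geometry.

    Defaults emulate a normative adult cohort imaged at five macular zones
    (fixation plus 5° offsets along both axes) with a 6.7° field of view.
    """

    n_participants: int = 10
    age_range: Tuple[float, float] = (23.0, 80.0)
    fraction_both_eyes: float = 0.65
    axial_length_mean: float = 23.6
    axial_length_sd: float = 0.8
    zones: Tuple[Tuple[float, float], ...] = (
        (0.0, 0.0),
        (5.0, 0.0),
        (-5.0, 0.0),
        (0.0, 5.0),
        (0.0, -5.0),
    )
    modalities: Tuple[str, ...] = ("RPE", "PR")
    fov_deg: float = DEFAULT_FOV_DEG
    image_size: int = DEFAULT_IMAGE_SIZE


@dataclass
class MosaicModelConfig:
    """Density field and rendering model of one modality's mosaic.

    ``base_density`` is defined at ``reference_ecc_deg`` and
    ``reference_age``; the field varies linearly with absolute eccentricity
    and with age and is floored at ``min_density``.
    """

    modality: str
    base_density: float
    reference_ecc_deg: float = 0.0
    reference_age: float = 50.0
    eccentricity_slope: float = 0.0
    age_slope: float = 0.0
    jitter: float = 0.15
    n_vessels: int = 3
    vessel_width_um: float = 60.0
    blur_fraction_base: float = 0.02
    blur_fraction_age_slope: float = 0.004
    nonmosaic_fraction: float = 0.05
    noise_sd: float = 0.03
    dot_sigma_frac: float = 0.18
    min_density: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter <= 0.5:
            raise ValueError("jitter must lie in [0, 0.5]")
        if self.base_density <= 0:
            raise ValueError("base_density must be positive")

    @classmethod
    def rpe_defaults(cls, **overrides) -> "MosaicModelConfig":
        """Normative RPE honeycomb: ~6313 cells/mm², flat over eccentricity,
        slight linear decline with age."""
        kw = dict(
            modality="RPE",
            base_density=6313.0,
            reference_ecc_deg=0.0,
            eccentricity_slope=0.0,
            age_slope=-20.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def pr_defaults(cls, **overrides) -> "MosaicModelConfig":
        """Normative cone mosaic: ~11,500 cells/mm² at 2.5°, declining with
        eccentricity, no age trend."""
        kw = dict(
            modality="PR",
            base_density=11500.0,
            reference_ecc_deg=2.5,
            eccentricity_slope=-400.0,
            age_slope=0.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def clean(cls, modality: str, density: float, **overrides) -> "MosaicModelConfig":
        """A uniform-density, full-visibility scene: no vessels, no blur,
        no non-mosaic patches.  Used for parameter-recovery experiments."""
        kw = dict(
            modality=modality,
            base_density=density,
            eccentricity_slope=0.0,
            age_slope=0.0,
            n_vessels=0,
            blur_fraction_base=0.0,
            blur_fraction_age_slope=0.0,
            nonmosaic_fraction=0.0,
        )
        kw.update(overrides)
        return cls(**kw)

    def density_at(self, ecc_deg, age: float):
        """Density field (cells/mm²) at signed eccentricity and age."""
        d = (
            self.base_density
            + self.eccentricity_slope * (np.abs(ecc_deg) - self.reference_ecc_deg)
            + self.age_slope * (age - self.reference_age)
        )
        return np.maximum(d, self.min_density)


@dataclass
class RenderResult:
    """A rendered scene with its ground truth."""

    image: ImageRecord
    centroids_px: np.ndarray  # (N, 2) float (row, col), inside the frame
    masks: MaskSet  # ground-truth footprints of every artefact


def _lattice_points(
    model: MosaicModelConfig,
    image: ImageRecord,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered hexagonal lattice following the density field, in px."""
    n = image.n_px
    eye = image.eye
    px_mm = image.pixel_size_um / 1000.0
    half = (n - 1) / 2.0
    scale = image.deg_per_px
    sign = 1.0 if eye.side == "OD" else -1.0
    cx, cy = image.center_deg

    def density_px(r: float, c: float) -> float:
        x = cx + sign * (c - half) * scale
        y = cy + (half - r) * scale
        d_mm2 = model.density_at(np.hypot(x, y), eye.age)
        return float(d_mm2) * px_mm**2

    s_center = float(np.sqrt(2.0 / (SQRT3 * density_px(half, half))))
    if s_center < 2.0:
        raise ValueError(
            f"configured density implies spacing {s_center:.2f} px < 2 px "
            "(below raster resolution)"
        )
    margin = 2.0 * s_center
    pts = []
    r = -margin
    parity = 0
    while r < n + margin:
        s_row = np.sqrt(2.0 / (SQRT3 * density_px(r, half)))
        h = 0.5 * SQRT3 * s_row
        c = -margin + (0.5 * s_row if parity else 0.0)
        while c < n + margin:
            pts.append((r, c))
            # In-row spacing chosen so local point density matches the field.
            c += 1.0 / (density_px(r, c) * h)
        r += h
        parity ^= 1
    pts = np.asarray(pts, dtype=float)
    if model.jitter > 0:
        s_local = np.sqrt(
            2.0
            / (
                SQRT3
                * np.array([density_px(r_, c_) for r_, c_ in pts])
            )
        )
        pts = pts + rng.normal(0.0, 1.0, pts.shape) * (model.jitter * s_local)[:, None]
    return pts  # includes margin points outside the frame, used for rendering


def _draw_vessels(
    n_px: int, n_vessels: int, width_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth dark-ribbon footprints crossing the frame."""
    path = np.zeros((n_px, n_px), dtype=bool)
    step = max(2.0, width_px / 8.0)
    for _ in range(n_vessels):
        edge = rng.integers(4)
        t = rng.uniform(0.1, 0.9) * n_px
        if edge == 0:
            pos, heading = np.array([0.0, t]), rng.uniform(-0.6, 0.6) + np.pi / 2
        elif edge == 1:
            pos, heading = np.array([n_px - 1.0, t]), rng.uniform(-0.6, 0.6) - np.pi / 2
        elif edge == 2:
            pos, heading = np.array([t, 0.0]), rng.uniform(-0.6, 0.6)
        else:
            pos, heading = np.array([t, n_px - 1.0]), rng.uniform(-0.6, 0.6) + np.pi
        for _ in range(int(4 * n_px / step)):
            rr, cc = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= rr < n_px and 0 <= cc < n_px):
                break
            path[rr, cc] = True
            heading += rng.normal(0.0, 0.08)
            pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
    if not path.any():
        return path
    dist = ndimage.distance_transform_edt(~path)
    return dist <= width_px / 2.0


def _elliptical_patch(
    n_px: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """A random axis-aligned elliptical region of ~``fraction`` of the frame."""
    patch = np.zeros((n_px, n_px), dtype=bool)
    if fraction <= 0:
        return patch
    target = fraction * n_px * n_px
    ratio = rng.uniform(0.5, 2.0)
    a = np.sqrt(target * ratio / np.pi)  # semi-axes in px
    b = target / (np.pi * a)
    cr = rng.uniform(min(b, n_px / 2), max(n_px - b, n_px / 2))
    cc = rng.uniform(min(a, n_px / 2), max(n_px - a, n_px / 2))
    rr, ccol = np.ogrid[:n_px, :n_px]
    patch = ((ccol - cc) / a) ** 2 + ((rr - cr) / b) ** 2 <= 1.0
    return patch


def render_mosaic_image(
    eye: EyeMeta,
    center_deg: Tuple[float, float],
    model: MosaicModelConfig,
    seed: int,
    image_size: int = DEFAULT_IMAGE_SIZE,
    fov_deg: float = DEFAULT_FOV_DEG,
    image_id: str = "",
) -> RenderResult:
    """Render one synthetic acquisition with full ground truth.

    Returns the image (uint16 grid), the true in-frame centroid positions,
    and a ground-truth :class:`MaskSet` recording the blur, vessel and
    non-mosaic footprints.
    """
    rng = np.random.default_rng(seed)
    n = image_size
    image = ImageRecord(
        eye=eye,
        modality=model.modality,
        pixels=np.zeros((n, n), dtype=np.uint16),
        center_deg=center_deg,
        fov_deg=fov_deg,
        image_id=image_id,
    )
    pts = _lattice_points(model, image, rng)
    px_mm = image.pixel_size_um / 1000.0
    s_center_px = float(
        np.sqrt(2.0 / (SQRT3 * model.density_at(np.hypot(*center_deg), eye.age)))
    ) / px_mm

    # Render on a margin-expanded canvas so cells just outside the frame
    # shape the border texture, then crop; without this the border shows
    # flat saturated bands where the nearest in-frame cell is far.
    m = int(np.ceil(2.5 * s_center_px))
    ne = n + 2 * m
    rr = np.rint(pts[:, 0]).astype(int) + m
    cc = np.rint(pts[:, 1]).astype(int) + m
    keep = (rr >= 0) & (rr < ne) & (cc >= 0) & (cc < ne)
    rr, cc = rr[keep], cc[keep]
    if model.modality == "RPE":
        marker = np.ones((ne, ne), dtype=bool)
        marker[rr, cc] = False
        dist = ndimage.distance_transform_edt(marker)
        img = np.clip(dist / (0.62 * s_center_px), 0.0, 1.0)
        img = 0.15 + 0.7 * img
    else:
        acc = np.zeros((ne, ne))
        np.add.at(acc, (rr, cc), 1.0)
        img = ndimage.gaussian_filter(acc, model.dot_sigma_frac * s_center_px)
        peak = img.max()
        if peak > 0:
            img = img / peak
        img = 0.1 + 0.8 * np.clip(img * 1.2, 0.0, 1.0)
    img = img[m:-m, m:-m]

    quality = np.ones((n, n), dtype=bool)
    vessel = np.zeros((n, n), dtype=bool)
    nonmosaic = np.zeros((n, n), dtype=bool)

    if model.n_vessels > 0:
        width_px = model.vessel_width_um / image.pixel_size_um
        vessel = _draw_vessels(n, model.n_vessels, width_px, rng)
        soft = ndimage.gaussian_filter(vessel.astype(float), width_px / 6.0)
        img = img * (1.0 - 0.85 * np.clip(soft * 1.5, 0.0, 1.0))

    if model.nonmosaic_fraction > 0:
        nonmosaic = _elliptical_patch(n, model.nonmosaic_fraction, rng)
        noise_patch = rng.normal(img[nonmosaic].mean(), 0.05, size=int(nonmosaic.sum()))
        img[nonmosaic] = np.clip(noise_patch, 0.0, 1.0)

    blur_frac = np.clip(
        model.blur_fraction_base
        + model.blur_fraction_age_slope * (eye.age - 23.0),
        0.0,
        0.6,
    )
    if blur_frac > 0:
        blur_region = _elliptical_patch(n, float(blur_frac), rng)
        blurred = ndimage.gaussian_filter(img, 1.5 * s_center_px)
        img = np.where(blur_region, blurred, img)
        quality = ~blur_region

    if model.noise_sd > 0:
        img = img + rng.normal(0.0, model.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    image.pixels = np.rint(img * 65535).astype(np.uint16)

    mosaic = quality & ~vessel & ~nonmosaic
    masks = MaskSet(quality_visible=quality, vessel=vessel, mosaic=mosaic)
    inside = (
        (pts[:, 0] >= -0.5)
        & (pts[:, 0] < n - 0.5)
        & (pts[:, 1] >= -0.5)
        & (pts[:, 1] < n - 0.5)
    )
    return RenderResult(image=image, centroids_px=pts[inside], masks=masks)


def generate_cohort(
    config: SyntheticCohortConfig, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: one eyes table and one image manifest.

    Demographics are sampled once per participant, axial length once per
    eye (shared by all of that eye's images).  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    eye_rows = []
    img_rows = []
    for p in range(config.n_participants):
        age = float(rng.uniform(*config.age_range))
        gender = "female" if rng.random() < 0.5 else "male"
        sides = ["OD", "OS"] if rng.random() < config.fraction_both_eyes else [
            "OD" if rng.random() < 0.5 else "OS"
        ]
        for side in sides:
            eye_id = f"P{p:03d}_{side}"
            axial = float(
                np.clip(
                    rng.normal(config.axial_length_mean, config.axial_length_sd),
                    20.0,
                    30.0,
                )
            )
            eye_rows.append(
                {
                    "eye_id": eye_id,
                    "side": side,
                    "age": round(age, 1),
                    "gender": gender,
                    "axial_length_mm": round(axial, 3),
                    "spherical_equivalent": round(float(rng.normal(0.0, 1.5)), 2),
                    "visual_acuity": round(float(np.clip(rng.normal(1.0, 0.15), 0.5, 1.6)), 2),
                }
            )
            for z, (zx, zy) in enumerate(config.zones):
                for modality in config.modalities:
                    img_rows.append(
                        {
                            "image_id": f"{eye_id}_{modality}_z{z}",
                            "eye_id": eye_id,
                            "modality": modality,
                            "center_x_deg": zx,
                            "center_y_deg": zy,
                            "path": f"{eye_id}_{modality}_z{z}.tif",
                        }
                    )
    eyes = pd.DataFrame(
        eye_rows,
        columns=[
            "eye_id",
            "side",
            "age",
            "gender",
            "axial_length_mm",
            "spherical_equivalent",
            "visual_acuity",
        ],
    )
    manifest = pd.DataFrame(
        img_rows,
        columns=["image_id", "eye_id", "modality", "center_x_deg", "center_y_deg", "path"],
    )
    return eyes, manifest


def generate_rater_matrix(
    true_counts: Sequence[int],
    k: int = 5,
    miss_rate: float = 0.05,
    extra_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate independent manual counts of the same patches.

    Each rater's count is the true count minus binomial misses plus Poisson
    spurious detections.  Emulates a multi-rater annotation experiment.
    """
    if k < 2:
        raise ValueError("at least 2 raters are required")
    if not (0 <= miss_rate < 1 and 0 <= extra_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    true_counts = np.asarray(true_counts, dtype=int)
    counts = np.empty((len(true_counts), k), dtype=int)
    for j in range(k):
        misses = rng.binomial(true_counts, miss_rate)
        extras = rng.poisson(extra_rate * true_counts)
        counts[:, j] = true_counts - misses + extras
    df = pd.DataFrame(counts, columns=[f"rater_{j + 1}" for j in range(k)])
    df.insert(0, "patch_id", [f"patch_{i:03d}" for i in range(len(true_counts))])
    return df


def per_image_seed(seed: int, index: int) -> int:
    """Stable per-image sub-seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))
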