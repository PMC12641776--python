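"""Quality, vessel and mosaic masking of AO acquisitions.

Cell morphometry is only meaningful where the cellular mosaic is actually
resolved, so every image is reduced to three boolean layers before any cell
is detected:

``quality_visible``
    In-focus, analyzable retina: local high-frequency energy above a
    threshold relative to the image's own sharp regions.
``vessel``
    Retinal blood vessels, which appear as dark elongated ribbons and
    interfere with cell segmentation; detected with a multi-scale ridge
    (tubeness) filter plus an elongation check.
``mosaic``
    Where the target cellular structure is clearly present: visible,
    vessel-free area whose local spectrum is dominated by the expected
    cell-spacing frequency band.

The mosaic layer is by construction a subset of ``quality_visible AND NOT
vessel``.  All detector thresholds are configuration values, not facts about
the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure


@dataclass
class MaskSet:
    """Boolean mask layers of one acquisition (True = member)."""

    quality_visible: np.ndarray
    vessel: np.ndarray
    mosaic: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.quality_visible.shape,
            self.vessel.shape,
            self.mosaic.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"mask layers differ in shape: {shapes}")
        visible = self.quality_visible & ~self.vessel
        if np.any(self.mosaic & ~visible):
            raise ValueError("mosaic mask must be a subset of visible AND NOT vessel")

    @property
    def masked_fraction(self) -> float:
        """Fraction of the frame excluded from mosaic analysis."""
        return float(1.0 - self.mosaic.mean())


@dataclass
class MaskParams:
    """Tunables of the masking stage (all invented defaults, in pixels)."""

    quality_highpass_sigma: float = 4.0
    quality_window: int = 15
    quality_threshold_rel: float = 0.05
    vessel_sigmas: tuple = (8.0, 16.0, 32.0)
    vessel_threshold_rel: float = 0.25
    vessel_dark_frac: float = 0.75
    vessel_min_size_px: int = 2000
    mosaic_band_sigma_frac: float = 0.18
    mosaic_band_threshold: float = 0.03
    mosaic_smooth_scales: float = 0.75
    mosaic_erosion_frac: float = 1.0
    closing_radius: int = 3


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return rr * rr + cc * cc <= radius * radius


def _close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with edge-replicated padding (no border loss)."""
    if radius <= 0:
        return mask
    p = np.pad(mask, radius, mode="edge")
    return ndimage.binary_closing(p, structure=_disk(radius))[radius:-radius, radius:-radius]


def _erode(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    p = np.pad(mask, radius, mode="edge")
    return ndimage.binary_erosion(p, structure=_disk(radius))[radius:-radius, radius:-radius]


def _normalize(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img


def build_quality_mask(image: np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """In-focus mask: local variance of a high-pass response above threshold.

    The threshold is relative to the 90th percentile of the local energy, so
    the decision is invariant to the intensity scale; a constant image has
    zero high-pass energy everywhere and yields an all-false mask.
    """
    params = params or MaskParams()
    img = _normalize(image)
    hp = img - ndimage.gaussian_filter(img, params.quality_highpass_sigma)
    energy = ndimage.uniform_filter(hp * hp, size=params.quality_window)
    thr = params.quality_threshold_rel * np.percentile(energy, 90)
    mask = energy > thr
    return _close(mask, params.closing_radius)


def build_vessel_mask(image: np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """Vessel mask: dark elongated ridges from a multi-scale tubeness filter.

    A pixel is a vessel candidate when the tubeness response of the
    inverted, texture-suppressed image is high *and* the pixel is darker
    than the smoothed image's median (vessels absorb light); connected
    candidate components below a minimum size are rejected.  An all-bright
    image has no dark ridges and yields an empty mask.
    """
    params = params or MaskParams()
    img = _normalize(image)
    # Suppress cell-scale texture before ridge filtering.
    smooth = ndimage.gaussian_filter(img, params.vessel_sigmas[0])
    response = filters.sato(1.0 - smooth, sigmas=params.vessel_sigmas, black_ridges=False)
    peak = response.max()
    if peak <= 0:
        return np.zeros_like(img, dtype=bool)
    dark = smooth < params.vessel_dark_frac * np.median(smooth)
    raw = (response > params.vessel_threshold_rel * peak) & dark
    raw = _close(raw, params.closing_radius)
    out = np.zeros_like(raw)
    labels = measure.label(raw)
    for region in measure.regionprops(labels):
        if region.area >= params.vessel_min_size_px:
            out[labels == region.label] = True
    return out


def build_mosaic_mask(
    image: np.ndarray,
    quality: np.ndarray,
    vessel: np.ndarray,
    expected_spacing_px: float,
    params: MaskParams | None = None,
) -> MaskSet:
    """Assemble the full mask set, adding the periodicity criterion.

    A region belongs to the mosaic when the local energy of a band-pass
    response matched to the expected cell spacing dominates the local
    broadband high-frequency energy.  Structureless noise spreads its energy
    across the spectrum and falls below the band-dominance threshold.
    """
    params = params or MaskParams()
    img = _normalize(image)
    s = expected_spacing_px
    sigma1 = params.mosaic_band_sigma_frac * s
    band = ndimage.gaussian_filter(img, sigma1) - ndimage.gaussian_filter(img, 1.6 * sigma1)
    broad = img - ndimage.gaussian_filter(img, 2.0 * s)
    w = params.mosaic_smooth_scales * s
    band_energy = ndimage.gaussian_filter(band * band, w)
    broad_energy = ndimage.gaussian_filter(broad * broad, w)
    ratio = band_energy / (broad_energy + 1e-12)
    periodic = ratio > params.mosaic_band_threshold
    periodic = _close(periodic, params.closing_radius)
    # Local energy smoothing smears mosaic-band energy past the true mosaic
    # boundary; an erosion of one expected spacing trims the halo.
    periodic = _erode(periodic, int(round(params.mosaic_erosion_frac * s)))
    mosaic = periodic & quality & ~vessel
    return MaskSet(quality_visible=quality, vessel=vessel, mosaic=mosaic)


def visible_mosaic_area_ratio(masks: MaskSet) -> float:
    """Area of resolved mosaic over all analyzable (visible, vessel-free) area.

    Raises
    ------
    ValueError
        When the image has no visible area at all.
    """
    visible = masks.quality_visible & ~masks.vessel
    denom = int(visible.sum())
    if denom == 0:
        raise ValueError("no visible area: mosaic-area ratio undefined")
    return float(masks.mosaic.sum() / denom)
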