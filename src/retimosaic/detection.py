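"""Cell-centroid detection on masked AO images.

A band-pass (difference-of-Gaussians) filter matched to the expected cell
spacing is followed by local-maxima extraction with a minimum separation of
half the expected spacing.  Photoreceptors are bright dots and are detected
directly; RPE cells appear as dim honeycomb centres surrounded by bright
borders, so the image is inverted first.  Only maxima falling inside the
mosaic mask are kept.

The expected spacing comes from the modality's nominal density through the
hexagonal-packing relation ``density = 2 / (sqrt(3) * spacing**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .masking import MaskSet

SQRT3 = float(np.sqrt(3.0))


def hex_spacing_from_density(density_per_mm2: float) -> float:
    """Centre-to-centre spacing (mm) of a hexagonal lattice at a density."""
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    return float(np.sqrt(2.0 / (SQRT3 * density_per_mm2)))


def hex_density_from_spacing(spacing_mm: float) -> float:
    """Density (cells/mm²) of a hexagonal lattice from its spacing (mm)."""
    return 2.0 / (SQRT3 * spacing_mm**2)


@dataclass
class DetectorParams:
    """Tunables of the centroid detector (invented defaults).

    ``sigma_frac`` sets the inner difference-of-Gaussians scale as a
    fraction of the expected spacing; the outer scale is 1.6x larger.
    ``min_sep_frac`` is the minimum peak separation as a fraction of the
    expected spacing.  ``threshold_rel`` rejects maxima weaker than this
    fraction of the strongest band-pass response.
    """

    sigma_frac: float = 0.15
    min_sep_frac: float = 0.4
    threshold_rel: float = 0.05


def detect_centroids(
    image: np.ndarray,
    masks: MaskSet,
    modality: str,
    expected_spacing_px: float,
    params: DetectorParams | None = None,
) -> np.ndarray:
    """Detect cell centroids inside the mosaic mask.

    Parameters
    ----------
    image:
        2-D intensity grid.
    masks:
        Mask layers; only centroids on mosaic pixels are returned.
    modality:
        ``"PR"`` (bright dots) or ``"RPE"`` (dark centres, inverted response).
    expected_spacing_px:
        Expected centre-to-centre cell spacing in pixels.

    Returns
    -------
    (N, 2) float array of (row, col) centroid positions, deterministic for
    identical inputs.  Empty when the mosaic mask is empty.
    """
    params = params or DetectorParams()
    if not masks.mosaic.any():
        return np.empty((0, 2))
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    if modality == "RPE":
        img = 1.0 - img
    elif modality != "PR":
        raise ValueError(f"modality must be 'RPE' or 'PR', got {modality!r}")

    s1 = params.sigma_frac * expected_spacing_px
    dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, 1.6 * s1)
    # Euclidean minimum separation: disc footprint, not the default square.
    r = max(1, int(round(params.min_sep_frac * expected_spacing_px)))
    rr, cc = np.ogrid[-r : r + 1, -r : r + 1]
    footprint = rr * rr + cc * cc <= r * r
    peaks = peak_local_max(
        dog,
        footprint=footprint,
        threshold_abs=params.threshold_rel * dog.max(),
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    keep = masks.mosaic[peaks[:, 0], peaks[:, 1]]
    return peaks[keep].astype(float)
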