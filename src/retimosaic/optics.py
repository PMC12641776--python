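"""Ocular magnification scaling and the fixation-based retinal coordinate system.

Adaptive-optics fundus images are acquired on a fixed angular field of view
(6.7° by default, 2048 px square), so the physical size of a pixel on the
retina depends on the eye's optics.  Following Bennett–Littmann, the retinal
magnification is a linear function of axial length, which gives the
micrometre-per-pixel scale used by all downstream morphometry.

Coordinates are expressed in degrees of visual angle relative to the fixation
target (an approximation of the foveal centre).  The horizontal axis is
mirrored between right (OD) and left (OS) eyes so that +x always points to
the temporal retina; +y points to the superior retina for both eyes.
Eccentricity is the radial distance from fixation, signed by the horizontal
component: positive temporal, negative nasal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

#: Bennett–Littmann axial-length offset (mm); the linear magnification model
#: passes through zero at this internal reference length.
AXIAL_LENGTH_OFFSET_MM = 1.82

#: Scale constants of the pixel-size model (device optics x schematic eye).
_PIXEL_SIZE_SCALE = 0.504 * 0.01306 * 6.5

DEFAULT_FOV_DEG = 6.7
DEFAULT_IMAGE_SIZE = 2048


class InvalidBiometryError(ValueError):
    """Axial length incompatible with the magnification model."""


def bennett_littmann_pixel_size(axial_length: float) -> float:
    """Pixel size on the retina, in micrometres, from axial length in mm.

    The model is linear in axial length::

        pixel_size(um) = 0.504 * 0.01306 * (axial_length - 1.82) * 6.5

    Parameters
    ----------
    axial_length:
        Axial length of the eye in millimetres.  Must exceed 1.82 mm, the
        zero of the linear form.

    Returns
    -------
    float
        Micrometres per pixel at the retina.
    """
    if not np.all(np.asarray(axial_length) > AXIAL_LENGTH_OFFSET_MM):
        raise InvalidBiometryError(
            f"axial length must exceed {AXIAL_LENGTH_OFFSET_MM} mm, "
            f"got {axial_length!r}"
        )
    return _PIXEL_SIZE_SCALE * (axial_length - AXIAL_LENGTH_OFFSET_MM)


@dataclass(frozen=True)
class EyeMeta:
    """Per-eye demographics and optical biometry.

    Attributes
    ----------
    eye_id:
        Opaque identifier of the eye.
    side:
        ``"OD"`` (right) or ``"OS"`` (left).
    age:
        Age of the participant in years.
    gender:
        ``"female"`` or ``"male"``.
    axial_length:
        Axial length in mm; drives the retinal magnification.
    spherical_equivalent, visual_acuity:
        Optional refraction (dioptres) and decimal acuity.
    """

    eye_id: str
    side: str
    age: float
    gender: str
    axial_length: float
    spherical_equivalent: Optional[float] = None
    visual_acuity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side not in ("OD", "OS"):
            raise ValueError(f"side must be 'OD' or 'OS', got {self.side!r}")
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.axial_length <= AXIAL_LENGTH_OFFSET_MM:
            raise InvalidBiometryError(
                f"axial length must exceed {AXIAL_LENGTH_OFFSET_MM} mm, "
                f"got {self.axial_length}"
            )

    @property
    def pixel_size_um(self) -> float:
        """Micrometres per pixel for the default angular sampling."""
        return bennett_littmann_pixel_size(self.axial_length)


@dataclass
class ImageRecord:
    """One AO acquisition: pixel grid plus its placement on the retina.

    ``center_deg`` is the (x°, y°) global coordinate of the image centre
    relative to the fixation target, already in the mirrored (+x temporal)
    convention.
    """

    eye: EyeMeta
    modality: str
    pixels: np.ndarray
    center_deg: Tuple[float, float]
    fov_deg: float = DEFAULT_FOV_DEG
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.modality not in ("RPE", "PR"):
            raise ValueError(f"modality must be 'RPE' or 'PR', got {self.modality!r}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"pixels must be square 2-D, got shape {self.pixels.shape}")
        if self.fov_deg <= 0:
            raise ValueError("fov_deg must be positive")

    @property
    def n_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_size_um(self) -> float:
        return bennett_littmann_pixel_size(self.eye.axial_length)

    @property
    def deg_per_px(self) -> float:
        return self.fov_deg / self.n_px


def pixel_to_global_degrees(row, col, image: ImageRecord):
    """Map pixel indices to global macular coordinates in degrees.

    Pixel ``(r, c)`` refers to the centre of that pixel, so the image centre
    sits at pixel coordinate ``((n-1)/2, (n-1)/2)`` and maps exactly to
    ``image.center_deg``.  Rows increase downward in the raster and map to
    decreasing y° (+y° = superior retina).  The horizontal axis is mirrored
    between eye sides here — and only here — so every downstream consumer
    sees +x° = temporal regardless of OD/OS.

    Accepts scalars or arrays; returns ``(x_deg, y_deg)`` of matching shape.
    """
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    n = image.n_px
    if np.any(row < -0.5) or np.any(row > n - 0.5) or np.any(col < -0.5) or np.any(col > n - 0.5):
        raise IndexError("pixel coordinates outside the image grid")
    half = (n - 1) / 2.0
    scale = image.deg_per_px
    # Raster columns increase toward the temporal side on OD by convention;
    # OS is mirrored so +x stays temporal.
    sign = 1.0 if image.eye.side == "OD" else -1.0
    x = image.center_deg[0] + sign * (col - half) * scale
    y = image.center_deg[1] + (half - row) * scale
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def signed_eccentricity(x, y):
    """Signed radial eccentricity in degrees: ``sign(x) * hypot(x, y)``.

    Positive on the temporal side, negative on the nasal side; ``sign(0)``
    is taken as +1 so the result is negative only for strictly nasal
    coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    e = np.where(x < 0, -1.0, 1.0) * np.hypot(x, y)
    if e.ndim == 0:
        return float(e)
    return e
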