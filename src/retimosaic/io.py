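"""Reading and writing the pipeline's on-disk formats.

Eye metadata and image manifests are CSV; images are 16-bit grayscale TIFF
(or PNG); masks are single-channel 0/255 PNG; per-image cell tables and all
aggregates are CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from .masking import MaskSet
from .optics import EyeMeta, ImageRecord

EYES_COLUMNS = [
    "eye_id", "side", "age", "gender",
    "axial_length_mm", "spherical_equivalent", "visual_acuity",
]
MANIFEST_COLUMNS = [
    "image_id", "eye_id", "modality", "center_x_deg", "center_y_deg", "path",
]
CELL_COLUMNS = [
    "image_id", "cell_id", "row_px", "col_px", "x_deg", "y_deg", "ecc_deg",
    "area_um2", "perimeter_um", "n_neighbors", "boundary_flag",
]


def read_eyes_csv(path) -> Dict[str, EyeMeta]:
    """Load the per-eye metadata table into EyeMeta objects keyed by eye_id."""
    df = pd.read_csv(path)
    eyes: Dict[str, EyeMeta] = {}
    for _, row in df.iterrows():
        eyes[str(row["eye_id"])] = EyeMeta(
            eye_id=str(row["eye_id"]),
            side=str(row["side"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            axial_length=float(row["axial_length_mm"]),
            spherical_equivalent=(
                float(row["spherical_equivalent"])
                if "spherical_equivalent" in row and pd.notna(row["spherical_equivalent"])
                else None
            ),
            visual_acuity=(
                float(row["visual_acuity"])
                if "visual_acuity" in row and pd.notna(row["visual_acuity"])
                else None
            ),
        )
    return eyes


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_image(path, pixels: np.ndarray) -> None:
    """Write a 16-bit grayscale image as TIFF or PNG by extension."""
    path = Path(path)
    arr = np.asarray(pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.uint16))
    else:
        PILImage.fromarray(arr.astype(np.uint16)).save(path)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(PILImage.open(path))


def write_mask_png(path, mask: np.ndarray) -> None:
    PILImage.fromarray((mask.astype(np.uint8)) * 255).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(PILImage.open(path)) > 127


def write_maskset(directory, image_id: str, masks: MaskSet) -> None:
    directory = Path(directory)
    write_mask_png(directory / f"{image_id}_quality.png", masks.quality_visible)
    write_mask_png(directory / f"{image_id}_vessel.png", masks.vessel)
    write_mask_png(directory / f"{image_id}_mosaic.png", masks.mosaic)


def read_maskset(directory, image_id: str) -> MaskSet:
    directory = Path(directory)
    return MaskSet(
        quality_visible=read_mask_png(directory / f"{image_id}_quality.png"),
        vessel=read_mask_png(directory / f"{image_id}_vessel.png"),
        mosaic=read_mask_png(directory / f"{image_id}_mosaic.png"),
    )


def write_cells_csv(path, image_id: str, cells: pd.DataFrame) -> None:
    out = cells.copy()
    out.insert(0, "cell_id", np.arange(len(out)))
    out.insert(0, "image_id", image_id)
    out[CELL_COLUMNS].to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
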