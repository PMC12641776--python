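"""Run configuration: every pipeline constant in one auditable place.

Constants fall into two provenance classes, recorded in the emitted
provenance dictionary: ``protocol`` values define the analysis itself
(field of view, grid size, cell-count filter, mask-exclusion threshold,
central cone exclusion band, bin count), while ``tuned`` values are
implementation choices of the classical detector and masking stage with no
protocol meaning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import yaml

from .detection import DetectorParams
from .masking import MaskParams

#: Nominal mosaic densities (cells/mm²) used only to set the expected cell
#: spacing of the matched filters, per modality.
NOMINAL_DENSITY = {"RPE": 6313.0, "PR": 10207.0}


@dataclass
class RunConfig:
    """All stage parameters of an end-to-end run."""

    fov_deg: float = 6.7
    image_size: int = 2048
    grid_px: int = 256
    min_cells_per_grid: int = 200
    max_masked_fraction: float = 0.90
    pr_exclusion_deg: float = 2.5
    n_bins: int = 25
    ecc_range: Tuple[float, float] = (-10.0, 10.0)
    match_tol_deg: float = 6.7 * 256 / 2048 / 2  # half a grid-square width
    nominal_density: Dict[str, float] = field(default_factory=lambda: dict(NOMINAL_DENSITY))
    mask_params: MaskParams = field(default_factory=MaskParams)
    detector_params: DetectorParams = field(default_factory=DetectorParams)
    seed: int = 0

    def provenance(self) -> dict:
        """Serializable record of every constant and its provenance class."""
        protocol = {
            "fov_deg": self.fov_deg,
            "image_size": self.image_size,
            "grid_px": self.grid_px,
            "min_cells_per_grid": self.min_cells_per_grid,
            "max_masked_fraction": self.max_masked_fraction,
            "pr_exclusion_deg": self.pr_exclusion_deg,
            "n_bins": self.n_bins,
            "ecc_range": list(self.ecc_range),
        }
        tuned = {
            "match_tol_deg": self.match_tol_deg,
            "nominal_density": dict(self.nominal_density),
            "mask_params": dataclasses.asdict(self.mask_params),
            "detector_params": dataclasses.asdict(self.detector_params),
        }
        return {"protocol": protocol, "tuned": tuned, "seed": self.seed}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.provenance(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw: dict = {}
        kw.update(raw.get("protocol", {}))
        tuned = raw.get("tuned", {})
        if "ecc_range" in kw:
            kw["ecc_range"] = tuple(kw["ecc_range"])
        if "match_tol_deg" in tuned:
            kw["match_tol_deg"] = tuned["match_tol_deg"]
        if "nominal_density" in tuned:
            kw["nominal_density"] = dict(tuned["nominal_density"])
        if "mask_params" in tuned:
            mp = dict(tuned["mask_params"])
            if "vessel_sigmas" in mp:
                mp["vessel_sigmas"] = tuple(mp["vessel_sigmas"])
            kw["mask_params"] = MaskParams(**mp)
        if "detector_params" in tuned:
            kw["detector_params"] = DetectorParams(**tuned["detector_params"])
        if "seed" in raw:
            kw["seed"] = raw["seed"]
        return cls(**kw)
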