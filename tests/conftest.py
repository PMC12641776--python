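import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from retimosaic import EyeMeta, MosaicModelConfig, render_mosaic_image

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def eye():
    return EyeMeta(
        eye_id="E01", side="OD", age=50.0, gender="female", axial_length=24.0
    )


@pytest.fixture(scope="session")
def eye_os():
    return EyeMeta(eye_id="E02", side="OS", age=50.0, gender="male", axial_length=24.0)


@pytest.fixture(scope="session")
def clean_rpe_scene(eye):
    """Clean uniform-density RPE honeycomb, 512 px, full visibility."""
    model = MosaicModelConfig.clean("RPE", 6313.0, noise_sd=0.03)
    return render_mosaic_image(eye, (0.0, 0.0), model, seed=11, image_size=512)


@pytest.fixture(scope="session")
def clean_pr_scene(eye):
    """Clean uniform-density cone mosaic, 512 px, full visibility."""
    model = MosaicModelConfig.clean("PR", 10207.0, noise_sd=0.03)
    return render_mosaic_image(eye, (5.0, 0.0), model, seed=12, image_size=512)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
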