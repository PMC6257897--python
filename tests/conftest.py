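import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leukocount as lk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> lk.PipelineConfig:
    return lk.PipelineConfig()


@pytest.fixture(scope="session")
def small_smear():
    """One neutrophil + one lymphocyte + platelets at reference
    resolution, seeded once per session."""
    recipe = lk.SmearRecipe(
        cells=(
            lk.make_cell(lk.WBCClass.NEUTROPHIL, (350.0, 350.0), lobe_angle_deg=30.0),
            lk.make_cell(lk.WBCClass.LYMPHOCYTE, (1100.0, 800.0)),
        ),
        n_platelets=6,
        seed=42,
    )
    img, labels, truth = lk.generate_smear(recipe)
    return recipe, img, labels, truth


def labeled_from_mask(mask: np.ndarray, connectivity: int = 8) -> lk.LabeledMask:
    return lk.label_components(np.asarray(mask, dtype=bool), connectivity)
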