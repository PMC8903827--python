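import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazepolarity import eye_image as ei

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def human_stimulus():
    return ei.render_eye_stimulus(ei.default_geometry("human"), ei.default_appearance("human"))


@pytest.fixture(scope="session")
def chimp_stimulus():
    return ei.render_eye_stimulus(
        ei.default_geometry("chimpanzee"), ei.default_appearance("chimpanzee")
    )


@pytest.fixture(scope="session")
def both_stimuli(human_stimulus, chimp_stimulus):
    return {"human": human_stimulus, "chimpanzee": chimp_stimulus}


def max_delta_e(img_a, img_b) -> float:
    lab_a = ei.image_to_lab(img_a.pixels)
    lab_b = ei.image_to_lab(img_b.pixels)
    return float(np.linalg.norm(lab_a - lab_b, axis=-1).max())
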