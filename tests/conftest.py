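import numpy as np
import pytest

from scalestack.pyramid import PyramidSpec


@pytest.fixture
def spec896():
    """896 x 896 base-20x slide: exactly 1 / 4 / 16 grid tiles at 5/10/20x."""
    return PyramidSpec(slide_id="s896", base_width=896, base_height=896)


@pytest.fixture
def tiny_cohort():
    """4 classes x 6 slides, 4x4 base grid, 8-dim embeddings (fast)."""
    from scalestack.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_classes=4,
        slides_per_class=6,
        tiles_base=4,
        embedding_dim=8,
        n_phenotypes=4,
        separation=8.0,
        noise_sd=1.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
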