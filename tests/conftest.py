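import numpy as np
import pytest

from cscmap import synthgen


@pytest.fixture(scope="session")
def small_scene():
    """A modest tissue scene with contacts, reused by several tests."""
    cfg = synthgen.SceneConfig(
        field_size=(800.0, 800.0),
        n_cells=200,
        csc_fraction_baseline=0.1,
        contact_fraction_by_class={"nonCSC": 0.3, "CSC": 0.65},
        seed=11,
    )
    stack, truth = synthgen.generate_tissue_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def puncta_scene():
    return synthgen.generate_puncta_scene(
        n_cells=40,
        stem_fraction=0.25,
        puncta_per_stem_area=0.02,
        puncta_per_nonstem_area=0.004,
        coloc_fraction=0.8,
        degradation_fraction_by_class={"stem": 0.10, "nonstem": 0.02},
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
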