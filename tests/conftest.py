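import numpy as np
import pytest

import wingmorph as wm

#: compact study design: 6 species in 3 genera, enough structure for the
#: whole pipeline but fast to superimpose and cross-validate
SMALL_SPECIES = (
    ("Ae_one", "Aedes", 12, 3),
    ("Ae_two", "Aedes", 12, 3),
    ("Ae_three", "Aedes", 12, 3),
    ("An_one", "Anopheles", 12, 3),
    ("An_two", "Anopheles", 12, 3),
    ("Cx_one", "Culex", 12, 3),
)


@pytest.fixture(scope="session")
def small_design():
    return wm.SimulationDesign(species=SMALL_SPECIES, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return wm.simulate_landmark_dataset(small_design)


@pytest.fixture(scope="session")
def aligned_shapes(small_dataset):
    dataset, _ = small_dataset
    aligned = wm.generalized_procrustes(dataset)
    return dataset, aligned, wm.tangent_projection(aligned)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_similarity(rng, scale_range=(0.5, 2.0), shift=5.0):
    """A random rotation/scale/translation to apply to a configuration."""
    angle = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    scale = rng.uniform(*scale_range)
    offset = rng.uniform(-shift, shift, size=2)
    return lambda cfg: cfg @ rot.T * scale + offset
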