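import numpy as np
import pytest

from wingmorph import SyntheticSpec, Taxonomy, generate, gpa, tangent_project

SMALL_TAXONOMY = Taxonomy(
    suprafamilies=2,
    families_per_suprafamily=2,
    subfamilies_per_family=2,
    tribes_per_subfamily=2,
    species_per_tribe=2,
    specimens_per_species=3,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(taxonomy=SMALL_TAXONOMY, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    dataset, _ = generate(small_spec)
    return dataset


@pytest.fixture(scope="session")
def small_truth(small_spec):
    _, truth = generate(small_spec)
    return truth


@pytest.fixture(scope="session")
def small_tangent(small_dataset):
    return tangent_project(gpa(small_dataset))


def random_shape(rng, k=5, spread=1.0):
    return rng.normal(0.0, spread, (k, 2))


def similarity_transform(rng, coords, max_shift=5.0):
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    scale = np.exp(rng.normal(0.0, 0.5))
    shift = rng.uniform(-max_shift, max_shift, 2)
    return coords @ rot.T * scale + shift
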