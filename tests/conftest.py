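import numpy as np
import pytest

from habitatrad.habitats import segment_patient
from habitatrad.pipeline import preprocess_patient
from habitatrad.synthetic import CohortSpec, generate_patient


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down cohort spec for fast unit tests."""
    return CohortSpec(
        n_patients=4,
        volume_shape=(32, 32, 32),
        tumor_radius_range=(6.0, 9.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def one_patient(small_spec):
    """One preprocessed (normalized, 1 mm) synthetic patient."""
    return preprocess_patient(generate_patient(small_spec, 0))


@pytest.fixture(scope="session")
def segmented_cohort20():
    """20 default-spec patients with truth and fitted habitat maps.

    Shared by the planted-partition recovery and label-harmonization checks.
    """
    spec = CohortSpec(n_patients=20, seed=11)
    patients, maps = [], []
    for i in range(spec.n_patients):
        p = preprocess_patient(generate_patient(spec, i))
        hmap, rule, _ = segment_patient(p.ace_volume, p.vce_volume, p.roi, seed=0)
        patients.append(p)
        maps.append(hmap)
    return spec, patients, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
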