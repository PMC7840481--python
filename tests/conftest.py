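import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nutrimir import CohortSpec, PlantedEffect, generate_cohort, size_factors


@pytest.fixture(scope="session")
def planted_cohort():
    """A 120-subject cohort with two planted pairs at |rho| = 0.5."""
    spec = CohortSpec(
        n_per_group=40,
        n_mirna=50,
        n_nc=8,
        seed=11,
        planted_pairs=[
            PlantedEffect("miR-0005", "calcium", 0.5),
            PlantedEffect("miR-0012", "iron", -0.5),
        ],
    )
    cm, meta, intake, truth = generate_cohort(spec)
    return spec, size_factors(cm), meta, intake, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted effects."""
    spec = CohortSpec(n_per_group=40, n_mirna=40, n_nc=6, seed=23)
    cm, meta, intake, truth = generate_cohort(spec)
    return spec, size_factors(cm), meta, intake, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_metadata():
    n = 120
    r = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "diet_group": np.repeat(["omnivore", "vegetarian", "vegan"], n // 3),
            "age": r.normal(45, 10, n).round(1),
            "sex": r.choice(["F", "M"], n),
            "bmi": r.normal(23, 3, n).round(1),
        }
    )
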