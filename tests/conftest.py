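import numpy as np
import pandas as pd
import pytest

from matchedcv import (
    CohortTable,
    ModalityBlock,
    PlantedEffect,
    SimConfig,
    generate_cohort,
)


def toy_cohort(labels, propensities, markers=None, ids=None, **demo):
    """Hand-built CohortTable for targeted unit tests."""
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if ids is None:
        ids = [f"t{i:03d}" for i in range(n)]
    data = pd.DataFrame(
        {
            "label": labels,
            "age": demo.get("age", np.full(n, 10.0)),
            "sex": demo.get("sex", ["M"] * n),
            "race_ethnicity": demo.get("race_ethnicity", ["White"] * n),
            "propensity": np.asarray(propensities, dtype=float),
        },
        index=pd.Index(ids, name="participant_id"),
    )
    modality_map = {}
    if markers is not None:
        for name, values in markers.items():
            data[name] = np.asarray(values, dtype=float)
            modality_map[name] = "s-MRI"
    return CohortTable(data, modality_map)


@pytest.fixture
def make_toy_cohort():
    return toy_cohort


SMALL_CONFIG = SimConfig(
    n_participants=800,
    prevalence=0.05,
    modality_blocks=(
        ModalityBlock("s-MRI", 6, 0.3),
        ModalityBlock("SDSC", 4, 0.2),
    ),
    planted_effects=(PlantedEffect("sdsc_001", 0.6, +1),),
    confounding_strength=0.3,
    near_duplicate_pairs=1,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """800 participants, 5% prevalence, 10 markers; fast enough for CV tests."""
    return generate_cohort(SMALL_CONFIG)
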