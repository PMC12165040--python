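"""Shared fixtures: small synthetic datasets and fitted models.

Everything is generated programmatically and seeded, so the suite needs
no data files and is bit-reproducible.
"""

import numpy as np
import pytest

from omicsformer.blood_risk import BloodRiskConfig, build_risk_model
from omicsformer.dataio import OmicsMatrix
from omicsformer.preprocess import PreprocessRecipe, preprocess_dataset
from omicsformer.synthetic import CohortSpec, generate_blood_panel, generate_multiomics_cohort
from omicsformer.training import TrainingConfig, fit_classifier


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(
        group_sizes=(30, 15, 15),
        layer_features={"alpha": 40, "beta": 25},
        informative_per_layer=8,
        effect_size=3.0,
        missing_rate=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_multiomics_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_recipe():
    return PreprocessRecipe(impute_factor=1.0)


@pytest.fixture(scope="session")
def tiny_pre(tiny_cohort, tiny_recipe):
    dataset, _ = tiny_cohort
    return preprocess_dataset(dataset, tiny_recipe).dataset


@pytest.fixture(scope="session")
def tiny_config():
    return TrainingConfig(
        seed=3, pretrain_epochs=150, finetune_epochs=60, d_hidden=16, d_mul=8
    )


@pytest.fixture(scope="session")
def tiny_fit(tiny_pre, tiny_config):
    return fit_classifier(tiny_pre, tiny_config)


@pytest.fixture(scope="session")
def small_panel():
    return generate_blood_panel(n=60, group_sizes=(30, 16, 14), separation=6.0, seed=11)


@pytest.fixture(scope="session")
def risk_model(small_panel):
    panel, _ = small_panel
    return build_risk_model(panel, BloodRiskConfig(seed=5, epochs=150))


@pytest.fixture()
def na_matrix():
    """3x2 matrix with exactly one missing entry."""
    values = np.array([[1.0, 2.0], [np.nan, 4.0], [5.0, 6.0]])
    return OmicsMatrix(values, ["s1", "s2", "s3"], ["f1", "f2"], "demo")
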