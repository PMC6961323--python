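import numpy as np
import pandas as pd
import pytest

import peddrugsafe as pds


def make_encounters(drug_rows, dx_rows, encounter_ids=None):
    """Build an EncounterTable from (encounter, code) tuples."""
    med = pd.DataFrame(drug_rows, columns=["encounter_id", "drug_code"])
    dx = pd.DataFrame(dx_rows, columns=["encounter_id", "diagnosis_code"])
    return pds.EncounterTable(med, dx, encounter_ids=encounter_ids)


@pytest.fixture
def tiny_encounters():
    """3 encounters, 2 drugs, 2 diagnoses."""
    return make_encounters(
        [("e1", "A"), ("e1", "B"), ("e2", "A"), ("e3", "B")],
        [("e1", "x"), ("e2", "y"), ("e3", "x")],
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """Small strong-signal cohort reused by several integration tests."""
    cfg = pds.preset(
        "strong",
        seed=11,
        n_encounters=1500,
        n_drugs=40,
        n_diagnoses=60,
        n_unassociated_drugs=5,
    )
    enc, truth = pds.generate_cohort(cfg)
    return cfg, enc, truth


@pytest.fixture(scope="session")
def strong_fit(strong_cohort):
    cfg, enc, truth = strong_cohort
    model = pds.DrugSafetyModel(
        enc,
        labels=pds.generate_labels(cfg, truth),
        clustering=pds.ClusteringConfig(k_min=2, k_max=8, B=10),
    )
    return model.fit(seed=5), truth


def random_binmat(rng, n_drugs, n_dx, density=0.3):
    mat = (rng.random((n_drugs, n_dx)) < density).astype(np.int8)
    return pd.DataFrame(
        mat,
        index=[f"D{i}" for i in range(n_drugs)],
        columns=[f"G{j}" for j in range(n_dx)],
    )
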