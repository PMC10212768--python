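import numpy as np
import pandas as pd
import pytest

from mmpt.synthetic import CohortConfig, TreatmentSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 samples, light wells; cells + layout only."""
    cfg = CohortConfig(n_samples=4, n_cells_per_well=300,
                       n_latent_features=10, seed=11)
    return generate_cohort(cfg, with_omics=False)


@pytest.fixture(scope="session")
def scored_cohort():
    """Cohort sized for drug-response assertions: one concentration,
    plasma-rich samples, known kills."""
    panel = (TreatmentSpec("killerA"), TreatmentSpec("killerB"),
             TreatmentSpec("inert"), TreatmentSpec("mab", kind="antibody"))
    kills = {
        "killerA": {"myeloma": 0.5},
        "killerB": {"myeloma": 0.3, "small": 0.1},
        "inert": {},
        "mab": {"myeloma": 0.4},
    }
    cfg = CohortConfig(n_samples=3, n_cells_per_well=1300,
                       n_latent_features=2, drug_panel=panel,
                       kill_fractions=kills, concentrations=(1.0,),
                       mode_assignment=[0, 0, 0], seed=21)
    return generate_cohort(cfg, with_omics=False)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_cells():
    """Hand-built cell table for arithmetic-level assertions."""
    return pd.DataFrame({
        "sample_id": ["s1"] * 6,
        "well_id": ["A01"] * 6,
        "cell_id": [f"c{i}" for i in range(6)],
        "cell_class": ["plasma", "plasma", "plasma", "plasma",
                       "t_cell", "monocyte"],
        "class_confidence": [0.9] * 6,
        "plasma_subtype": ["myeloma", "myeloma", "small", "small",
                           "none", "none"],
        "t_subtype": ["none"] * 4 + ["activated", "none"],
        "x_um": [0.0, 100.0, 200.0, 300.0, 5.0, 500.0],
        "y_um": [0.0] * 6,
        "diameter_um": [14.0, 15.0, 8.0, 8.0, 9.0, 10.0],
        "CD138": [100.0, 100.0, 100.0, 100.0, 1.0, 1.0],
        "CD319": [100.0, 100.0, 100.0, 100.0, 1.0, 1.0],
        "CD3": [1.0, 1.0, 1.0, 1.0, 100.0, 1.0],
        "CD14": [1.0, 1.0, 1.0, 1.0, 1.0, 100.0],
        "DAPI": [50.0] * 6,
    })
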