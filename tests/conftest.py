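import numpy as np
import pytest

from allocart import (
    CELL_SCHEDULE,
    PopulationModel,
    StudyTemplate,
    generate_study,
    run_npc,
    typical_subject,
)
from allocart.synthetic import archetype_regimen


@pytest.fixture(scope="session")
def pop():
    return PopulationModel.default()


@pytest.fixture(scope="session")
def reg40():
    return archetype_regimen(40.0)


@pytest.fixture(scope="session")
def typical(pop):
    return typical_subject(pop)


@pytest.fixture(scope="session")
def study(pop):
    """One generated virtual trial shared across tests."""
    return generate_study(StudyTemplate(), pop, seed=101)


@pytest.fixture(scope="session")
def study_covariates(study):
    return [
        {
            "allo_active": bool(r.ALLO_ACTIVE),
            "trunc_active": bool(r.TRUNC_ACTIVE),
            "dose_fractions": (r.FSCM, r.FCM, r.FEM),
            "refHostNK": r.REFNK,
            "refHostT": r.REFHOSTT,
        }
        for r in study.covariates.itertuples()
    ]


@pytest.fixture(scope="session")
def npc_result(pop, study, study_covariates):
    """The numerical predictive check at reduced replicate count."""
    return run_npc(
        pop, study.regimens, n_reps=100, seed=2024, covariates=study_covariates
    )
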