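"""Shared fixtures.

The expensive fixtures (healing-simulation cohorts) are session-scoped and
deliberately small; every simulation is generated at run time from the
synthetic-cohort module.
"""

from __future__ import annotations

import numpy as np
import pytest

from bcsheal.cohort import CohortDesign, PatientCharacteristics, sample_characteristics
from bcsheal.fem import SolverConfig, simulate_patient
from bcsheal.kinetics import default_params
from bcsheal.outcomes import outcome_from_simulation
from bcsheal.pipeline import simulate_cohort


@pytest.fixture(scope="session")
def median_patient():
    """Cohort-median characteristics (small tumor, median breast)."""
    return PatientCharacteristics(0.2595, 1485.32, 755_890.0, 19.74, 0.0, seed=11)


@pytest.fixture(scope="session")
def small_mesh(median_patient):
    from bcsheal.cohort import build_geometry

    return build_geometry(median_patient, "low")


@pytest.fixture(scope="session")
def reference_sim(median_patient):
    """One full healing simulation of the median patient (low fidelity)."""
    return simulate_patient(median_patient, "low")


@pytest.fixture(scope="session")
def reference_outcome(reference_sim):
    return outcome_from_simulation(reference_sim)


@pytest.fixture(scope="session")
def cohort_low_outcomes():
    """24-patient LHS design of low-fidelity healing simulations (the
    cohort-trajectory and surrogate-training evidence base)."""
    pats = sample_characteristics(CohortDesign(n_samples=24, seed=202, fidelity="low"))
    outs, failed = simulate_cohort(pats, "low", default_params(), SolverConfig())
    assert len(outs) >= 10, f"too many failed low-fidelity patients: {failed}"
    return outs


@pytest.fixture(scope="session")
def cohort_high_outcomes():
    """12-patient high-fidelity design (surrogate validation evidence base)."""
    pats = sample_characteristics(CohortDesign(n_samples=12, seed=303, fidelity="high"))
    outs, failed = simulate_cohort(pats, "high", default_params(), SolverConfig())
    assert len(outs) >= 5, f"too many failed high-fidelity patients: {failed}"
    return outs


def random_elastic_states(n, rng, compressive=False):
    """Random moderate elastic deformation gradients with positive det."""
    F = np.eye(3) + 0.15 * rng.standard_normal((n, 3, 3))
    det = np.linalg.det(F)
    F[det <= 0.1] = np.eye(3)
    if compressive:
        F *= rng.uniform(0.85, 1.0, size=(n, 1, 1))
    return F
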