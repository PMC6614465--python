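from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import settings

from dxtraj.cohort_selection import build_cohort
from dxtraj.registry_model import DiagnosisCode, PatientTrajectory, VisitRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

ORIGIN = date(1990, 1, 1)


def visit(pid: str, day: int, *codes: str) -> VisitRecord:
    """Visit `day` days after the fixture origin, with zero or more codes."""
    return VisitRecord(
        patient_id=pid,
        visit_date=ORIGIN + timedelta(days=day),
        codes=tuple(DiagnosisCode(c) for c in codes),
    )


def traj(pid: str, spec: list) -> PatientTrajectory:
    """Build a trajectory from [(day, code, ...), ...] tuples."""
    return PatientTrajectory(
        patient_id=pid, visits=[visit(pid, item[0], *item[1:]) for item in spec]
    )


@pytest.fixture
def small_cohort():
    """Four eligible patients with distinct first-visit diagnoses and some
    pre-onset history."""
    trajectories = [
        traj("a", [(0, "F20"), (30, "F20"), (60, "F20")]),
        traj("b", [(0, "F20", "F31"), (20, "F22"), (100, "F22")]),
        traj("c", [(0, "F3"), (40, "F3"), (80, "F20"), (120, "F20")]),
        traj("d", [(0, "F41"), (10, "F3", "F6"), (50,), (90, "F20")]),
    ]
    return build_cohort(trajectories)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
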