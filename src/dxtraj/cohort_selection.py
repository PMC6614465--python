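"""Cohort selection: inclusion criteria and onset of the schizophrenia diagnosis.

A patient enters the cohort when (a) at least one visit carries an ICD-10
category-F20 code in either diagnosis slot, and (b) at least three distinct
visits carry at least one recorded diagnosis. The onset visit is the earliest
visit with an F20 code; visits strictly before it form the pre-onset segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .registry_model import PatientTrajectory, VisitRecord, is_schizophrenia

__all__ = ["Cohort", "eligible", "onset_index", "split_pre_post", "build_cohort"]


def _has_f20(visit: VisitRecord) -> bool:
    return any(is_schizophrenia(c) for c in visit.codes)


def eligible(trajectory: PatientTrajectory) -> bool:
    """Inclusion test: an F20 visit and >=3 visits with a recorded diagnosis.

    Undiagnosed visits (no code) do not count toward the three; the F20 code
    may sit in either diagnosis slot.
    """
    n_diagnosed = sum(1 for v in trajectory.visits if v.has_diagnosis)
    if n_diagnosed < 3:
        return False
    return any(_has_f20(v) for v in trajectory.visits)


def onset_index(trajectory: PatientTrajectory) -> int:
    """Index of the earliest visit carrying an F20-category code.

    Visits are date-sorted with stable input order, so two F20 visits on the
    same day resolve to the one that appeared first in the input.
    """
    for i, v in enumerate(trajectory.visits):
        if _has_f20(v):
            return i
    raise ValueError(f"patient {trajectory.patient_id!r} has no F20 visit")


def split_pre_post(
    trajectory: PatientTrajectory, onset: int
) -> tuple[list[VisitRecord], list[VisitRecord]]:
    """Split into (visits strictly before onset, onset visit onward)."""
    return list(trajectory.visits[:onset]), list(trajectory.visits[onset:])


@dataclass
class Cohort:
    """Eligible trajectories with their onset indices (parallel lists)."""

    trajectories: list[PatientTrajectory]
    onset_indices: list[int]

    def __post_init__(self) -> None:
        if len(self.trajectories) != len(self.onset_indices):
            raise ValueError("trajectories and onset_indices differ in length")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(zip(self.trajectories, self.onset_indices))

    @property
    def n_visits(self) -> int:
        return sum(len(t) for t in self.trajectories)

    @property
    def n_pre_visits(self) -> int:
        """Total visits strictly before onset, summed over patients."""
        return sum(self.onset_indices)

    def summary(self) -> dict:
        return {
            "n_patients": len(self),
            "n_visits": self.n_visits,
            "n_pre_visits": self.n_pre_visits,
        }


def build_cohort(trajectories: Iterable[PatientTrajectory]) -> Cohort:
    """Filter to eligible patients and locate each onset visit."""
    kept: list[PatientTrajectory] = []
    onsets: list[int] = []
    for traj in trajectories:
        if eligible(traj):
            kept.append(traj)
            onsets.append(onset_index(traj))
    return Cohort(trajectories=kept, onset_indices=onsets)
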