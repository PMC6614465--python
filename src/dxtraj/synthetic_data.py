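"""Synthetic outpatient registry drawn from a known CT-HMM.

Each simulated patient carries a hidden diagnostic state evolving as a
continuous-time Markov jump process. Visits happen at two kinds of moments:

* jump visits — the jump clock of the current state fires (rate q_i); the
  state moves to j with probability q_ij / q_i and a claim is recorded at
  that instant, realising the assumption that state changes coincide with
  claims;
* repeat visits — an independent clock (rate ``repeat_visit_rate`` per
  year) fires and a claim is recorded with the state unchanged. Without
  these, consecutive same-state observations would never occur and the
  emission matrix would be unidentifiable.

At every visit the recorded diagnosis is missing with probability
``missing_prob``; otherwise the primary code is drawn from the emission row
of the current state, and with probability ``comorbid_prob`` a second code
is drawn from the same row. Visit dates are the fixed origin (1990-01-01)
plus the event time rounded to whole days, so same-day duplicate visits do
occur, as in a real registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_selection import build_cohort
from .cthmm import CTHMMParams, StateSpace, fit_em, sequences_from_cohort
from .registry_model import DiagnosisCode, PatientTrajectory, VisitRecord, write_visits

__all__ = [
    "ORIGIN_DATE",
    "GeneratorConfig",
    "Manifest",
    "sample_trajectory",
    "generate_trajectories",
    "generate_cohort",
    "recovery_experiment",
]

ORIGIN_DATE = date(1990, 1, 1)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters and sampling knobs for one synthetic cohort.

    Defaults mirror the parameter-recovery study conditions: a three-state
    progression (an acute psychotic diagnosis resolving into a persistent
    delusional diagnosis and then schizophrenia), ten years of follow-up,
    one extra same-state visit per year, and 10% missing diagnoses.
    """

    truth: CTHMMParams
    n_patients: int = 2000
    horizon: float = 10.0  # years of follow-up per patient
    repeat_visit_rate: float = 1.0  # extra same-state visits per year
    missing_prob: float = 0.1
    comorbid_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_prob <= 1.0 and 0.0 <= self.comorbid_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.repeat_visit_rate < 0 or self.n_patients < 1 or self.horizon <= 0:
            raise ValueError("invalid sampling configuration")
        if self.repeat_visit_rate == 0 and np.all(self.truth.exit_rates == 0):
            raise ValueError(
                "all exit rates and the repeat-visit rate are zero: "
                "no visit after the first would ever occur"
            )

    @staticmethod
    def default_truth() -> CTHMMParams:
        space = StateSpace(("F23", "F22", "F20"))
        Q = np.zeros((3, 3))
        Q[0, 1] = 0.4  # acute psychosis -> persistent delusional, per year
        Q[1, 2] = 0.6  # persistent delusional -> schizophrenia, per year
        B = np.full((3, 3), 0.075)
        np.fill_diagonal(B, 0.85)
        return CTHMMParams(space, pi=np.array([0.5, 0.3, 0.2]), Q=Q, B=B)

    @classmethod
    def default(cls, **overrides) -> "GeneratorConfig":
        return cls(truth=cls.default_truth(), **overrides)


@dataclass
class Manifest:
    """Truth parameters, config echo and per-patient hidden paths; JSON round-trippable."""

    truth: CTHMMParams
    config: dict
    paths: list[dict]  # per patient: {"patient_id", "times", "states"}

    def to_json(self) -> str:
        return json.dumps(
            {"truth": self.truth.to_dict(), "config": self.config, "paths": self.paths},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        d = json.loads(text)
        return cls(truth=CTHMMParams.from_dict(d["truth"]), config=d["config"], paths=d["paths"])


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # counter-derived substream: patient k's draws do not depend on n_patients
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(patient_index,)))


def sample_trajectory(
    cfg: GeneratorConfig, patient_index: int, rng: np.random.Generator | None = None
) -> tuple[list[VisitRecord], dict]:
    """Simulate one patient: visit records plus the hidden path.

    Competing exponential clocks drive the visit process (see module
    docstring); the returned path dict records the jump times and states.
    """
    rng = rng if rng is not None else _patient_rng(cfg.seed, patient_index)
    truth = cfg.truth
    labels = truth.state_space.labels
    n = truth.state_space.n
    exit_rates = truth.exit_rates

    pid = f"P{patient_index:06d}"
    state = int(rng.choice(n, p=truth.pi))
    t = 0.0
    path_times, path_states = [0.0], [labels[state]]
    event_times: list[float] = [0.0]
    event_states: list[int] = [state]

    while True:
        total = exit_rates[state] + cfg.repeat_visit_rate
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t > cfg.horizon:
            break
        if rng.uniform() < exit_rates[state] / total:
            state = int(rng.choice(n, p=truth.Q[state] / exit_rates[state]))
            path_times.append(t)
            path_states.append(labels[state])
        event_times.append(t)
        event_states.append(state)

    visits: list[VisitRecord] = []
    for tt, ss in zip(event_times, event_states):
        codes: tuple[DiagnosisCode, ...] = ()
        if rng.uniform() >= cfg.missing_prob:
            primary = labels[int(rng.choice(n, p=truth.B[ss]))]
            codes = (DiagnosisCode(primary),)
            if rng.uniform() < cfg.comorbid_prob:
                codes = codes + (DiagnosisCode(labels[int(rng.choice(n, p=truth.B[ss]))]),)
        visit_date = ORIGIN_DATE + timedelta(days=round(tt * 365.25))
        visits.append(VisitRecord(patient_id=pid, visit_date=visit_date, codes=codes))

    path = {"patient_id": pid, "times": path_times, "states": path_states}
    return visits, path


def generate_trajectories(cfg: GeneratorConfig) -> tuple[list[PatientTrajectory], Manifest]:
    """Simulate the whole cohort in memory."""
    trajectories: list[PatientTrajectory] = []
    paths: list[dict] = []
    for k in range(cfg.n_patients):
        visits, path = sample_trajectory(cfg, k)
        trajectories.append(PatientTrajectory(patient_id=path["patient_id"], visits=visits))
        paths.append(path)
    config_echo = {
        "n_patients": cfg.n_patients,
        "horizon": cfg.horizon,
        "repeat_visit_rate": cfg.repeat_visit_rate,
        "missing_prob": cfg.missing_prob,
        "comorbid_prob": cfg.comorbid_prob,
        "seed": cfg.seed,
        "origin_date": ORIGIN_DATE.isoformat(),
    }
    return trajectories, Manifest(truth=cfg.truth, config=config_echo, paths=paths)


def generate_cohort(cfg: GeneratorConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write visits.csv (registry schema) and manifest.json; returns both paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trajectories, manifest = generate_trajectories(cfg)
    visits_path = out / "visits.csv"
    manifest_path = out / "manifest.json"
    write_visits(trajectories, visits_path)
    manifest_path.write_text(manifest.to_json(), encoding="utf-8")
    return visits_path, manifest_path


def recovery_experiment(
    truth: CTHMMParams | None = None,
    n: int = 2000,
    seed: int = 0,
    horizon: float = 10.0,
    repeat_visit_rate: float = 1.0,
    missing_prob: float = 0.1,
    n_restarts: int = 2,
    max_iter: int = 500,
) -> dict:
    """Generate a cohort from known truth, refit by EM, and report errors.

    Returns relative errors of every true-nonzero intensity, absolute errors
    of the emission diagonal, and the fit metadata. States are anchored to
    their labels by the diagonal-dominant initialisation, so no permutation
    alignment is needed.
    """
    truth = truth if truth is not None else GeneratorConfig.default_truth()
    if np.any(np.diag(truth.B) < 0.6):
        raise ValueError("recovery needs an identifiable truth: emission diagonal >= 0.6")
    cfg = GeneratorConfig(
        truth=truth,
        n_patients=n,
        horizon=horizon,
        repeat_visit_rate=repeat_visit_rate,
        missing_prob=missing_prob,
        seed=seed,
    )
    trajectories, _manifest = generate_trajectories(cfg)
    space = truth.state_space
    sequences = sequences_from_cohort(
        [(t, 0) for t in trajectories], space, other_label=None
    )
    fit = fit_em(sequences, space, seed=seed, n_restarts=n_restarts, max_iter=max_iter)

    nz = truth.Q > 0
    rel_q = np.abs(fit.params.Q[nz] - truth.Q[nz]) / truth.Q[nz]
    abs_b = np.abs(np.diag(fit.params.B) - np.diag(truth.B))
    return {
        "n_patients": n,
        "seed": seed,
        "mean_rel_q_error": float(rel_q.mean()),
        "max_rel_q_error": float(rel_q.max()),
        "rel_q_errors": rel_q.tolist(),
        "max_abs_b_diag_error": float(abs_b.max()),
        "abs_b_diag_errors": abs_b.tolist(),
        "fitted": fit.params.to_dict(),
        "truth": truth.to_dict(),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "final_loglik": fit.loglik_trace[-1],
    }
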