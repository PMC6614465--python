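"""Continuous-time hidden Markov model of transitions between diagnoses.

The hidden state is the patient's underlying disorder, evolving as a
continuous-time Markov jump process with intensity matrix entries
``q_ij`` (events per year, i != j) and exit rates ``q_i = sum_j q_ij``.
At each visit the clinician records a diagnosis drawn from the emission
matrix ``b_i(k)`` — the probability of recording label k when the true
state is i — or records nothing, which enters the likelihood as an
uninformative (uncertain) observation.

Two interval semantics are supported for the likelihood of the gap between
consecutive visits:

* ``exact_times`` (default): the state is assumed to change only at visit
  times, so an interval of length dt contributes the sojourn survival
  ``exp(-q_i * dt)`` and, when the state changes, the jump selection
  ``q_ij``. This admits closed-form EM updates.
* ``panel``: the state may jump (multiple times) anywhere inside the
  interval; the interval contributes the transition probability
  ``expm(G * dt)`` of the generator ``G`` (off-diagonals q_ij, diagonal
  -q_i). Provided for likelihood evaluation and cross-checks only; EM under
  panel semantics is not implemented.

Parameters are estimated by EM: the E-step runs a scaled forward-backward
pass over every visit sequence and accumulates expected jump counts,
expected sojourn times, emission counts, and initial-state counts; the
M-step is the closed-form maximum-likelihood update
``q_ij = n_ij / T_i``, ``b_i(k) = m_ik / sum_k m_ik``, ``pi_i = g_i / n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.linalg import expm

from .registry_model import CodeTaxonomy, PatientTrajectory

__all__ = [
    "MISSING",
    "StateSpace",
    "CTHMMParams",
    "ObsSequence",
    "SufficientStats",
    "FitResult",
    "interval_kernel_exact",
    "interval_kernel_panel",
    "emission",
    "loglik",
    "posteriors",
    "estep",
    "mstep",
    "fit_em",
    "random_init",
    "extract_graph",
    "graph_to_dot",
    "sequences_from_cohort",
    "observed_label_counts",
]

#: Sentinel for a visit whose diagnosis was not recorded.
MISSING = None

#: Smallest allowed inter-visit gap in years (half a day); two same-day
#: visits are pushed apart by this amount so sojourn densities stay defined.
MIN_GAP_YEARS = 0.5 / 365.25


@dataclass(frozen=True)
class StateSpace:
    """Ordered hidden-state labels; the observation alphabet is the same set
    of labels plus MISSING."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("state space needs at least 2 states")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in state space {self.labels}") from None


@dataclass
class CTHMMParams:
    """CT-HMM parameters: initial distribution pi, off-diagonal intensities
    Q (diagonal ignored and stored as zero), and emission matrix B."""

    state_space: StateSpace
    pi: np.ndarray  # (n,)
    Q: np.ndarray  # (n, n), off-diagonal rates per year, zero diagonal
    B: np.ndarray  # (n, n), b_i(k) over the label alphabet

    def __post_init__(self) -> None:
        n = self.state_space.n
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float).copy()
        self.B = np.asarray(self.B, dtype=float)
        if self.pi.shape != (n,) or self.Q.shape != (n, n) or self.B.shape != (n, n):
            raise ValueError("parameter shapes inconsistent with state space")
        np.fill_diagonal(self.Q, 0.0)
        if (self.Q < 0).any():
            raise ValueError("intensities q_ij must be non-negative")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.B.sum(axis=1), 1.0):
            raise ValueError("emission rows must sum to 1")

    @property
    def exit_rates(self) -> np.ndarray:
        """q_i = sum_{j != i} q_ij."""
        return self.Q.sum(axis=1)

    def generator(self) -> np.ndarray:
        """G with off-diagonals q_ij and diagonal -q_i; rows sum to zero."""
        G = self.Q.copy()
        np.fill_diagonal(G, -self.exit_rates)
        return G

    def to_dict(self) -> dict:
        return {
            "labels": list(self.state_space.labels),
            "pi": self.pi.tolist(),
            "Q": self.Q.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CTHMMParams":
        space = StateSpace(tuple(d["labels"]))
        return cls(space, np.array(d["pi"]), np.array(d["Q"]), np.array(d["B"]))


@dataclass
class ObsSequence:
    """One patient's visit sequence: times in years from the first visit and
    the observed label (or MISSING) at each time."""

    times: np.ndarray
    observations: tuple[str | None, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.observations):
            raise ValueError("times and observations must be 1-d and equal length")
        if len(self.times) == 0:
            raise ValueError("empty sequence")
        if self.times[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class SufficientStats:
    """Expected complete-data statistics accumulated by the E-step."""

    n_ij: np.ndarray  # expected jump counts, zero diagonal
    T_i: np.ndarray  # expected sojourn years per state
    m_ik: np.ndarray  # expected emission counts (non-missing visits only)
    g_i: np.ndarray  # expected initial-state counts
    loglik: float  # total log-likelihood of the E-step parameters
    n_sequences: int

    @property
    def total_time(self) -> float:
        return float(self.T_i.sum())


@dataclass
class FitResult:
    params: CTHMMParams
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    seed: int


# --- interval kernels and emissions ----------------------------------------


def interval_kernel_exact(params: CTHMMParams, dt: float) -> np.ndarray:
    """Exact-times likelihood factors for a gap of dt years.

    Entry (i, j): ``q_ij * exp(-q_i dt)`` for j != i (sojourn density at dt
    times jump selection), ``exp(-q_i dt)`` on the diagonal (no jump at this
    visit). Rows are likelihood factors, not a probability distribution.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    surv = np.exp(-params.exit_rates * dt)
    K = params.Q * surv[:, None]
    np.fill_diagonal(K, surv)
    return K


def interval_kernel_panel(params: CTHMMParams, dt: float) -> np.ndarray:
    """Transition probability matrix expm(G*dt); rows sum to 1. dt=0 gives I."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    if dt == 0:
        return np.eye(params.state_space.n)
    return expm(params.generator() * dt)


def emission(params: CTHMMParams, i: int | str, obs: str | None) -> float:
    """Likelihood factor b_i(obs); MISSING observations are uninformative (1)."""
    state = params.state_space.index(i) if isinstance(i, str) else i
    if obs is MISSING:
        return 1.0
    return float(params.B[state, params.state_space.index(obs)])


def _emission_row(params: CTHMMParams, obs: str | None) -> np.ndarray:
    if obs is MISSING:
        return np.ones(params.state_space.n)
    return params.B[:, params.state_space.index(obs)].copy()


# --- batched forward-backward ----------------------------------------------
# Sequences are padded to a common length; padded steps use an identity
# kernel and unit emissions so they leave the recursion untouched.


def _pack(params: CTHMMParams, sequences: Sequence[ObsSequence]):
    space = params.state_space
    S = len(sequences)
    T = max(len(s) for s in sequences)
    obs_idx = np.full((S, T), -1, dtype=int)  # -1 = MISSING or padding
    dts = np.ones((S, T))
    valid = np.zeros((S, T), dtype=bool)
    for s, seq in enumerate(sequences):
        L = len(seq)
        valid[s, :L] = True
        if L > 1:
            dts[s, 1:L] = np.diff(seq.times)
        for t, o in enumerate(seq.observations):
            if o is not MISSING:
                obs_idx[s, t] = space.index(o)
    return obs_idx, dts, valid


def _emissions_packed(params: CTHMMParams, obs_idx: np.ndarray) -> np.ndarray:
    """E[s, t, i] = b_i(o_st), 1 where missing/padded."""
    B_ext = np.concatenate([params.B.T, np.ones((1, params.state_space.n))], axis=0)
    return B_ext[obs_idx]  # fancy-index: row -1 is the all-ones row


def _kernels_packed(params: CTHMMParams, dts: np.ndarray, valid: np.ndarray, kernel: str) -> np.ndarray:
    """K[s, t] = interval kernel for the gap ending at visit t (t >= 1);
    identity on padded steps."""
    S, T = dts.shape
    n = params.state_space.n
    if kernel == "exact_times":
        A = params.Q + np.eye(n)
        surv = np.exp(-np.multiply.outer(dts, params.exit_rates))  # (S, T, n)
        K = surv[..., None] * A[None, None]
    elif kernel == "panel":
        K = np.empty((S, T, n, n))
        for s in range(S):
            for t in range(T):
                K[s, t] = expm(params.generator() * dts[s, t])
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    K[~valid] = np.eye(n)
    K[:, 0] = np.eye(n)  # no gap before the first visit
    return K


def _forward_backward(params: CTHMMParams, sequences: Sequence[ObsSequence], kernel: str):
    """Scaled forward-backward over all sequences at once.

    Returns per-sequence loglik, smoothed marginals gamma (S,T,n), pair
    marginals xi (S,T,n,n) for the interval ending at each visit t>=1, and
    the validity mask. Zero-probability sequences get loglik -inf and NaN
    posteriors.
    """
    obs_idx, dts, valid = _pack(params, sequences)
    S, T = obs_idx.shape
    n = params.state_space.n
    E = _emissions_packed(params, obs_idx)
    K = _kernels_packed(params, dts, valid, kernel)

    alpha = np.empty((S, T, n))
    c = np.ones((S, T))
    a = params.pi[None, :] * E[:, 0]
    c[:, 0] = a.sum(axis=1)
    dead = c[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha[:, 0] = np.where(dead[:, None], np.nan, a / np.where(dead, 1.0, c[:, 0])[:, None])
    for t in range(1, T):
        a = np.einsum("si,sij->sj", alpha[:, t - 1], K[:, t]) * E[:, t]
        ct = a.sum(axis=1)
        newly_dead = (ct == 0) & valid[:, t] & ~dead
        dead = dead | newly_dead
        safe = np.where(ct == 0, 1.0, ct)
        alpha[:, t] = a / safe[:, None]
        c[:, t] = np.where(valid[:, t], safe, 1.0)
        c[newly_dead, t] = 0.0

    with np.errstate(divide="ignore"):
        loglik = np.where(dead, -np.inf, np.log(np.where(c > 0, c, 1.0)).sum(axis=1))

    beta = np.empty((S, T, n))
    beta[:, T - 1] = 1.0
    csafe = np.where(c > 0, c, 1.0)
    for t in range(T - 2, -1, -1):
        b = np.einsum("sij,sj->si", K[:, t + 1], E[:, t + 1] * beta[:, t + 1])
        beta[:, t] = b / csafe[:, t + 1][:, None]

    gamma = alpha * beta
    # xi_t(i,j) for the interval (t-1, t]
    xi = np.zeros((S, T, n, n))
    xi[:, 1:] = (
        alpha[:, :-1, :, None]
        * K[:, 1:]
        * (E[:, 1:] * beta[:, 1:])[:, :, None, :]
        / csafe[:, 1:, None, None]
    )
    gamma[dead] = np.nan
    xi[dead] = np.nan
    return loglik, gamma, xi, valid, dts, obs_idx, dead


# --- public likelihood / posterior API --------------------------------------


def loglik(params: CTHMMParams, seq: ObsSequence, kernel: str = "exact_times") -> float:
    """Log-likelihood of one visit sequence (scaled forward recursion).

    Returns -inf with a warning when the sequence has probability zero under
    the parameters.
    """
    ll = _forward_backward(params, [seq], kernel)[0][0]
    if ll == -np.inf:
        warnings.warn("sequence has zero probability under the parameters")
    return float(ll)


def posteriors(
    params: CTHMMParams, seq: ObsSequence, kernel: str = "exact_times"
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed per-visit state marginals gamma (T, n) and per-interval pair
    marginals xi (T-1, n, n), xi[v] covering the gap between visits v and v+1."""
    ll, gamma, xi, valid, _, _, dead = _forward_backward(params, [seq], kernel)
    if dead[0]:
        raise ValueError("zero-probability sequence: posteriors undefined")
    L = int(valid[0].sum())
    return gamma[0, :L], xi[0, 1:L]


# --- EM ---------------------------------------------------------------------


def estep(
    params: CTHMMParams,
    sequences: Sequence[ObsSequence],
    kernel: str = "exact_times",
) -> SufficientStats:
    """Expected sufficient statistics under the current parameters.

    Exact-times semantics: expected jumps n_ij sum the pair marginals over
    intervals; expected sojourn in i attributes each interval's full length
    to its start state (T_i = sum_v dt_v * gamma_{v-1}(i)); emission counts
    sum gamma over non-missing visits. Zero-probability sequences are
    excluded with a warning.
    """
    if kernel != "exact_times":
        raise NotImplementedError(
            "EM expectations are defined only under exact_times semantics; "
            "the panel kernel is for likelihood evaluation only"
        )
    ll, gamma, xi, valid, dts, obs_idx, dead = _forward_backward(params, sequences, kernel)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-probability sequence(s) excluded from E-step")
    alive = ~dead
    if not alive.any():
        raise ValueError(
            "all sequences have zero probability under the parameters; "
            "consider smoothing the emission matrix"
        )
    n = params.state_space.n
    w = (valid & alive[:, None]).astype(float)  # (S,T)

    xi_w = xi * w[:, :, None, None]
    xi_w = np.nan_to_num(xi_w, nan=0.0)
    n_ij = xi_w.sum(axis=(0, 1))
    np.fill_diagonal(n_ij, 0.0)

    # sum_j xi_t(i, j) = gamma_{t-1}(i); the sojourn of the interval ending at
    # visit t is attributed to its start state. xi at t=0 is all zero, so the
    # first visit contributes no interval.
    occ = xi_w.sum(axis=3)  # (S,T,n)
    T_i = np.einsum("st,sti->i", dts * w, occ)

    gamma_w = np.nan_to_num(gamma, nan=0.0) * w[:, :, None]
    m_ik = np.zeros((n, n))
    observed = obs_idx >= 0
    for k in range(n):
        sel = observed & (obs_idx == k)
        m_ik[:, k] = gamma_w[sel].sum(axis=0)

    g_i = gamma_w[:, 0, :].sum(axis=0)
    total_ll = float(ll[alive].sum())
    return SufficientStats(
        n_ij=n_ij, T_i=T_i, m_ik=m_ik, g_i=g_i, loglik=total_ll, n_sequences=int(alive.sum())
    )


def mstep(
    stats: SufficientStats,
    state_space: StateSpace,
    prev: CTHMMParams | None = None,
    emission_floor: float = 1e-8,
) -> CTHMMParams:
    """Closed-form maximum-likelihood update from the expected statistics.

    q_ij = n_ij / T_i (zero when T_i = 0); b_i(k) = m_ik / sum_k m_ik with a
    small additive floor guarding against absorbing zeros (a row with zero
    expected emissions keeps its previous values); pi = g_i / sum g_i.
    """
    n = state_space.n
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = np.where(stats.T_i[:, None] > 0, stats.n_ij / np.where(stats.T_i, stats.T_i, 1.0)[:, None], 0.0)
    np.fill_diagonal(Q, 0.0)

    B = np.full((n, n), 1.0 / n) if prev is None else prev.B.copy()
    row_tot = stats.m_ik.sum(axis=1)
    seen = row_tot > 0
    m = stats.m_ik[seen] + emission_floor
    B[seen] = m / m.sum(axis=1, keepdims=True)

    g = stats.g_i
    pi = g / g.sum() if g.sum() > 0 else np.full(n, 1.0 / n)
    return CTHMMParams(state_space, pi=pi, Q=Q, B=B)


def random_init(
    state_space: StateSpace,
    rng: np.random.Generator,
    b_diag: float = 0.8,
    q_base: float = 0.1,
    q_jitter: float = 0.05,
) -> CTHMMParams:
    """Diagonal-dominant starting point anchoring state i to diagnosis label i.

    B gets ``b_diag`` on the diagonal and spreads the rest uniformly; each
    off-diagonal intensity is ``q_base + Uniform(0, q_jitter)``; pi uniform.
    """
    n = state_space.n
    B = np.full((n, n), (1.0 - b_diag) / (n - 1))
    np.fill_diagonal(B, b_diag)
    Q = q_base + rng.uniform(0.0, q_jitter, size=(n, n))
    np.fill_diagonal(Q, 0.0)
    pi = np.full(n, 1.0 / n)
    return CTHMMParams(state_space, pi=pi, Q=Q, B=B)


def fit_em(
    sequences: Sequence[ObsSequence],
    state_space: StateSpace,
    init: CTHMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 3,
    emission_floor: float = 1e-8,
) -> FitResult:
    """Fit by EM with seeded random restarts; the best final loglik wins.

    ``tol`` is the relative per-iteration log-likelihood improvement below
    which the run is declared converged. Passing an explicit ``init``
    disables restarts (the run is then fully determined by the start point).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    restarts = 1 if init is not None else max(1, n_restarts)
    best: FitResult | None = None
    for _ in range(restarts):
        params = init if init is not None else random_init(state_space, rng)
        trace: list[float] = []
        converged = False
        for _it in range(max_iter):
            stats = estep(params, sequences)
            trace.append(stats.loglik)
            params = mstep(stats, state_space, prev=params, emission_floor=emission_floor)
            if len(trace) >= 2:
                prev_ll, ll = trace[-2], trace[-1]
                if abs(ll - prev_ll) <= tol * abs(prev_ll):
                    converged = True
                    break
        result = FitResult(
            params=params, loglik_trace=trace, converged=converged, n_iter=len(trace), seed=seed
        )
        if best is None or result.loglik_trace[-1] > best.loglik_trace[-1]:
            best = result
    assert best is not None
    return best


# --- transition-graph extraction -------------------------------------------


def extract_graph(
    params: CTHMMParams,
    state_frequencies: Mapping[str, int],
    target: str = "F20",
    q_threshold: float = 0.05,
) -> nx.DiGraph:
    """Directed graph of diagnoses converging into the target diagnosis.

    Nodes are states observed in the sample (frequency > 0; the target is
    always kept), weighted by frequency. Edges keep intensities
    q_ij >= q_threshold (per year) and carry both the rate and the embedded
    jump probability q_ij / q_i. Only nodes with a directed path to the
    target survive.
    """
    space = params.state_space
    if target not in space.labels:
        raise KeyError(f"target {target!r} not in state space")
    exit_rates = params.exit_rates
    G = nx.DiGraph(q_threshold=q_threshold, target=target)
    for lab in space.labels:
        freq = int(state_frequencies.get(lab, 0))
        if freq > 0 or lab == target:
            G.add_node(lab, frequency=freq)
    for i, src in enumerate(space.labels):
        for j, dst in enumerate(space.labels):
            if i == j or src not in G or dst not in G:
                continue
            q = float(params.Q[i, j])
            if q >= q_threshold:
                embedded = q / exit_rates[i] if exit_rates[i] > 0 else 0.0
                G.add_edge(src, dst, rate=q, embedded_prob=float(embedded))
    keep = nx.ancestors(G, target) | {target}
    return G.subgraph(keep).copy()


def graph_to_dot(G: nx.DiGraph) -> str:
    """Plain DOT rendering: node weight = sample frequency, edge label = rate."""
    lines = ["digraph diagnoses {"]
    for node, data in sorted(G.nodes(data=True)):
        lines.append(f'  "{node}" [frequency={data.get("frequency", 0)}];')
    for u, v, data in sorted(G.edges(data=True)):
        lines.append(f'  "{u}" -> "{v}" [label="{data["rate"]:.4f}", rate={data["rate"]:.6f}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


# --- bridging from registry trajectories ------------------------------------


def sequences_from_cohort(
    trajectories_with_onset: Iterable[tuple[PatientTrajectory, int]],
    state_space: StateSpace,
    taxonomy: CodeTaxonomy | None = None,
    other_label: str | None = None,
    from_onset: bool = False,
) -> list[ObsSequence]:
    """Convert trajectories to observation sequences for the CT-HMM.

    Each visit yields one observation: the rendered label of its first
    diagnosis code, or MISSING when no diagnosis was recorded. Labels outside
    the state space map to ``other_label`` when given, else raise. Times are
    years from the first included visit; same-day visits are separated by
    half a day. ``from_onset`` starts the sequence at the onset visit.
    """
    taxonomy = taxonomy or CodeTaxonomy()
    out: list[ObsSequence] = []
    for traj, onset in trajectories_with_onset:
        visits = traj.visits[onset:] if from_onset else traj.visits
        t0 = visits[0].visit_date
        times: list[float] = []
        obs: list[str | None] = []
        for v in visits:
            t = (v.visit_date - t0).days / 365.25
            if times and t <= times[-1]:
                t = times[-1] + MIN_GAP_YEARS
            times.append(t)
            if not v.has_diagnosis:
                obs.append(MISSING)
                continue
            code = v.codes[0]
            label = (
                sorted(taxonomy.chapters(code))[0] if code.is_combination else taxonomy.render(code)
            )
            if label not in state_space.labels:
                if other_label is None:
                    raise KeyError(
                        f"label {label!r} outside state space and no other_label given"
                    )
                label = other_label
            obs.append(label)
        out.append(ObsSequence(times=np.array(times), observations=tuple(obs)))
    return out


def observed_label_counts(sequences: Sequence[ObsSequence], state_space: StateSpace) -> dict[str, int]:
    """Observed (non-missing) diagnosis counts per label, for graph node sizes."""
    counts = {lab: 0 for lab in state_space.labels}
    for seq in sequences:
        for o in seq.observations:
            if o is not MISSING:
                counts[o] += 1
    return counts
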