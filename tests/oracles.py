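"""Independent oracles used by the test suite.

Everything here recomputes CT-HMM quantities by exhaustive enumeration over
hidden state paths, deliberately sharing no code with the recursion-based
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _interval_factor(params, i, j, dt, kernel):
    if kernel == "exact_times":
        qi = params.exit_rates[i]
        if i == j:
            return math.exp(-qi * dt)
        return params.Q[i, j] * math.exp(-qi * dt)
    from scipy.linalg import expm

    return expm(params.generator() * dt)[i, j]


def _emission_factor(params, i, obs):
    if obs is None:
        return 1.0
    return params.B[i, params.state_space.index(obs)]


def enumerate_posteriors(params, seq, kernel="exact_times"):
    """(loglik, gamma, xi, stats) by brute-force summation over all paths.

    stats is a dict with n_ij, T_i, m_ik, g_i matching the E-step contract.
    """
    n = params.state_space.n
    T = len(seq)
    dts = np.diff(seq.times)
    Z = 0.0
    gamma = np.zeros((T, n))
    xi = np.zeros((max(T - 1, 0), n, n))
    n_ij = np.zeros((n, n))
    T_i = np.zeros(n)
    m_ik = np.zeros((n, n))
    g_i = np.zeros(n)
    for path in itertools.product(range(n), repeat=T):
        w = params.pi[path[0]] * _emission_factor(params, path[0], seq.observations[0])
        for v in range(1, T):
            w *= _interval_factor(params, path[v - 1], path[v], dts[v - 1], kernel)
            w *= _emission_factor(params, path[v], seq.observations[v])
        if w == 0.0:
            continue
        Z += w
        for v in range(T):
            gamma[v, path[v]] += w
            obs = seq.observations[v]
            if obs is not None:
                m_ik[path[v], params.state_space.index(obs)] += w
        for v in range(1, T):
            xi[v - 1, path[v - 1], path[v]] += w
            T_i[path[v - 1]] += dts[v - 1] * w
            if path[v] != path[v - 1]:
                n_ij[path[v - 1], path[v]] += w
        g_i[path[0]] += w
    if Z == 0.0:
        return -np.inf, gamma, xi, None
    stats = {"n_ij": n_ij / Z, "T_i": T_i / Z, "m_ik": m_ik / Z, "g_i": g_i / Z}
    return math.log(Z), gamma / Z, xi / Z, stats


def random_instance(rng, n_states, n_visits, missing_rate=0.3):
    """A random small CT-HMM instance plus an observation sequence."""
    from dxtraj.cthmm import CTHMMParams, ObsSequence, StateSpace

    labels = tuple(f"S{i}" for i in range(n_states))
    space = StateSpace(labels)
    Q = rng.uniform(0.05, 1.5, (n_states, n_states))
    np.fill_diagonal(Q, 0.0)
    B = rng.dirichlet(np.ones(n_states) * 2.0, size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    params = CTHMMParams(space, pi=pi, Q=Q, B=B)
    times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.05, 2.0, n_visits - 1))])
    obs = tuple(
        None if rng.uniform() < missing_rate else labels[rng.integers(n_states)]
        for _ in range(n_visits)
    )
    return params, ObsSequence(times=times, observations=obs)
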