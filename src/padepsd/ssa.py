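"""Exact stochastic simulation (Gillespie SSA) and path functionals.

``simulate`` is the reference implementation: a pure-Python event loop that
supports every propensity and displacement type (including jump kernels and
register resets) and stores the full jump-time/state path.  Long-horizon
ensemble runs that only need path *functionals* (time averages, register
integrals, state occupancies) go through the compiled engine in
:mod:`padepsd.engine` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PadePSDError
from .network import Fixed, JumpKernel, ReactionNetwork, RegisterReset, propensity

__all__ = [
    "Trajectory",
    "EnsembleConfig",
    "simulate",
    "time_average",
    "stationary_mean_variance",
    "trajectory_seeds",
]


@dataclass
class Trajectory:
    """Piecewise-constant right-continuous CTMC path on [0, horizon].

    ``states[i]`` holds on [times[i], times[i+1]); ``reaction_indices[i]`` is
    the reaction that produced state i (-1 for the initial state).
    """

    times: np.ndarray
    states: np.ndarray
    reaction_indices: np.ndarray
    horizon: float
    seed: int | None = None

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise PadePSDError("times/states length mismatch")
        if self.times[0] != 0.0:
            raise PadePSDError("first jump time must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise PadePSDError("jump times must be strictly increasing")

    def state_at(self, t: float) -> np.ndarray:
        """Right-continuous evaluation X(t)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(idx, 0)]

    def component(self, j: int) -> np.ndarray:
        return self.states[:, j]


@dataclass
class EnsembleConfig:
    """Monte-Carlo ensemble settings: Q trajectories on [0, T_f] with the
    initial transient [0, T_c] discarded from all stationary estimators."""

    Q: int = 10
    T_f: float = 1e4
    T_c: float = 1e2
    base_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.T_c < self.T_f):
            raise PadePSDError("need 0 <= T_c < T_f")
        if self.Q < 1:
            raise PadePSDError("need Q >= 1")


def trajectory_seeds(base_seed: int, Q: int) -> np.ndarray:
    """Deterministic per-trajectory seeds via seed-sequence spawning."""
    ss = np.random.SeedSequence(int(base_seed))
    return np.array([int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(Q)], dtype=np.int64)


def simulate(
    network: ReactionNetwork,
    initial_state,
    T_f: float,
    seed: int,
    max_events: int | None = None,
) -> Trajectory:
    """Exact SSA path of ``network`` on [0, T_f].

    If all propensities vanish (and there are no reset reactions firing) the
    state is absorbing and the path simply holds until the horizon.
    """
    rng = np.random.default_rng(int(seed))
    x = np.asarray(initial_state, dtype=np.int64).copy()
    if np.any(x < 0):
        raise PadePSDError("initial state must be non-negative")
    times = [0.0]
    states = [x.copy()]
    fired = [-1]
    t = 0.0
    K = len(network.reactions)
    props = np.empty(K)
    n_events = 0
    while True:
        for k, r in enumerate(network.reactions):
            props[k] = propensity(r, x)
        if np.any(props < 0):
            raise PadePSDError("negative propensity encountered")
        a0 = props.sum()
        if a0 <= 0.0:
            break  # absorbing: hold until horizon
        t = t + rng.exponential(1.0 / a0)
        if t >= T_f:
            break
        k = int(np.searchsorted(np.cumsum(props), rng.random() * a0, side="right"))
        k = min(k, K - 1)
        disp = network.reactions[k].displacement
        if isinstance(disp, Fixed):
            x = x + np.asarray(disp.zeta, dtype=np.int64)
        elif isinstance(disp, RegisterReset):
            x = disp.apply(x)
        elif isinstance(disp, JumpKernel):
            x = x + disp.sample(x, rng)
        if np.any(x < 0):
            raise PadePSDError(f"reaction {k} drove the state negative")
        times.append(t)
        states.append(x.copy())
        fired.append(k)
        n_events += 1
        if max_events is not None and n_events >= max_events:
            break
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states, dtype=np.int64),
        reaction_indices=np.asarray(fired, dtype=np.int64),
        horizon=float(T_f),
        seed=int(seed),
    )


def time_average(trajectory: Trajectory, g, T_c: float, T_f: float) -> float:
    """Exact (T_f - T_c)^{-1} * integral of g(X(t)) over [T_c, T_f].

    The path is piecewise constant, so the integral is a finite sum of
    g(state) * holding-time terms — no discretisation error.
    """
    if not (T_c < T_f <= trajectory.horizon + 1e-9):
        raise PadePSDError("need T_c < T_f <= trajectory horizon")
    times = trajectory.times
    total = 0.0
    n = len(times)
    for i in range(n):
        a = max(times[i], T_c)
        b = min(times[i + 1] if i + 1 < n else trajectory.horizon, T_f)
        if b > a:
            total += float(g(trajectory.states[i])) * (b - a)
    return total / (T_f - T_c)


def stationary_mean_variance(
    trajectories: list[Trajectory], output_index: int, T_c: float, T_f: float
):
    """Pooled time-average mean and variance of the output copy-number.

    The variance subtracts the square of the *pooled* mean (one global
    centering, not per-trajectory).  Standard errors come from the spread of
    the per-trajectory first and (mean-corrected) second moments; a single
    trajectory yields NaN standard errors — use the batched engine for that.
    """
    if T_c >= T_f:
        raise PadePSDError("need T_c < T_f")
    m1 = np.array([time_average(tr, lambda s: s[output_index], T_c, T_f) for tr in trajectories])
    m2 = np.array([time_average(tr, lambda s: s[output_index] ** 2, T_c, T_f) for tr in trajectories])
    mean = float(m1.mean())
    var = float(m2.mean() - mean**2)
    q = len(trajectories)
    if q > 1:
        mean_se = float(m1.std(ddof=1) / np.sqrt(q))
        per_var = m2 - 2 * mean * m1 + mean**2
        var_se = float(per_var.std(ddof=1) / np.sqrt(q))
    else:
        mean_se = var_se = float("nan")
    return mean, var, mean_se, var_se
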