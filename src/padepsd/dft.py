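"""Nonparametric periodogram PSD estimation (the comparison baseline).

A CTMC path is sampled on a uniform grid, mean-subtracted, and the squared
modulus of its discrete Fourier transform is scaled by dt/N so the estimate
targets the continuous-time two-sided PSD.  The per-bin estimator is
inconsistent (its variance does not vanish as the horizon grows), which is
why ensemble averaging over Q trajectories is used everywhere — and why the
parametric resolvent route exists in the first place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import run_ensemble
from .errors import PadePSDError
from .network import ReactionNetwork, propensity
from .ssa import EnsembleConfig, Trajectory

__all__ = [
    "SampledSeries",
    "sample",
    "periodogram",
    "ensemble_psd",
    "ensemble_psd_network",
    "default_sample_dt",
]


@dataclass
class SampledSeries:
    """Uniformly sampled output series X_n(T_c + k dt), k = 0..N-1."""

    dt: float
    values: np.ndarray
    mean_subtracted: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise PadePSDError("dt must be > 0")
        if len(self.values) < 2:
            raise PadePSDError("series needs at least 2 samples")

    def demeaned(self) -> "SampledSeries":
        return SampledSeries(self.dt, self.values - self.values.mean(), mean_subtracted=True)


def default_sample_dt(network: ReactionNetwork, state=None) -> float:
    """Heuristic anti-aliasing step: 0.1 / (total propensity at the reference
    state), i.e. a tenth of the mean holding time."""
    x = np.asarray(state) if state is not None else network.default_initial_state()
    total = sum(propensity(r, x) for r in network.reactions)
    if total <= 0:
        raise PadePSDError("all propensities vanish at the reference state")
    return 0.1 / total


def sample(trajectory: Trajectory, dt: float, T_c: float, T_f: float,
           output_index: int = 0) -> SampledSeries:
    """Right-continuous evaluation of the piecewise-constant path on the
    uniform grid T_c + k dt inside [T_c, T_f)."""
    if not T_c < T_f <= trajectory.horizon + 1e-9:
        raise PadePSDError("empty or out-of-range sampling window")
    if dt >= (T_f - T_c) / 2:
        raise PadePSDError("dt must be smaller than half the window")
    grid = np.arange(T_c, T_f - 1e-12, dt)
    idx = np.searchsorted(trajectory.times, grid, side="right") - 1
    values = trajectory.states[np.maximum(idx, 0), output_index].astype(float)
    return SampledSeries(dt=dt, values=values)


def periodogram(series: SampledSeries):
    """(omega grid, PSD estimates) for a mean-subtracted series.

    Scaling dt/N makes the estimator target the continuous-time two-sided
    PSD; the grid is omega_k = 2 pi k / (N dt) for k = 0..N//2 (rad/time).
    The mean of the *full* DFT periodogram over all N bins equals dt times
    the sample variance (discrete Parseval).
    """
    if not series.mean_subtracted:
        raise PadePSDError("subtract the mean first (series.demeaned())")
    x = series.values
    N = len(x)
    F = np.fft.rfft(x)
    psd = series.dt * np.abs(F) ** 2 / N
    omega = 2.0 * np.pi * np.arange(len(F)) / (N * series.dt)
    return omega, psd


def ensemble_psd(trajectories: list[Trajectory], dt: float, T_c: float, T_f: float,
                 output_index: int = 0):
    """Averaged periodogram over an ensemble: (omega, mean PSD, sd band)."""
    if len(trajectories) < 1:
        raise PadePSDError("need at least one trajectory")
    psds = []
    omega = None
    for tr in trajectories:
        series = sample(tr, dt, T_c, T_f, output_index).demeaned()
        omega, p = periodogram(series)
        psds.append(p)
    psds = np.asarray(psds)
    sd = psds.std(axis=0, ddof=1) if len(psds) > 1 else np.zeros_like(psds[0])
    return omega, psds.mean(axis=0), sd


def ensemble_psd_network(network: ReactionNetwork, config: EnsembleConfig,
                         dt: float | None = None):
    """Averaged periodogram of Q fresh trajectories of ``network``, sampled
    inside the engine (no path storage)."""
    if dt is None:
        dt = default_sample_dt(network)
    else:
        ref_dt = default_sample_dt(network)
        if dt > 50.0 * ref_dt:
            warnings.warn(
                f"sampling step {dt} is much larger than the mean holding time; "
                "the periodogram may alias"
            )
    result = run_ensemble(network, config, sample_dt=dt, n_batches=1)
    psds = []
    omega = None
    for q in range(config.Q):
        series = SampledSeries(dt, result.samples[q]).demeaned()
        omega, p = periodogram(series)
        psds.append(p)
    psds = np.asarray(psds)
    sd = psds.std(axis=0, ddof=1) if len(psds) > 1 else np.zeros_like(psds[0])
    return omega, psds.mean(axis=0), sd
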