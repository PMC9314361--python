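"""Monte-Carlo estimators of the Pade derivatives D_m^(s) and of direct
resolvent values G(s_bar).

Three routes are implemented:

* finite points: D_m^(s) = (-1)^m s^{-(m+1)} [Var - delta_m/2], with
  delta_m the time-averaged squared mismatch between the output and its
  shift register Y_{m+1} (an Erlang-lagged copy of the output);
* s = infinity, naive: time average of f(x) A^m f(x) — unbiased but
  high-variance, kept as a diagnostic;
* s = infinity, covariate: time average of the integrand Psi_m built from
  generator powers and carre-du-champ terms, which has the same stationary
  mean and typically far lower variance.  This is the default.

All estimators pool over Q trajectories split into time batches; standard
errors are batch-mean standard deviations divided by sqrt(#batches), so a
single long trajectory still yields a serviceable error bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augmentation import AugmentationLayout
from .engine import EnsembleResult
from .errors import PadePSDError
from .generator import GeneratorPowers
from .network import ReactionNetwork

__all__ = [
    "DerivativeEstimate",
    "PadeDerivativeSet",
    "ensemble_moments",
    "finite_point_derivatives",
    "infinity_derivatives_naive",
    "infinity_derivatives_covariate",
    "direct_G_estimates",
    "estimate_derivatives",
]


@dataclass
class DerivativeEstimate:
    """Estimated derivatives D_0..D_{rho-1} at one interpolation point."""

    s: float  # may be numpy.inf
    values: np.ndarray
    standard_errors: np.ndarray
    method: str


@dataclass
class PadeDerivativeSet:
    """All interpolation data feeding the Pade linear system."""

    estimates: list[DerivativeEstimate]
    mean: float
    mean_se: float
    variance: float
    variance_se: float
    direct: dict[float, tuple[float, float]] = field(default_factory=dict)

    def by_point(self) -> list[tuple[float, np.ndarray]]:
        return [(e.s, e.values) for e in self.estimates]


def _batch_se(batch_values: np.ndarray) -> float:
    flat = np.asarray(batch_values, dtype=float).ravel()
    if flat.size < 2:
        return float("nan")
    return float(flat.std(ddof=1) / np.sqrt(flat.size))


def _layout(result: EnsembleResult) -> AugmentationLayout:
    layout = result.network.metadata.get("augmentation")
    if layout is None:
        raise PadePSDError("ensemble was not run on an augmented network")
    return layout


def ensemble_moments(result: EnsembleResult):
    """Pooled stationary mean and variance of the output with standard errors.

    The variance subtracts the square of the pooled mean (a single global
    centering); batch values are linearised around the pooled mean for the
    error bar.
    """
    tb, T = result.batch_time, result.total_time
    mean = float(result.int_x.sum() / T)
    var = float(result.int_x2.sum() / T - mean**2)
    mean_b = result.int_x / tb
    var_b = result.int_x2 / tb - 2 * mean * mean_b + mean**2
    return mean, var, _batch_se(mean_b), _batch_se(var_b)


def finite_point_derivatives(result: EnsembleResult, ell: int) -> DerivativeEstimate:
    """D_0..D_{rho_l - 1} at the finite point s_l from the shift registers."""
    layout = _layout(result)
    if ell >= len(layout.finite_points):
        raise PadePSDError(f"no finite point with index {ell}")
    s = layout.finite_points[ell]
    rho = layout.rho[ell]
    off = layout.y_offset(ell)
    tb, T = result.batch_time, result.total_time
    mean, var, _, _ = ensemble_moments(result)
    mean_b = result.int_x / tb
    var_b = result.int_x2 / tb - 2 * mean * mean_b + mean**2
    values = np.empty(rho)
    ses = np.empty(rho)
    for m in range(rho):
        delta = float(result.int_ysq[:, :, off + m].sum() / T)
        scale = (-1.0) ** m / s ** (m + 1)
        values[m] = scale * (var - delta / 2.0)
        delta_b = result.int_ysq[:, :, off + m] / tb
        ses[m] = abs(scale) * _batch_se(var_b - delta_b / 2.0)
    return DerivativeEstimate(s=s, values=values, standard_errors=ses, method="erlang-register")


def direct_G_estimates(result: EnsembleResult) -> dict[float, tuple[float, float]]:
    """Direct estimates G_hat(s_bar_r) from the snapshot registers:
    G_hat = (Var - delta_0/2) / s_bar."""
    layout = _layout(result)
    if layout.n_z == 0:
        raise PadePSDError("no snapshot registers present")
    tb, T = result.batch_time, result.total_time
    mean, var, _, _ = ensemble_moments(result)
    mean_b = result.int_x / tb
    var_b = result.int_x2 / tb - 2 * mean * mean_b + mean**2
    out: dict[float, tuple[float, float]] = {}
    for r, sbar in enumerate(layout.test_points):
        delta = float(result.int_zsq[:, :, r].sum() / T)
        val = (var - delta / 2.0) / sbar
        delta_b = result.int_zsq[:, :, r] / tb
        out[sbar] = (val, _batch_se((var_b - delta_b / 2.0) / sbar))
    return out


def _base_network(result: EnsembleResult) -> ReactionNetwork:
    return result.network.metadata.get("base_network", result.network)


def _occupancy_average(result: EnsembleResult, integrand) -> tuple[float, float]:
    """Pooled time average (and batch SE) of a state function from the
    occupancy measure."""
    if result.occupancy is None:
        raise PadePSDError("ensemble was run without occupancy collection")
    tb, T = result.batch_time, result.total_time
    Q, B = result.int_x.shape
    batch_acc = np.zeros((Q, B))
    total = 0.0
    for state, w in result.occupancy.items():
        val = integrand(state)
        total += val * w.sum()
        batch_acc += val * w
    return total / T, _batch_se(batch_acc / tb)


def infinity_derivatives_covariate(result: EnsembleResult, rho_inf: int) -> DerivativeEstimate:
    """D_0..D_{rho-1} at s = infinity via the covariate integrands Psi_m.

    D_0 is the stationary variance (estimated directly from the output
    moments); for m >= 1 the integrand Psi_m does not depend on the
    plug-in stationary mean, since the generator annihilates constants.
    """
    mean, var, _, var_se = ensemble_moments(result)
    gp = GeneratorPowers(_base_network(result), center=mean)
    values = np.empty(rho_inf)
    ses = np.empty(rho_inf)
    values[0], ses[0] = var, var_se
    for m in range(1, rho_inf):
        values[m], ses[m] = _occupancy_average(result, lambda x, m=m: gp.psi(m, x))
    return DerivativeEstimate(s=np.inf, values=values, standard_errors=ses, method="covariate")


def infinity_derivatives_naive(result: EnsembleResult, rho_inf: int) -> DerivativeEstimate:
    """D_0..D_{rho-1} at s = infinity via the plain f * A^m f time average
    (high-variance diagnostic; m = 0 reduces to the variance estimator)."""
    mean, var, _, var_se = ensemble_moments(result)
    gp = GeneratorPowers(_base_network(result), center=mean)
    values = np.empty(rho_inf)
    ses = np.empty(rho_inf)
    values[0], ses[0] = var, var_se
    for m in range(1, rho_inf):
        values[m], ses[m] = _occupancy_average(result, lambda x, m=m: gp.f_times_power(m, x))
    return DerivativeEstimate(s=np.inf, values=values, standard_errors=ses, method="naive")


def estimate_derivatives(
    result: EnsembleResult,
    s_points,
    rho,
    infinity_method: str = "covariate",
) -> PadeDerivativeSet:
    """Assemble the full derivative set for interpolation data (s, rho).

    ``s_points`` may include ``numpy.inf`` (conventionally last); finite
    points must match the augmentation the ensemble was run with.
    """
    layout = _layout(result)
    mean, var, mean_se, var_se = ensemble_moments(result)
    estimates: list[DerivativeEstimate] = []
    finite_seen = 0
    for s, r in zip(s_points, rho):
        if np.isinf(s):
            if infinity_method == "covariate":
                estimates.append(infinity_derivatives_covariate(result, r))
            elif infinity_method == "naive":
                estimates.append(infinity_derivatives_naive(result, r))
            else:
                raise PadePSDError(f"unknown infinity method {infinity_method!r}")
        else:
            idx = layout.finite_points.index(float(s))
            if layout.rho[idx] < r:
                raise PadePSDError(f"augmentation has only {layout.rho[idx]} registers at s={s}")
            est = finite_point_derivatives(result, idx)
            est = DerivativeEstimate(est.s, est.values[:r], est.standard_errors[:r], est.method)
            estimates.append(est)
            finite_seen += 1
    direct = direct_G_estimates(result) if layout.n_z else {}
    return PadeDerivativeSet(
        estimates=estimates,
        mean=mean, mean_se=mean_se,
        variance=var, variance_se=var_se,
        direct=direct,
    )
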