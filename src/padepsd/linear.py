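"""Exact PSD machinery for linear (affine-propensity) reaction networks.

For a network whose propensity vector is affine, lambda(x) = Lambda x + b~,
the mean obeys dx/dt = A x + b with A = S Lambda, b = S b~, the stationary
covariance Sigma solves the Lyapunov equation

    A Sigma + Sigma A^T + D D^T = 0,   D D^T = S diag(Lambda xbar + b~) S^T,

and the output PSD has the closed form

    S_n(omega) = -2 e_n^T (omega^2 I + A^2)^{-1} A Sigma e_n.

When the network is stimulated by independent external signals through
zeroth-order creation reactions (rate theta_j Y_j(t), creating c_j), the
output PSD decomposes into an intrinsic part (inputs frozen at their means)
plus gain-modulated input PSDs — the basis of the composite estimator for
oscillator-driven circuits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import linalg as sla

from .errors import ErgodicityError, NonAffinePropensityError, PadePSDError
from .network import (
    AffineClamped,
    Fixed,
    Hill,
    MassAction,
    ReactionNetwork,
)

__all__ = [
    "LinearNetworkMatrices",
    "InputSignalSpec",
    "linearize",
    "psd_exact",
    "rational_psd_exact",
    "resolvent_G",
    "exact_pade_derivatives",
    "decompose",
    "composite_psd",
    "nfb_oscillation_criterion",
]


@dataclass
class LinearNetworkMatrices:
    """Affine-kinetics matrices: propensity map (Lambda, b~), stoichiometry S,
    drift A = S Lambda, b = S b~, stationary mean xbar = -A^{-1} b, diffusion
    DDt and the Lyapunov covariance Sigma."""

    Lambda: np.ndarray
    btilde: np.ndarray
    S: np.ndarray
    A: np.ndarray
    b: np.ndarray
    xbar: np.ndarray
    DDt: np.ndarray
    Sigma: np.ndarray

    @property
    def d(self) -> int:
        return self.A.shape[0]


def _affine_parts(reaction, d):
    """(intercept, coefficient-vector) of a propensity, or raise."""
    p = reaction.propensity
    if isinstance(p, MassAction):
        nu = np.asarray(reaction.reactant_counts)
        order = int(nu.sum())
        if order == 0:
            return p.rate_constant, np.zeros(d)
        if order == 1:
            j = int(np.nonzero(nu)[0][0])
            coeffs = np.zeros(d)
            coeffs[j] = p.rate_constant
            return 0.0, coeffs
        raise NonAffinePropensityError(
            f"reaction {reaction.name!r}: mass-action order {order} is not affine"
        )
    if isinstance(p, AffineClamped):
        coeffs = np.zeros(d)
        coeffs[: len(p.coeffs)] = p.coeffs
        return p.intercept, coeffs
    kind = "Hill" if isinstance(p, Hill) else type(p).__name__
    raise NonAffinePropensityError(f"reaction {reaction.name!r}: {kind} propensity is not affine")


def linearize(network: ReactionNetwork) -> LinearNetworkMatrices:
    """Extract the affine-kinetics matrices of a linear network.

    Clamped-affine propensities contribute their affine part (the clamp is a
    simulation-side guard); any genuinely non-affine propensity or
    state-dependent jump kernel raises.  A non-Hurwitz drift matrix raises an
    ergodicity error.
    """
    d = network.d
    K = len(network.reactions)
    Lam = np.zeros((K, d))
    bt = np.zeros(K)
    S = np.zeros((d, K))
    for k, r in enumerate(network.reactions):
        if not isinstance(r.displacement, Fixed):
            raise NonAffinePropensityError(
                f"reaction {r.name!r}: state-dependent displacement is outside the linear theory"
            )
        bt[k], Lam[k] = _affine_parts(r, d)
        S[:, k] = r.displacement.zeta
    A = S @ Lam
    b = S @ bt
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= -1e-12):
        raise ErgodicityError(f"drift matrix is not Hurwitz (eigenvalues {np.sort_complex(eig)})")
    xbar = -np.linalg.solve(A, b)
    # raw affine rates: an individual linearised term may be negative at the
    # mean (its positive part is a simulation-side guard only)
    rates = Lam @ xbar + bt
    DDt = S @ np.diag(rates) @ S.T
    Sigma = sla.solve_continuous_lyapunov(A, -DDt)
    Sigma = 0.5 * (Sigma + Sigma.T)
    return LinearNetworkMatrices(Lambda=Lam, btilde=bt, S=S, A=A, b=b, xbar=xbar, DDt=DDt, Sigma=Sigma)


def psd_exact(mats: LinearNetworkMatrices, n: int, omega):
    """Exact output PSD -2 e_n^T (w^2 I + A^2)^{-1} A Sigma e_n (vectorised)."""
    A, Sigma = mats.A, mats.Sigma
    d = mats.d
    rhs = A @ Sigma[:, n]
    scalar = np.ndim(omega) == 0
    om = np.atleast_1d(np.asarray(omega, dtype=float))
    out = np.empty(len(om))
    for i, w in enumerate(om):
        M = w**2 * np.eye(d) + A @ A
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.solve(M + 1e-9 * np.eye(d), rhs)
        out[i] = -2.0 * sol[n]
    return float(out[0]) if scalar else out


def rational_psd_exact(mats: LinearNetworkMatrices, n: int):
    """The exact PSD as a rational function of u = omega^2 (ascending
    coefficients, monic denominator det(u I + A^2) of degree d)."""
    A = mats.A
    d = mats.d
    den_desc = np.poly(np.linalg.eigvals(-A @ A))
    den = np.real(den_desc[::-1])
    den = den / den[-1]
    u_pts = np.arange(1.0, d + 1.0)
    s_vals = psd_exact(mats, n, np.sqrt(u_pts))
    den_vals = np.polynomial.polynomial.polyval(u_pts, den)
    V = np.vander(u_pts, N=d, increasing=True)
    num = np.linalg.solve(V, s_vals * den_vals)
    num[np.abs(num) < 1e-9 * max(1.0, np.max(np.abs(num)))] = 0.0
    return num, den


def resolvent_G(mats: LinearNetworkMatrices, n: int, s):
    """G(s) = e_n^T (s I - A)^{-1} Sigma e_n — exact for linear networks."""
    s = complex(s)
    sol = np.linalg.solve(s * np.eye(mats.d) - mats.A, mats.Sigma[:, n])
    return sol[n]


def exact_pade_derivatives(mats: LinearNetworkMatrices, n: int, s: float, count: int) -> np.ndarray:
    """Exact Pade derivatives of a linear network at point s (inf allowed):
    D_m = e_n^T A^m Sigma e_n at infinity, (-1)^m e_n^T (sI-A)^{-(m+1)} Sigma e_n
    at finite s."""
    A, Sigma = mats.A, mats.Sigma
    v = Sigma[:, n]
    out = np.empty(count)
    if np.isinf(s):
        w = v.copy()
        for m in range(count):
            out[m] = w[n]
            w = A @ w
    else:
        M = float(s) * np.eye(mats.d) - A
        w = v.copy()
        for m in range(count):
            w = np.linalg.solve(M, w)
            out[m] = (-1.0) ** m * w[n]
    return out


@dataclass
class InputSignalSpec:
    """One stimulating signal Y_j: creation reaction of rate theta * Y_j(t)
    producing the integer vector c; ``psd`` evaluates S_{Y_j}(omega) and
    ``mean`` is the stationary input mean used to freeze the intrinsic part."""

    theta: float
    c: np.ndarray
    psd: Callable[[float], float]
    mean: float | None = None


def decompose(mats: LinearNetworkMatrices, n: int, inputs: Sequence[InputSignalSpec], omega):
    """Output-PSD decomposition: intrinsic term plus one gain-modulated term
    per stimulating signal.

    ``mats`` must be built from the downstream network with every input
    frozen at its stationary mean (so Sigma is the frozen-input covariance).
    Returns (intrinsic, [extrinsic_j]); their sum is the full output PSD.
    """
    for spec in inputs:
        if spec.mean is None:
            raise PadePSDError("every input needs its stationary mean (used to freeze Sigma)")
    intrinsic = psd_exact(mats, n, omega)
    scalar = np.ndim(omega) == 0
    om = np.atleast_1d(np.asarray(omega, dtype=float))
    A, d = mats.A, mats.d
    extrinsics = []
    for spec in inputs:
        c = np.asarray(spec.c, dtype=float)
        vals = np.empty(len(om))
        for i, w in enumerate(om):
            sol = np.linalg.solve(A + 1j * w * np.eye(d), c)
            gain = spec.theta**2 * abs(sol[n]) ** 2
            vals[i] = gain * float(spec.psd(w))
        extrinsics.append(float(vals[0]) if scalar else vals)
    return (float(intrinsic) if scalar else intrinsic), extrinsics


def composite_psd(
    mats: LinearNetworkMatrices,
    n: int,
    upstream_psd: Callable[[float], float],
    theta: float,
    c,
    omega,
    upstream_mean: float | None = 0.0,
):
    """Composite PSD of a linear circuit driven by one upstream signal whose
    PSD was obtained elsewhere (analytically or by the Pade estimator).

    theta = 0 reduces to the isolated-circuit PSD.  Returns
    (total, intrinsic, extrinsic).
    """
    if theta == 0.0:
        iso = psd_exact(mats, n, omega)
        zero = np.zeros_like(np.atleast_1d(omega), dtype=float)
        zero = float(zero[0]) if np.ndim(omega) == 0 else zero
        return iso, iso, zero
    spec = InputSignalSpec(theta=theta, c=np.asarray(c), psd=upstream_psd, mean=upstream_mean)
    intrinsic, (extrinsic,) = decompose(mats, n, [spec], omega)
    return intrinsic + extrinsic, intrinsic, extrinsic


def nfb_oscillation_criterion(
    gamma_c: float, gamma_o: float, k_o: float, beta_fb: float, I_0: float
) -> bool:
    """Oscillation criterion of the three-node negative-feedback circuit.

    The linearised NFB output PSD has a strictly positive global maximum iff

        k_o * beta_fb * I_0 > (g_c^4 + g_c^3 k_o + g_o^2 g_c k_o)
                              / (sqrt(Gamma) + g_c g_o + g_c^2 + k_o g_c),

    with Gamma = (g_c g_o + g_c^2 + k_o g_c)^2 + g_c^4 + g_c^3 k_o + g_o^2 g_c k_o.
    The inequality is strict: boundary equality counts as non-oscillatory.
    """
    if min(gamma_c, gamma_o, k_o, beta_fb, I_0) <= 0:
        raise PadePSDError("all NFB parameters must be > 0")
    top = gamma_c**4 + gamma_c**3 * k_o + gamma_o**2 * gamma_c * k_o
    base = gamma_c * gamma_o + gamma_c**2 + k_o * gamma_c
    Gamma = base**2 + top
    threshold = top / (np.sqrt(Gamma) + base)
    return bool(k_o * beta_fb * I_0 > threshold)
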