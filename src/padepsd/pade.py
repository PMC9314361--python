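"""Multipoint Pade approximation of the resolvent transform G(s) and the
rational PSD built from it.

G(s) = E_pi(f R(s) f) admits the eigenmode expansion sum_j alpha_j/(s - sigma_j);
keeping p significant modes gives the rational ansatz

    G_p(s) = (k_0 + k_1 s + ... + k_{p-1} s^{p-1})
             / (b_0 + b_1 s + ... + b_{p-1} s^{p-1} + s^p),

whose 2p coefficients are fixed by matching power-series terms of G at the
interpolation points (the Pade derivatives D_m).  Each point contributes a
small linear block; the stacked system is solved in the least-squares sense,
and the PSD follows as S(omega) = 2 Re G_p(i omega).

A known factor B(s) of the denominator (inherited from an upstream network's
significant eigenvalues, e.g. the cell-cycle clock) can be imposed through a
convolution-matrix change of variables, reducing the number of free
denominator coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import integrate, optimize

from .errors import PadePSDError

__all__ = [
    "RationalPSD",
    "ValidationReport",
    "build_block",
    "solve_pade",
    "peak_frequency",
    "entrainment_score",
    "total_power",
    "validate",
]


def build_block(s: float, rho: int, derivatives, p: int):
    """Linear block (A, b) contributed by interpolation point ``s``.

    Rows j = 0..rho-1 match the j-th power-series coefficient of G_p at s to
    the supplied Pade derivative D_j; the unknown vector is
    (k_0..k_{p-1}, b_0..b_{p-1}).  ``s`` may be ``numpy.inf``.
    """
    if p < 1:
        raise PadePSDError("order p must be >= 1")
    D = np.asarray(derivatives, dtype=float)
    if len(D) < rho:
        raise PadePSDError(f"need {rho} derivatives, got {len(D)}")
    A = np.zeros((rho, 2 * p))
    b = np.zeros(rho)
    if np.isinf(s):
        for j in range(rho):
            if 0 <= p - 1 - j:
                A[j, p - 1 - j] = 1.0
            for i in range(max(p, 2 * p - j), 2 * p):
                A[j, i] = -D[j + i - 2 * p]
            b[j] = D[j]
    else:
        s = float(s)
        for j in range(rho):
            for i in range(j, p):
                A[j, i] = comb(i, j) * s ** (i - j)
            for i in range(p, 2 * p):
                acc = 0.0
                for k in range(0, min(i - p, j) + 1):
                    acc += comb(i - p, k) * s ** (i - p - k) * D[j - k]
                A[j, i] = -acc
            b[j] = sum(comb(p, k) * s ** (p - k) * D[j - k] for k in range(0, min(j, p) + 1))
    return A, b


@dataclass
class RationalPSD:
    """Rational resolvent approximant G_p(s) and the PSD it induces.

    ``numerator``/``denominator`` are ascending-power coefficient arrays of
    the full rational function (denominator monic of degree p, including any
    known factor).  Evaluation: S(omega) = 2 Re G_p(i omega); imperfect
    approximants can dip below zero, so both raw and clipped values are
    available.
    """

    numerator: np.ndarray
    denominator: np.ndarray
    known_factor: np.ndarray | None = None
    residual: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.numerator = np.asarray(self.numerator, dtype=float)
        self.denominator = np.asarray(self.denominator, dtype=float)
        if abs(self.denominator[-1] - 1.0) > 1e-9:
            raise PadePSDError("denominator must be monic")

    @property
    def p(self) -> int:
        return len(self.denominator) - 1

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.denominator[::-1])

    @property
    def stable(self) -> bool:
        return bool(np.all(self.poles.real < 0))

    def G(self, s):
        s = np.asarray(s, dtype=complex)
        num = npoly.polyval(s, self.numerator)
        den = npoly.polyval(s, self.denominator)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        if np.any(den == 0):
            warnings.warn("G_p evaluated at a denominator root; returning inf")
            out = np.where(den == 0, np.inf, out)
        return out if out.shape else complex(out)

    def psd(self, omega, clip: bool = False):
        """Two-sided PSD S(omega) = 2 Re G_p(i omega) (even in omega)."""
        val = 2.0 * np.real(self.G(1j * np.asarray(omega, dtype=float)))
        if clip:
            val = np.clip(val, 0.0, None)
        return val if np.ndim(omega) else float(val)

    def psd_rational(self):
        """PSD as a ratio of polynomials in u = omega^2, monic denominator.

        Writing P(i w) = Pe(u) + i w Po(u) for each polynomial, the PSD is
        2 (Ne De + u No Do) / (De^2 + u Do^2); the denominator is
        automatically monic of degree p in u.
        """
        def split(c):
            ce = np.array([c[k] * (-1.0) ** (k // 2) for k in range(0, len(c), 2)])
            co = np.array([c[k] * (-1.0) ** ((k - 1) // 2) for k in range(1, len(c), 2)])
            return ce, (co if len(co) else np.zeros(1))

        ne, no = split(self.numerator)
        de, do = split(self.denominator)
        num_u = 2.0 * npoly.polyadd(npoly.polymul(ne, de),
                                    npoly.polymul([0.0, 1.0], npoly.polymul(no, do)))
        den_u = npoly.polyadd(npoly.polymul(de, de),
                              npoly.polymul([0.0, 1.0], npoly.polymul(do, do)))
        den_u = np.asarray(den_u)
        num_u = np.asarray(num_u) / den_u[-1]
        den_u = den_u / den_u[-1]
        num_u = np.pad(num_u, (0, max(0, len(den_u) - 1 - len(num_u))))
        return num_u, den_u


def solve_pade(
    blocks,
    p: int,
    known_factor=None,
    rcond: float = 1e-10,
) -> RationalPSD:
    """Least-squares solution of the stacked multipoint system.

    ``blocks`` is an iterable of (s, derivatives) pairs; ``known_factor`` is
    the coefficient vector (B_0, ..., B_{q-1}) of a monic degree-q factor
    imposed on the denominator (q = 0 / None reproduces the plain system
    exactly).  Columns are norm-scaled before the pseudoinverse solve; a
    numerically rank-deficient system is still solved, with a warning.
    """
    blocks = list(blocks)
    if not blocks:
        raise PadePSDError("no interpolation blocks supplied")
    A_rows, b_rows = [], []
    for s, D in blocks:
        D = np.asarray(D, dtype=float)
        Ab, bb = build_block(s, len(D), D, p)
        A_rows.append(Ab)
        b_rows.append(bb)
    A = np.vstack(A_rows)
    b = np.concatenate(b_rows)

    Bhat = np.asarray(known_factor, dtype=float) if known_factor is not None else np.zeros(0)
    q = len(Bhat)
    if q > p:
        raise PadePSDError("known factor degree q must be <= p")
    Bfull = np.concatenate([Bhat, [1.0]])  # monic B(s)
    if q:
        # beta_j = sum_i C_{ji} beta'_i + (coeff of s^j in s^{p-q} B(s))
        C = np.zeros((p, p - q))
        for j in range(p):
            for i in range(max(0, j - q), min(j, p - q - 1) + 1):
                C[j, i] = Bfull[j - i]
        shift = np.zeros(p)
        for j in range(p - q, p):
            shift[j] = Bfull[j - (p - q)]
        T = np.block([
            [np.eye(p), np.zeros((p, p - q))],
            [np.zeros((p, p)), C],
        ])
        v = np.concatenate([np.zeros(p), shift])
        A_eff = A @ T
        b_eff = b - A @ v
    else:
        A_eff, b_eff = A, b

    scale = np.linalg.norm(A_eff, axis=0)
    scale[scale == 0] = 1.0
    As = A_eff / scale
    rank = np.linalg.matrix_rank(As, tol=rcond * max(As.shape) * np.linalg.norm(As, 2))
    if rank < As.shape[1]:
        warnings.warn(
            f"Pade system numerically rank-deficient (rank {rank} < {As.shape[1]}); "
            "solving via pseudoinverse"
        )
    x_scaled = np.linalg.pinv(As, rcond=rcond) @ b_eff
    x = x_scaled / scale
    residual = float(np.linalg.norm(A_eff @ x - b_eff))

    numer = x[:p]
    if q:
        beta_prime = np.concatenate([x[p:], [1.0]])
        denom = npoly.polymul(beta_prime, Bfull)
    else:
        denom = np.concatenate([x[p:], [1.0]])
    rational = RationalPSD(
        numerator=numer,
        denominator=np.asarray(denom, dtype=float),
        known_factor=Bhat if q else None,
        residual=residual,
        metadata={"p": p, "points": [s for s, _ in blocks]},
    )
    if not rational.stable:
        warnings.warn(
            "Pade denominator has roots with non-negative real part; "
            "validate the approximant before trusting the PSD"
        )
    return rational


def peak_frequency(psd, omega_hi: float | None = None, n_grid: int = 2001) -> float:
    """Location of the global PSD maximum on [0, omega_hi].

    ``psd`` is a callable or a :class:`RationalPSD` (then ``omega_hi``
    defaults to a few times the largest pole magnitude).  A coarse grid
    locates the maximum and a bounded scalar polish refines it; 0 means the
    output is non-oscillatory.
    """
    if isinstance(psd, RationalPSD):
        if omega_hi is None:
            omega_hi = 5.0 * float(np.max(np.abs(psd.poles))) + 1.0
        fn = psd.psd
    else:
        if omega_hi is None:
            raise PadePSDError("omega_hi is required for generic callables")
        fn = psd
    grid = np.linspace(0.0, omega_hi, n_grid)
    vals = np.array([fn(w) for w in grid])
    i = int(np.argmax(vals))
    if i == 0:
        return 0.0
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda w: -fn(w), bounds=(lo, hi), method="bounded")
    w_star = float(res.x)
    if fn(w_star) <= fn(0.0) * (1.0 + 1e-12):
        return 0.0
    return w_star


def _check_integrable(psd) -> None:
    if isinstance(psd, RationalPSD):
        num_u, den_u = psd.psd_rational()
        nz = np.nonzero(np.abs(num_u) > 1e-12 * max(1.0, np.max(np.abs(num_u))))[0]
        deg_num = nz[-1] if len(nz) else 0
        if deg_num >= len(den_u) - 1:
            raise PadePSDError("PSD is not integrable on [0, inf)")


def total_power(psd) -> float:
    """(1/2pi) * integral of S over the whole real line (= band power of the
    even two-sided PSD).  For a perfect approximant this equals Var_pi(X_n)."""
    _check_integrable(psd)
    fn = psd.psd if isinstance(psd, RationalPSD) else psd
    val, _ = integrate.quad(fn, 0.0, np.inf, limit=400)
    return val / np.pi


def entrainment_score(psd, omega0: float, band_frac: float = 0.1) -> float:
    """Fraction of total signal power inside [(1-band_frac) w0, (1+band_frac) w0].

    A score near 1 means the output oscillates essentially at the driver
    frequency w0; the band defaults to +-10% of w0.
    """
    if omega0 <= 0:
        raise PadePSDError("omega0 must be > 0")
    _check_integrable(psd)
    fn = psd.psd if isinstance(psd, RationalPSD) else psd
    lo, hi = (1.0 - band_frac) * omega0, (1.0 + band_frac) * omega0
    if hi <= lo:
        return 0.0
    band, _ = integrate.quad(fn, lo, hi, limit=200)
    head, _ = integrate.quad(fn, 0.0, max(hi * 2.0, 2.0 * omega0), limit=400)
    tail, _ = integrate.quad(fn, max(hi * 2.0, 2.0 * omega0), np.inf, limit=400)
    total = head + tail
    if total <= 0:
        return 0.0
    return float(band / total)


@dataclass
class ValidationEntry:
    s_bar: float
    G_pade: float
    G_direct: float
    se: float
    relative_error: float
    passed: bool


@dataclass
class ValidationReport:
    entries: list[ValidationEntry]
    threshold: float

    @property
    def passed(self) -> bool:
        return all(e.passed for e in self.entries)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "passed": self.passed,
            "points": [
                {
                    "s_bar": e.s_bar,
                    "G_pade": e.G_pade,
                    "G_direct": e.G_direct,
                    "se": e.se,
                    "relative_error": e.relative_error,
                    "passed": e.passed,
                }
                for e in self.entries
            ],
        }


def validate(rational: RationalPSD, direct: dict, threshold: float = 0.1) -> ValidationReport:
    """Compare G_p(s_bar) against the direct register estimates G_hat(s_bar).

    A point passes when |G_p - G_hat| <= max(threshold * |G_hat|, 3 se); the
    approximant passes when every test point does.
    """
    if not direct:
        raise PadePSDError("need at least one test point")
    entries = []
    for s_bar, (g_hat, se) in sorted(direct.items()):
        g_p = float(np.real(rational.G(s_bar)))
        err = abs(g_p - g_hat)
        rel = err / abs(g_hat) if g_hat != 0 else np.inf
        tol = max(threshold * abs(g_hat), 3.0 * (se if np.isfinite(se) else 0.0))
        entries.append(
            ValidationEntry(
                s_bar=float(s_bar), G_pade=g_p, G_direct=float(g_hat),
                se=float(se), relative_error=float(rel), passed=bool(err <= tol),
            )
        )
    return ValidationReport(entries=entries, threshold=threshold)
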