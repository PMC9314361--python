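"""Memoized generator powers A^m f and the covariate integrands for the
infinity-point derivative estimators.

The m-th derivative of the resolvent transform at s = infinity is the
stationary expectation E_pi(f A^m f), where f(x) = x_n - E_pi(X_n).  A^m f is
evaluated pointwise by the recursion

    A^m f(x) = sum_k lambda_k(x) [ A^{m-1} f(x + zeta_k) - A^{m-1} f(x) ],

memoized over (m, state): ergodic chains revisit the same states constantly,
so a lookup table turns an exponentially branching recursion into a cheap
per-state evaluation.
"""

from __future__ import annotations

from collections import OrderedDict
from math import comb

import numpy as np

from .errors import UnsupportedOperationError
from .network import Fixed, JumpKernel, ReactionNetwork, propensity

__all__ = ["GeneratorPowers", "generator_power"]


class GeneratorPowers:
    """Lookup-table evaluator for A^m f on a fixed-displacement network.

    ``center`` is the value subtracted from the output count, i.e.
    f(x) = x_n - center.  Note that A^m f for m >= 1 does not depend on
    ``center`` (the generator annihilates constants), so a plug-in estimate
    of the stationary mean only affects the m = 0 term.
    """

    def __init__(self, network: ReactionNetwork, center: float = 0.0, max_entries: int = 2_000_000):
        for r in network.reactions:
            if isinstance(r.displacement, JumpKernel):
                raise UnsupportedOperationError(
                    "generator powers require fixed displacements; use finite "
                    "interpolation points for networks with jump kernels"
                )
        self.network = network
        self.center = float(center)
        self.n = network.output_index
        self.max_entries = max_entries
        self._cache: OrderedDict[tuple, float] = OrderedDict()
        # per-state propensities and neighbours are also memoized
        self._moves: OrderedDict[tuple, list[tuple[float, tuple]]] = OrderedDict()

    # -- internals ---------------------------------------------------------
    def _move_list(self, state: tuple) -> list[tuple[float, tuple]]:
        got = self._moves.get(state)
        if got is not None:
            return got
        arr = np.asarray(state, dtype=np.int64)
        moves = []
        for r in self.network.reactions:
            lam = propensity(r, arr)
            if lam == 0.0:
                continue
            disp = r.displacement
            if isinstance(disp, Fixed):
                moves.append((lam, tuple(int(a + b) for a, b in zip(state, disp.zeta))))
            else:  # RegisterReset inside an augmented chain: registers never
                # feed back into the base species, and f depends only on the
                # base output, so resets contribute 0 to A^m f.
                continue
        if len(self._moves) >= self.max_entries:
            self._moves.popitem(last=False)
        self._moves[state] = moves
        return moves

    def value(self, m: int, state) -> float:
        """A^m f evaluated at ``state`` (A^0 f = f)."""
        if m < 0:
            raise ValueError("m must be >= 0")
        state = tuple(int(v) for v in state)
        if m == 0:
            return state[self.n] - self.center
        key = (m, state)
        got = self._cache.get(key)
        if got is not None:
            return got
        val = 0.0
        prev = self.value(m - 1, state)
        for lam, nbr in self._move_list(state):
            val += lam * (self.value(m - 1, nbr) - prev)
        if len(self._cache) >= self.max_entries:
            self._cache.popitem(last=False)
        self._cache[key] = val
        return val

    # -- covariate machinery ------------------------------------------------
    def gamma(self, j: int, l: int, state) -> float:
        """Carre-du-champ term gamma_jl(x) = sum_k lambda_k(x)
        [A^j f(x+zeta_k) - A^j f(x)] [A^l f(x+zeta_k) - A^l f(x)]."""
        state = tuple(int(v) for v in state)
        aj = self.value(j, state)
        al = self.value(l, state)
        total = 0.0
        for lam, nbr in self._move_list(state):
            total += lam * (self.value(j, nbr) - aj) * (self.value(l, nbr) - al)
        return total

    def psi(self, m: int, state) -> float:
        """Covariate integrand Psi_m whose stationary mean is E_pi(f A^m f).

        Defined for m >= 1; the m = 0 derivative is the stationary variance
        and is estimated directly from the output path.
        """
        if m < 1:
            raise ValueError("psi is defined for m >= 1; use the variance estimator for m = 0")
        state = tuple(int(v) for v in state)
        if m % 2 == 0:
            r = m // 2
            val = 0.5 * comb(m, r) * self.value(r, state) ** 2
            for k in range(1, r):
                val += comb(m, k) * self.value(k, state) * self.value(m - k, state)
            for k in range(r):
                val += comb(m - 1, k) * self.gamma(k, m - 1 - k, state)
        else:
            r = (m - 1) // 2
            val = 0.0
            for k in range(1, r + 1):
                val += comb(m, k) * self.value(k, state) * self.value(m - k, state)
            for k in range(r):
                val += comb(m - 1, k) * self.gamma(k, m - 1 - k, state)
            val += 0.5 * comb(m - 1, r) * self.gamma(r, r, state)
        return -val

    def f_times_power(self, m: int, state) -> float:
        """f(x) * A^m f(x) — the integrand of the naive estimator."""
        return self.value(0, state) * self.value(m, state)


def generator_power(network: ReactionNetwork, m: int, state, center: float = 0.0) -> float:
    """One-shot A^m f(x) (f(x) = x_n - center); see :class:`GeneratorPowers`."""
    return GeneratorPowers(network, center=center).value(m, state)
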