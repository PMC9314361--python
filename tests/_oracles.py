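"""Independent oracles for the test suite: finite-state truncated generator
matrices, their stationary laws, resolvent transforms and series
coefficients.

Everything here is computed by dense linear algebra on an explicitly
enumerated state space — no code path is shared with the estimators under
test beyond the propensity evaluation used to fill the rate matrix.
"""

from __future__ import annotations

import numpy as np

from padepsd import Fixed, propensity


class TruncatedOracle:
    """Exact chain quantities on an enumerated, truncated state space."""

    def __init__(self, network, caps):
        self.network = network
        self.caps = tuple(caps)
        ranges = [range(c + 1) for c in self.caps]
        self.states = [tuple(s) for s in np.stack(
            np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, len(self.caps))]
        self.index = {s: i for i, s in enumerate(self.states)}
        N = len(self.states)
        Q = np.zeros((N, N))
        for s in self.states:
            i = self.index[s]
            for r in network.reactions:
                if not isinstance(r.displacement, Fixed):
                    raise ValueError("oracle supports fixed displacements only")
                lam = propensity(r, np.asarray(s))
                if lam <= 0:
                    continue
                target = tuple(int(a + b) for a, b in zip(s, r.displacement.zeta))
                if target in self.index:
                    Q[i, self.index[target]] += lam
            Q[i, i] -= Q[i].sum() - Q[i, i]
        self.Q = Q
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        self.pi = pi / pi.sum()
        n = network.output_index
        xn = np.array([s[n] for s in self.states], dtype=float)
        self.mean = float(self.pi @ xn)
        self.f = xn - self.mean
        self.variance = float(self.pi @ self.f**2)

    def G(self, s: complex) -> complex:
        """G(s) = pi-weighted f (sI - Q)^{-1} f."""
        N = len(self.states)
        sol = np.linalg.solve(s * np.eye(N) - self.Q, self.f)
        return complex((self.pi * self.f) @ sol)

    def psd(self, omega: float) -> float:
        return 2.0 * self.G(1j * omega).real

    def pade_derivatives(self, s: float, count: int) -> np.ndarray:
        """D_m at point s (inf allowed), m = 0..count-1."""
        out = np.empty(count)
        if np.isinf(s):
            w = self.f.copy()
            for m in range(count):
                out[m] = (self.pi * self.f) @ w
                w = self.Q @ w
        else:
            M = float(s) * np.eye(len(self.states)) - self.Q
            w = self.f.copy()
            for m in range(count):
                w = np.linalg.solve(M, w)
                out[m] = (-1.0) ** m * (self.pi * self.f) @ w
        return out

    def expectation(self, fn) -> float:
        return float(sum(p * fn(s) for p, s in zip(self.pi, self.states)))
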