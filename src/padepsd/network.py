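"""Reaction networks as continuous-time Markov chains on the copy-number lattice.

A network is a list of species and a list of reactions.  Each reaction has a
propensity (mass-action, clamped-affine, Hill, or an arbitrary callable) and a
displacement, which is either a fixed stoichiometric vector or a state-dependent
jump kernel (used for whole-cell events such as division, where the molecular
population is repartitioned).  The generator of the chain is

    A h(x) = sum_k lambda_k(x) * E[ h(x + zeta) - h(x) ],

with the expectation over the reaction's displacement distribution; for fixed
displacements this is the classical chemical-master-equation generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import NegativeStateError, NetworkSpecError, UnsupportedOperationError

__all__ = [
    "MassAction",
    "AffineClamped",
    "Hill",
    "CustomPropensity",
    "Fixed",
    "JumpKernel",
    "BinomialPartition",
    "StrictBinaryPartition",
    "CellDivision",
    "RegisterReset",
    "AffineFunction",
    "Reaction",
    "ReactionNetwork",
    "propensity",
    "apply_generator",
]


# ---------------------------------------------------------------------------
# propensity forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassAction:
    """Mass-action propensity theta * prod_j C(x_j, nu_jk).

    The reactant counts nu live on the owning :class:`Reaction`.  A reaction
    with no reactants is zeroth order with constant rate ``rate_constant``.
    """

    rate_constant: float

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise NetworkSpecError("mass-action rate constant must be > 0")


@dataclass(frozen=True)
class AffineClamped:
    """Propensity max(intercept + coeffs . x, 0).

    The clamp at zero matches how simulations treat linearised repression
    terms; the linear-network analytics use the unclamped affine part.
    """

    intercept: float
    coeffs: tuple[float, ...]

    def value(self, state: np.ndarray) -> float:
        return max(self.intercept + float(np.dot(self.coeffs, state[: len(self.coeffs)])), 0.0)


@dataclass(frozen=True)
class Hill:
    """Propensity basal + amplitude / (K + x_j**H).

    With basal=0 this is the repressing Hill form K0/(K1 + x^H); with H=1 it
    also covers hyperbolic feedback terms such as a/(b + x).
    """

    species: int
    amplitude: float
    K: float
    H: float
    basal: float = 0.0

    def value(self, state: np.ndarray) -> float:
        return self.basal + self.amplitude / (self.K + float(state[self.species]) ** self.H)


@dataclass
class CustomPropensity:
    """Arbitrary state -> rate callable; negative values are clamped at 0."""

    fn: Callable[[np.ndarray], float]
    expression: str | None = None

    def value(self, state: np.ndarray) -> float:
        return max(float(self.fn(state)), 0.0)


# ---------------------------------------------------------------------------
# displacements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixed:
    """Deterministic integer displacement (stoichiometric vector)."""

    zeta: tuple[int, ...]


class JumpKernel:
    """State-dependent displacement distribution mu_k(x, .).

    Subclasses provide ``sample`` plus closed-form first and second conditional
    moments of the post-jump state, assuming independence across components.
    The moment interface is what keeps the generator applicable to affine
    observables without enumerating the (possibly huge) partition support.
    """

    kind = "custom"

    def sample(self, state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def post_mean(self, state: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def post_var(self, state: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class BinomialPartition(JumpKernel):
    """Symmetric binomial partition: each tracked molecule is kept with
    probability 1/2, independently.  E[x'_j] = x_j/2, Var[x'_j] = x_j/4."""

    kind = "binomial_partition"

    def __init__(self, species: Sequence[int]):
        self.species = tuple(species)

    def sample(self, state, rng):
        disp = np.zeros(len(state), dtype=np.int64)
        for j in self.species:
            disp[j] = rng.binomial(int(state[j]), 0.5) - int(state[j])
        return disp

    def post_mean(self, state):
        mean = np.asarray(state, dtype=float).copy()
        for j in self.species:
            mean[j] = state[j] / 2.0
        return mean

    def post_var(self, state):
        var = np.zeros(len(state))
        for j in self.species:
            var[j] = state[j] / 4.0
        return var


class StrictBinaryPartition(JumpKernel):
    """Strict binary partition: the tracked cell receives exactly half of each
    species; an odd count 2m+1 yields m or m+1 with probability 1/2 each."""

    kind = "strict_binary_partition"

    def __init__(self, species: Sequence[int]):
        self.species = tuple(species)

    def sample(self, state, rng):
        disp = np.zeros(len(state), dtype=np.int64)
        for j in self.species:
            xj = int(state[j])
            half = xj // 2
            if xj % 2 == 1 and rng.random() < 0.5:
                half += 1
            disp[j] = half - xj
        return disp

    def post_mean(self, state):
        mean = np.asarray(state, dtype=float).copy()
        for j in self.species:
            mean[j] = state[j] / 2.0
        return mean

    def post_var(self, state):
        var = np.zeros(len(state))
        for j in self.species:
            var[j] = 0.25 if int(state[j]) % 2 == 1 else 0.0
        return var


class CellDivision(JumpKernel):
    """Cell-cycle stage advance with division at the end of the cycle.

    The stage species cycles through 0..N-1 at constant rate; when the jump
    fires at stage N-1 the stage resets to 0 and the molecular species are
    partitioned between the daughter cells by the wrapped partition kernel.
    The displacement is therefore state-dependent but, given the state, the
    branch (advance vs divide) is deterministic.
    """

    kind = "cell_division"

    def __init__(self, stage_index: int, n_stages: int, partition: JumpKernel):
        if n_stages < 2:
            raise NetworkSpecError("cell cycle needs at least 2 stages")
        self.stage_index = stage_index
        self.n_stages = n_stages
        self.partition = partition

    def _dividing(self, state) -> bool:
        return int(state[self.stage_index]) >= self.n_stages - 1

    def sample(self, state, rng):
        disp = np.zeros(len(state), dtype=np.int64)
        if not self._dividing(state):
            disp[self.stage_index] = 1
            return disp
        disp = self.partition.sample(state, rng)
        disp[self.stage_index] = -int(state[self.stage_index])
        return disp

    def post_mean(self, state):
        if not self._dividing(state):
            mean = np.asarray(state, dtype=float).copy()
            mean[self.stage_index] += 1
            return mean
        mean = self.partition.post_mean(state)
        mean[self.stage_index] = 0.0
        return mean

    def post_var(self, state):
        if not self._dividing(state):
            return np.zeros(len(state))
        var = self.partition.post_var(state)
        var[self.stage_index] = 0.0
        return var


@dataclass(frozen=True)
class RegisterReset:
    """Reset map for augmented-chain registers (not a stoichiometric jump).

    kind='shift': Y_start <- x_source and Y_{j} <- Y_{j-1} down the block.
    kind='snapshot': Z_slot <- x_source.
    Indices are absolute positions in the augmented state vector.
    """

    kind: str  # "shift" | "snapshot"
    start: int
    length: int
    source: int

    def apply(self, state: np.ndarray) -> np.ndarray:
        new = state.copy()
        if self.kind == "shift":
            new[self.start + 1 : self.start + self.length] = state[self.start : self.start + self.length - 1]
            new[self.start] = state[self.source]
        else:
            new[self.start] = state[self.source]
        return new


# ---------------------------------------------------------------------------
# reactions and networks
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """One reaction channel: reactant counts (drive mass-action kinetics),
    a propensity object and a displacement (Fixed, JumpKernel or RegisterReset)."""

    reactant_counts: tuple[int, ...]
    propensity: MassAction | AffineClamped | Hill | CustomPropensity
    displacement: Fixed | JumpKernel | RegisterReset
    name: str = ""

    @staticmethod
    def from_counts(
        d: int,
        reactants: dict[int, int] | None,
        products: dict[int, int] | None,
        propensity,
        name: str = "",
    ) -> "Reaction":
        nu = [0] * d
        for j, c in (reactants or {}).items():
            nu[j] = c
        zeta = [0] * d
        for j, c in (products or {}).items():
            zeta[j] += c
        for j, c in (reactants or {}).items():
            zeta[j] -= c
        return Reaction(tuple(nu), propensity, Fixed(tuple(zeta)), name=name)


@dataclass
class ReactionNetwork:
    """A reaction network with a designated scalar output species.

    ``output_index`` is 0-based internally; user-facing configuration uses
    species names (and 1-based indices where numeric).
    """

    species_names: list[str]
    reactions: list[Reaction]
    output_species: str
    initial_state: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.species_names) < 1:
            raise NetworkSpecError("network needs at least one species")
        if len(set(self.species_names)) != len(self.species_names):
            raise NetworkSpecError("duplicate species names")
        if self.output_species not in self.species_names:
            raise NetworkSpecError(f"unknown output species {self.output_species!r}")
        d = self.d
        for r in self.reactions:
            if len(r.reactant_counts) != d:
                raise NetworkSpecError(f"reaction {r.name!r}: reactant vector length != {d}")
            if any(c < 0 for c in r.reactant_counts):
                raise NetworkSpecError(f"reaction {r.name!r}: negative reactant count")
            if isinstance(r.displacement, Fixed) and len(r.displacement.zeta) != d:
                raise NetworkSpecError(f"reaction {r.name!r}: displacement length != {d}")
        if self.initial_state is not None:
            self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
            if self.initial_state.shape != (d,):
                raise NetworkSpecError("initial_state has wrong length")

    @property
    def d(self) -> int:
        return len(self.species_names)

    @property
    def output_index(self) -> int:
        return self.species_names.index(self.output_species)

    @property
    def has_kernels(self) -> bool:
        return any(isinstance(r.displacement, JumpKernel) for r in self.reactions)

    @property
    def has_custom(self) -> bool:
        return any(isinstance(r.propensity, CustomPropensity) for r in self.reactions)

    def default_initial_state(self) -> np.ndarray:
        if self.initial_state is not None:
            return self.initial_state.copy()
        return np.zeros(self.d, dtype=np.int64)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def propensity(reaction: Reaction, state: np.ndarray) -> float:
    """Firing rate of ``reaction`` at ``state`` (componentwise >= 0).

    Mass-action uses the combinatorial falling-factorial form
    theta * prod_j x_j(x_j-1)...(x_j-nu_jk+1)/nu_jk!, which vanishes whenever
    any reactant count is insufficient.
    """
    state = np.asarray(state)
    if np.any(state < 0):
        raise NegativeStateError(f"negative state {state}")
    prop = reaction.propensity
    if isinstance(prop, MassAction):
        rate = prop.rate_constant
        for xj, nu in zip(state, reaction.reactant_counts):
            if nu:
                rate *= math.comb(int(xj), nu)
                if rate == 0.0:
                    return 0.0
        return float(rate)
    return float(prop.value(state))


@dataclass(frozen=True)
class AffineFunction:
    """Affine observable h(x) = const + coeffs . x.

    The generator maps affine functions to affine-friendly expectations even
    for partition kernels, because the conditional post-state mean is itself
    affine in the state.
    """

    const: float
    coeffs: tuple[float, ...]

    def __call__(self, state) -> float:
        return self.const + float(np.dot(self.coeffs, np.asarray(state, dtype=float)))


def apply_generator(network: ReactionNetwork, h, state) -> float:
    """Evaluate A h(x) = sum_k lambda_k(x) E[h(x + zeta) - h(x)].

    ``h`` may be any callable for fixed-displacement (and register-reset)
    reactions.  For jump-kernel reactions ``h`` must be an
    :class:`AffineFunction` so the expectation is available in closed form via
    the kernel's moment interface.
    """
    state = np.asarray(state, dtype=np.int64)
    if np.any(state < 0):
        raise NegativeStateError(f"negative state {state}")
    hx = float(h(state))
    total = 0.0
    for r in network.reactions:
        lam = propensity(r, state)
        if lam == 0.0:
            continue
        disp = r.displacement
        if isinstance(disp, Fixed):
            total += lam * (float(h(state + np.asarray(disp.zeta))) - hx)
        elif isinstance(disp, RegisterReset):
            total += lam * (float(h(disp.apply(state))) - hx)
        else:  # JumpKernel
            if not isinstance(h, AffineFunction):
                raise UnsupportedOperationError(
                    "jump-kernel reactions require an AffineFunction observable "
                    "(closed-form conditional moments)"
                )
            total += lam * (h.const + float(np.dot(h.coeffs, disp.post_mean(state))) - hx)
    return total
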