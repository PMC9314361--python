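"""Augmented CTMC construction: shift registers and snapshot registers.

Finite-point Pade derivatives are correlations of the output with its own
past at Erlang-distributed lags.  Rather than post-processing a stored path,
the chain itself is augmented: for each finite interpolation point s a
constant-rate reaction R_s fires as a Poisson clock, and on each firing a
block of rho registers shifts, capturing X_n at the firing epoch:

    Y_1 <- X_n(t-),   Y_j <- Y_{j-1}(t-)  (j = 2..rho).

At any time T, Y_{m+1} then equals X_n(T - tau) with tau ~ Erlang(m+1, s),
independent of the chain.  Snapshot registers Z_r (one per validation point
s_bar_r) do the same with a single slot.  Registers never feed back into the
base species, so the marginal law of X is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PadePSDError
from .network import (
    AffineClamped,
    Fixed,
    MassAction,
    Reaction,
    ReactionNetwork,
    RegisterReset,
)
from .ssa import Trajectory

__all__ = ["AugmentationLayout", "augment", "register_lag_law_check"]


@dataclass
class AugmentationLayout:
    """Register bookkeeping for an augmented network.

    ``finite_points``/``rho`` exclude s = infinity (which needs no
    registers); ``y_offsets[l]`` is the index of the first register of block
    l within the Y vector.
    """

    finite_points: tuple[float, ...]
    rho: tuple[int, ...]
    test_points: tuple[float, ...]
    n_base_species: int
    y_start: int
    z_start: int
    reset_reaction_indices: tuple[int, ...]
    snapshot_reaction_indices: tuple[int, ...]

    @property
    def n_y(self) -> int:
        return sum(self.rho)

    @property
    def n_z(self) -> int:
        return len(self.test_points)

    def y_offset(self, ell: int) -> int:
        return sum(self.rho[:ell])


def augment(
    network: ReactionNetwork,
    s_points=(),
    rho=(),
    test_points=(),
) -> ReactionNetwork:
    """Build the augmented chain (X, Y, Z) for the given interpolation data.

    ``s_points`` lists the *finite* interpolation points with their match
    counts ``rho`` (s = infinity contributes no registers and must not be
    passed here); ``test_points`` are the validation points s_bar_r.
    """
    s_points = tuple(float(s) for s in s_points)
    rho = tuple(int(r) for r in rho)
    test_points = tuple(float(s) for s in test_points)
    if len(s_points) != len(rho):
        raise PadePSDError("s_points and rho must have equal length")
    if any(not np.isfinite(s) for s in s_points):
        raise PadePSDError("s = infinity carries no registers; pass finite points only")
    if any(s <= 0 for s in s_points) or any(s <= 0 for s in test_points):
        raise PadePSDError("interpolation/test points must be > 0")
    if len(set(s_points)) != len(s_points) or len(set(test_points)) != len(test_points):
        raise PadePSDError("duplicate interpolation or test points")
    if any(r < 1 for r in rho):
        raise PadePSDError("each match count rho must be >= 1")

    d = network.d
    n_y = sum(rho)
    n_z = len(test_points)
    d_aug = d + n_y + n_z
    names = list(network.species_names)
    names += [f"_Y{j+1}" for j in range(n_y)]
    names += [f"_Z{r+1}" for r in range(n_z)]
    n = network.output_index

    reactions: list[Reaction] = []
    for r in network.reactions:
        nu = tuple(r.reactant_counts) + (0,) * (n_y + n_z)
        prop = r.propensity
        if isinstance(prop, AffineClamped):
            prop = AffineClamped(prop.intercept, tuple(prop.coeffs) + (0.0,) * (d_aug - len(prop.coeffs)))
        disp = r.displacement
        if isinstance(disp, Fixed):
            disp = Fixed(tuple(disp.zeta) + (0,) * (n_y + n_z))
        reactions.append(Reaction(nu, prop, disp, name=r.name))

    reset_idx = []
    off = d
    for ell, (s, rl) in enumerate(zip(s_points, rho)):
        reset_idx.append(len(reactions))
        reactions.append(
            Reaction(
                (0,) * d_aug,
                MassAction(s),
                RegisterReset("shift", start=off, length=rl, source=n),
                name=f"R_s{ell+1}",
            )
        )
        off += rl
    snap_idx = []
    for r_i, s in enumerate(test_points):
        snap_idx.append(len(reactions))
        reactions.append(
            Reaction(
                (0,) * d_aug,
                MassAction(s),
                RegisterReset("snapshot", start=d + n_y + r_i, length=1, source=n),
                name=f"R_sbar{r_i+1}",
            )
        )

    layout = AugmentationLayout(
        finite_points=s_points,
        rho=rho,
        test_points=test_points,
        n_base_species=d,
        y_start=d,
        z_start=d + n_y,
        reset_reaction_indices=tuple(reset_idx),
        snapshot_reaction_indices=tuple(snap_idx),
    )
    x0 = None
    if network.initial_state is not None:
        xn0 = int(network.initial_state[n])
        x0 = np.concatenate([network.initial_state, np.full(n_y + n_z, xn0, dtype=np.int64)])
    aug = ReactionNetwork(
        species_names=names,
        reactions=reactions,
        output_species=network.output_species,
        initial_state=x0,
        metadata={
            **network.metadata,
            "base_network": network,
            "n_base_species": d,
            "y_start": d,
            "n_y": n_y,
            "z_start": d + n_y,
            "n_z": n_z,
            "augmentation": layout,
        },
    )
    return aug


def register_lag_law_check(
    trajectory: Trajectory,
    augmented: ReactionNetwork,
    ell: int,
    m: int,
    n_inspection_times: int = 400,
) -> np.ndarray:
    """Empirical lag sample for register Y_{m+1} of finite point l.

    At inspection time T the register Y_{m+1} must equal X_n evaluated just
    before the (m+1)-th most recent firing of R_{s_l}; the elapsed lags are
    returned for distributional testing (they should follow an
    Erlang(m+1, s_l) law at stationarity of the Poisson reset clock).
    Raises if the path contains fewer than m+1 firings.
    """
    layout: AugmentationLayout = augmented.metadata["augmentation"]
    if ell >= len(layout.finite_points):
        raise PadePSDError(f"no finite interpolation point with index {ell}")
    if m >= layout.rho[ell]:
        raise PadePSDError(f"register m={m} not present (rho={layout.rho[ell]})")
    ridx = layout.reset_reaction_indices[ell]
    fire_mask = trajectory.reaction_indices == ridx
    fire_positions = np.nonzero(fire_mask)[0]
    if len(fire_positions) < m + 1:
        raise PadePSDError(f"need at least {m+1} firings of the reset reaction")
    fire_times = trajectory.times[fire_positions]
    n_out = augmented.output_index
    reg_index = layout.y_start + layout.y_offset(ell) + m
    t_lo = fire_times[m]
    grid = np.linspace(t_lo + 1e-9, trajectory.horizon, n_inspection_times)
    lags = np.empty(len(grid))
    for i, T in enumerate(grid):
        idx = int(np.searchsorted(fire_times, T, side="right"))
        pos = fire_positions[idx - 1 - m]  # path row of the (m+1)-th most recent firing
        t_star = trajectory.times[pos]
        lags[i] = T - t_star
        expected = trajectory.states[pos - 1, n_out]  # X_n just before the firing
        actual = trajectory.state_at(T)[reg_index]
        if actual != expected:
            raise PadePSDError(
                f"register mismatch at T={T}: Y_{m+1}={actual}, X_n(t*-)={expected}"
            )
    return lags
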