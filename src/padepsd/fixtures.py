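"""Catalog of example networks: the analytic benchmark set (birth-death,
gene expression, RNA splicing, IFF, NFB), the synthetic-biology circuits
(repressilator, antithetic integral feedback), the self-regulating gene used
for PSD-based inference, and the dividing-cell host.

The four linear benchmarks carry the parameter sets whose closed-form PSDs
are asserted exactly in the test suite.  The nonlinear circuits use
representative defaults chosen to sit in the qualitative regime of interest
(sustained stochastic oscillations; set-point tracking with tunable extra
feedback); they are documented as package defaults, not literature values.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .engine import run_ensemble
from .errors import NetworkSpecError, PadePSDError
from .network import (
    AffineClamped,
    BinomialPartition,
    CellDivision,
    Fixed,
    Hill,
    MassAction,
    Reaction,
    ReactionNetwork,
    StrictBinaryPartition,
)
from .ssa import EnsembleConfig

__all__ = [
    "birth_death",
    "telegraph",
    "gene_expression",
    "rna_splicing",
    "iff",
    "nfb",
    "self_regulating_gene",
    "repressilator",
    "aif_gene_expression",
    "cell_cycle_host",
    "entrainment_circuit",
    "known_factor_for_cell_cycle",
    "synthetic_experiment_traces",
    "CATALOG",
    "make",
]


def _rxn(d, reactants, products, prop, name):
    return Reaction.from_counts(d, reactants, products, prop, name=name)


def birth_death(k: float = 1.0, gamma: float = 1.0) -> ReactionNetwork:
    """0 -> X at rate k, X -> 0 at rate gamma x.  Stationary law Poisson(k/gamma);
    PSD 2k/(gamma^2 + omega^2)."""
    reactions = [
        _rxn(1, {}, {0: 1}, MassAction(k), "birth"),
        _rxn(1, {0: 1}, {}, MassAction(gamma), "death"),
    ]
    return ReactionNetwork(["X"], reactions, "X",
                           initial_state=[max(1, round(k / gamma))])


def telegraph(k_on: float = 1.0, k_off: float = 3.0) -> ReactionNetwork:
    """Two-state gene represented as a single 0/1 species G: activation at
    affine rate k_on (1 - g), deactivation at rate k_off g."""
    reactions = [
        Reaction((0,), AffineClamped(k_on, (-k_on,)), Fixed((1,)), name="activate"),
        _rxn(1, {0: 1}, {}, MassAction(k_off), "deactivate"),
    ]
    return ReactionNetwork(["G"], reactions, "G", initial_state=[0])


def gene_expression(k_r: float = 10.0, gamma_r: float = 1.0,
                    k_p: float = 2.0, gamma_p: float = 0.5) -> ReactionNetwork:
    """Constitutive transcription-translation: mRNA X1, protein X2 (output)."""
    reactions = [
        _rxn(2, {}, {0: 1}, MassAction(k_r), "transcription"),
        _rxn(2, {0: 1}, {}, MassAction(gamma_r), "mRNA decay"),
        Reaction((1, 0), MassAction(k_p), Fixed((0, 1)), name="translation"),
        _rxn(2, {1: 1}, {}, MassAction(gamma_p), "protein decay"),
    ]
    x1 = k_r / gamma_r
    x2 = k_p * x1 / gamma_p
    return ReactionNetwork(["mRNA", "protein"], reactions, "protein",
                           initial_state=[round(x1), round(x2)])


def rna_splicing(k_on: float = 1.0, k_off: float = 3.0, alpha_on: float = 6.0,
                 alpha_off: float = 0.4, beta: float = 1.0, gamma_u: float = 2.0,
                 gamma_r: float = 0.5) -> ReactionNetwork:
    """Telegraph gene G driving unspliced (U) -> spliced (R) mRNA; output R.

    Transcription rate alpha_off + (alpha_on - alpha_off) g is affine in the
    0/1 gene state, so the whole network is linear with a Hurwitz drift.
    """
    d = 3
    reactions = [
        Reaction((0,) * d, AffineClamped(k_on, (-k_on, 0.0, 0.0)), Fixed((1, 0, 0)), name="activate"),
        _rxn(d, {0: 1}, {}, MassAction(k_off), "deactivate"),
        Reaction((0,) * d, AffineClamped(alpha_off, (alpha_on - alpha_off, 0.0, 0.0)),
                 Fixed((0, 1, 0)), name="transcription"),
        _rxn(d, {1: 1}, {2: 1}, MassAction(beta), "splicing"),
        _rxn(d, {1: 1}, {}, MassAction(gamma_u), "unspliced decay"),
        _rxn(d, {2: 1}, {}, MassAction(gamma_r), "spliced decay"),
    ]
    g = k_on / (k_on + k_off)
    u = (alpha_off + (alpha_on - alpha_off) * g) / (beta + gamma_u)
    r = beta * u / gamma_r
    return ReactionNetwork(["gene", "unspliced", "spliced"], reactions, "spliced",
                           initial_state=[0, round(u), round(r)])


def iff(I_0: float = 10.0, k_c: float = 3.6, gamma_c: float = 1.0, k_o: float = 5.0,
        beta_0: float = 15.0, beta_ff: float = 0.5, gamma_o: float = 0.5) -> ReactionNetwork:
    """Incoherent feedforward: input (constant I_0) produces output O directly
    and represses it through the controller C.  Simulation uses the positive
    part of the linear feedforward function."""
    d = 2
    reactions = [
        _rxn(d, {}, {0: 1}, MassAction(k_c * I_0), "C production"),
        _rxn(d, {0: 1}, {}, MassAction(gamma_c), "C decay"),
        # total O production rate (k_o I_0 + F_f(x_c))_+, clamped as a whole
        Reaction((0, 0), AffineClamped(k_o * I_0 + beta_0, (-beta_ff, 0.0)), Fixed((0, 1)),
                 name="O production"),
        _rxn(d, {1: 1}, {}, MassAction(gamma_o), "O decay"),
    ]
    xc = k_c * I_0 / gamma_c
    xo = (k_o * I_0 + beta_0 - beta_ff * xc) / gamma_o
    return ReactionNetwork(["C", "O"], reactions, "O", initial_state=[round(xc), round(xo)])


def nfb(I_0: float = 10.0, beta_0: float = 5.0, beta_fb: float = 0.05, k_o: float = 2.0,
        gamma_c: float = 1.0, gamma_o: float = 0.5) -> ReactionNetwork:
    """Negative feedback: input produces controller C at rate I_0 (beta_0 -
    beta_fb x_o)_+, C catalyses output O, O represses C production."""
    d = 2
    reactions = [
        Reaction((0, 0), AffineClamped(I_0 * beta_0, (0.0, -I_0 * beta_fb)), Fixed((1, 0)),
                 name="C production (feedback)"),
        _rxn(d, {0: 1}, {}, MassAction(gamma_c), "C decay"),
        Reaction((1, 0), MassAction(k_o), Fixed((0, 1)), name="O production"),
        _rxn(d, {1: 1}, {}, MassAction(gamma_o), "O decay"),
    ]
    den = gamma_c * gamma_o + k_o * beta_fb * I_0
    xc = gamma_o * beta_0 * I_0 / den
    xo = k_o * beta_0 * I_0 / den
    return ReactionNetwork(["C", "O"], reactions, "O", initial_state=[round(xc), round(xo)])


def self_regulating_gene(K_0: float = 500.0, K_1: float = 10.0, H: float = 1.0,
                         gamma: float = 1.0) -> ReactionNetwork:
    """Birth-death with repressing-Hill production K_0/(K_1 + x^H) and linear
    degradation; the cooperativity H is the inference target."""
    if H <= 0:
        raise NetworkSpecError("Hill coefficient H must be > 0")
    reactions = [
        Reaction((0,), Hill(species=0, amplitude=K_0, K=K_1, H=H), Fixed((1,)),
                 name="autoregulated production"),
        _rxn(1, {0: 1}, {}, MassAction(gamma), "decay"),
    ]
    xbar = brentq(lambda x: K_0 / (K_1 + x**H) - gamma * x, 1e-6, K_0 / gamma + 1.0)
    return ReactionNetwork(["X"], reactions, "X", initial_state=[round(xbar)])


def repressilator(H: float = 2.0, sponge: bool = False, a_max: float = 160.0,
                  a_basal: float = 1.6, K_half: float = 12.0, k_p: float = 16.0,
                  gamma_m: float = 4.0, gamma_p: float = 2.0,
                  n_sponge: int = 60, k_bind: float = 8.0, k_unbind: float = 4.0
                  ) -> ReactionNetwork:
    """Three-gene ring oscillator; protein i represses transcription of gene
    i+1 through a Hill function with cooperativity H.  The optional sponge
    competitively sequesters protein 1 (TetR), raising the derepression
    threshold of gene 2 (cI, the output).

    Defaults are package-representative values placed in the oscillatory
    regime; the output is the cI protein count.
    """
    names = ["m1", "p1", "m2", "p2", "m3", "p3"]
    d = 6 + (2 if sponge else 0)
    if sponge:
        names += ["sponge", "complex"]

    def hill_prop(repressor_index):
        # a_basal + a_max / (1 + (p/K)^H), written over a common denominator
        return Hill(species=repressor_index, amplitude=a_max * K_half**H,
                    K=K_half**H, H=H, basal=a_basal)

    reactions = []
    repressors = [5, 1, 3]  # p3 -| gene1, p1 -| gene2, p2 -| gene3
    for g in range(3):
        m, p = 2 * g, 2 * g + 1
        reactions.append(Reaction((0,) * d, hill_prop(repressors[g]),
                                  Fixed(tuple(1 if j == m else 0 for j in range(d))),
                                  name=f"transcription {g+1}"))
        reactions.append(_rxn(d, {m: 1}, {}, MassAction(gamma_m), f"mRNA decay {g+1}"))
        reactions.append(Reaction(tuple(1 if j == m else 0 for j in range(d)), MassAction(k_p),
                                  Fixed(tuple(1 if j == p else 0 for j in range(d))),
                                  name=f"translation {g+1}"))
        reactions.append(_rxn(d, {p: 1}, {}, MassAction(gamma_p), f"protein decay {g+1}"))
    if sponge:
        reactions.append(_rxn(d, {1: 1, 6: 1}, {7: 1}, MassAction(k_bind), "sponge binding"))
        reactions.append(_rxn(d, {7: 1}, {1: 1, 6: 1}, MassAction(k_unbind), "sponge unbinding"))
    x0 = [2, 30, 8, 2, 2, 30] + ([n_sponge, 0] if sponge else [])
    return ReactionNetwork(names, reactions, "p2", initial_state=x0)


def aif_gene_expression(mu: float = 10.0, theta: float = 0.25, eta: float = 50.0,
                        k: float = 2.0, k_fb: float = 0.0, feedback: str = "none",
                        k_p: float = 1.0, gamma_r: float = 1.0, gamma_p: float = 1.0
                        ) -> ReactionNetwork:
    """Antithetic integral feedback controller closing the loop around the
    gene expression module; output protein X2 tracks the set-point mu/theta.

    The optional extra negative feedback (Hill: 4 k_fb mu_hat^2/(mu_hat + x2);
    proportional: k_fb (3 mu_hat - x2)_+) augments the actuation rate k z1
    and damps the single-cell oscillations the pure integral loop produces.
    Set-point tracking requires the feedback alone not to saturate the
    integral action, i.e. 2 k_fb k_p < gamma_r gamma_p; the defaults keep a
    factor-2 margin at k_fb = 0.25.
    """
    if feedback not in ("none", "hill", "proportional"):
        raise NetworkSpecError(f"unknown feedback type {feedback!r}")
    mu_hat = mu / theta
    d = 4  # Z1, Z2, X1 (mRNA), X2 (protein)
    reactions = [
        _rxn(d, {}, {0: 1}, MassAction(mu), "Z1 production"),
        _rxn(d, {0: 1, 1: 1}, {}, MassAction(eta), "annihilation"),
        Reaction((0, 0, 0, 1), MassAction(theta), Fixed((0, 1, 0, 0)), name="sensing"),
        Reaction((1, 0, 0, 0), MassAction(k), Fixed((0, 0, 1, 0)), name="actuation"),
        Reaction((0, 0, 1, 0), MassAction(k_p), Fixed((0, 0, 0, 1)), name="translation"),
        _rxn(d, {2: 1}, {}, MassAction(gamma_r), "mRNA decay"),
        _rxn(d, {3: 1}, {}, MassAction(gamma_p), "protein decay"),
    ]
    if feedback == "hill" and k_fb > 0:
        reactions.append(Reaction((0,) * d,
                                  Hill(species=3, amplitude=4 * k_fb * mu_hat**2, K=mu_hat, H=1.0),
                                  Fixed((0, 0, 1, 0)), name="hill feedback"))
    elif feedback == "proportional" and k_fb > 0:
        reactions.append(Reaction((0,) * d,
                                  AffineClamped(3 * k_fb * mu_hat, (0.0, 0.0, 0.0, -k_fb)),
                                  Fixed((0, 0, 1, 0)), name="proportional feedback"))
    x1 = gamma_p * mu_hat / k_p
    z1 = gamma_r * x1 / k
    return ReactionNetwork(["Z1", "Z2", "mRNA", "protein"], reactions, "protein",
                           initial_state=[max(1, round(z1)), 1, round(x1), round(mu_hat)])


def cell_cycle_host(N: int = 4, alpha: float = 1.0, partition: str = "binomial",
                    inner: ReactionNetwork | None = None) -> ReactionNetwork:
    """A dividing cell hosting ``inner`` (default: the gene expression module).

    The cell-cycle is an N-stage clock advancing at rate alpha; completing
    the cycle divides the cell and partitions every inner species between the
    daughters (symmetric binomial or strict binary), tracking one daughter.
    Expected cycle duration: N/alpha.
    """
    if N < 2:
        raise NetworkSpecError("need N >= 2 cell-cycle stages")
    if partition not in ("binomial", "strict_binary"):
        raise NetworkSpecError(f"unknown partition mechanism {partition!r}")
    inner = inner if inner is not None else gene_expression()
    d0 = inner.d
    d = d0 + 1
    stage = d0
    reactions = []
    for r in inner.reactions:
        nu = tuple(r.reactant_counts) + (0,)
        disp = r.displacement
        if isinstance(disp, Fixed):
            disp = Fixed(tuple(disp.zeta) + (0,))
        else:
            raise NetworkSpecError("inner network must have fixed displacements")
        prop = r.propensity
        if isinstance(prop, AffineClamped):
            prop = AffineClamped(prop.intercept, tuple(prop.coeffs) + (0.0,))
        reactions.append(Reaction(nu, prop, disp, name=r.name))
    part_cls = BinomialPartition if partition == "binomial" else StrictBinaryPartition
    kernel = CellDivision(stage_index=stage, n_stages=N, partition=part_cls(range(d0)))
    reactions.append(Reaction((0,) * d, MassAction(alpha), kernel, name="cycle advance"))
    x0 = list(inner.default_initial_state()) + [0]
    return ReactionNetwork(inner.species_names + ["cycle_stage"], reactions,
                           inner.output_species, initial_state=x0,
                           metadata={"cycle_reaction": len(reactions) - 1,
                                     "n_stages": N, "alpha": alpha})


def entrainment_circuit(k_r: float = 50.0, k_fb: float = 0.5, k_p: float = 2.0,
                        gamma_r: float = 1.0, gamma_p: float = 0.5,
                        theta: float = 0.0, upstream_mean: float = 0.0) -> ReactionNetwork:
    """Gene expression with linearised transcriptional feedback
    F_b(x2) = k_r - k_fb x2, optionally driven by an upstream activator with
    stationary mean ``upstream_mean`` at coupling strength ``theta`` (the
    upstream signal frozen at its mean; use linear.composite_psd for the
    full driven spectrum)."""
    d = 2
    basal = theta * upstream_mean + k_r
    reactions = [
        Reaction((0, 0), AffineClamped(basal, (0.0, -k_fb)), Fixed((1, 0)), name="transcription"),
        _rxn(d, {0: 1}, {}, MassAction(gamma_r), "mRNA decay"),
        Reaction((1, 0), MassAction(k_p), Fixed((0, 1)), name="translation"),
        _rxn(d, {1: 1}, {}, MassAction(gamma_p), "protein decay"),
    ]
    den = gamma_r * gamma_p + k_p * k_fb
    x1 = gamma_p * basal / den
    x2 = k_p * basal / den
    return ReactionNetwork(["mRNA", "protein"], reactions, "protein",
                           initial_state=[round(x1), round(x2)])


def known_factor_for_cell_cycle(N: int, alpha: float):
    """Quadratic denominator factor B(s) = |sigma|^2 - 2 Re(sigma) s + s^2
    contributed by the slowest oscillatory eigenvalue
    sigma = -alpha (1 - exp(2 pi i / N)) of the cell-cycle clock."""
    if N < 2:
        raise PadePSDError("need N >= 2")
    if alpha <= 0:
        raise PadePSDError("alpha must be > 0")
    sigma = -alpha * (1.0 - np.exp(2j * np.pi / N))
    return (float(abs(sigma) ** 2), float(-2.0 * sigma.real))


def synthetic_experiment_traces(network: ReactionNetwork, Q: int, dt: float,
                                proportionality: float, seed: int,
                                T_f: float = 1000.0, T_c: float = 50.0) -> np.ndarray:
    """Emulated time-lapse microscopy traces: the output copy-number sampled
    at step dt and scaled by an (in practice unknown) proportionality
    constant c > 0.  Normalised PSDs are invariant to c, which is what makes
    PSD-based inference possible without calibrating the reporter."""
    if proportionality <= 0:
        raise PadePSDError("proportionality constant must be > 0")
    if Q < 1:
        raise PadePSDError("need at least one trace")
    cfg = EnsembleConfig(Q=Q, T_f=T_f, T_c=T_c, base_seed=seed)
    result = run_ensemble(network, cfg, sample_dt=dt, n_batches=1)
    return proportionality * result.samples


CATALOG = {
    "birth_death": birth_death,
    "telegraph": telegraph,
    "gene_expression": gene_expression,
    "rna_splicing": rna_splicing,
    "iff": iff,
    "nfb": nfb,
    "self_regulating_gene": self_regulating_gene,
    "repressilator": repressilator,
    "aif_gene_expression": aif_gene_expression,
    "cell_cycle_host": cell_cycle_host,
    "entrainment_circuit": entrainment_circuit,
}


def make(name: str, **params) -> ReactionNetwork:
    """Construct a catalogued network by name with keyword overrides."""
    if name not in CATALOG:
        raise NetworkSpecError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(CATALOG))}"
        )
    return CATALOG[name](**params)
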