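"""End-to-end estimation pipeline: augment, simulate, estimate derivatives,
solve the Pade system, validate.

This is the function the CLI wraps and the one to call from scripts:

    result = pade_psd(fixtures.gene_expression(), p=2, s_points=(np.inf,),
                      rho=(4,), Q=10, T_f=1e4, T_c=1e2, seed=7)
    omega = np.linspace(0, 5, 200)
    curve = result.rational.psd(omega)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmentation import augment
from .engine import EnsembleResult, run_ensemble
from .errors import PadePSDError
from .estimators import PadeDerivativeSet, estimate_derivatives
from .network import ReactionNetwork
from .pade import RationalPSD, ValidationReport, solve_pade, validate
from .ssa import EnsembleConfig

__all__ = ["PadePSDResult", "pade_psd"]


@dataclass
class PadePSDResult:
    rational: RationalPSD
    derivatives: PadeDerivativeSet
    validation: ValidationReport | None
    ensemble: EnsembleResult
    config: dict

    def as_dict(self) -> dict:
        num_u, den_u = self.rational.psd_rational()
        return {
            "config": self.config,
            "G_numerator": list(self.rational.numerator),
            "G_denominator": list(self.rational.denominator),
            "psd_numerator_u": list(num_u),
            "psd_denominator_u": list(den_u),
            "stable": self.rational.stable,
            "variance": self.derivatives.variance,
            "variance_se": self.derivatives.variance_se,
            "mean": self.derivatives.mean,
            "mean_se": self.derivatives.mean_se,
            "derivatives": [
                {
                    "s": ("inf" if np.isinf(e.s) else e.s),
                    "method": e.method,
                    "values": list(e.values),
                    "standard_errors": list(e.standard_errors),
                }
                for e in self.derivatives.estimates
            ],
            "validation": self.validation.as_dict() if self.validation else None,
        }


def pade_psd(
    network: ReactionNetwork,
    p: int = 2,
    s_points=(np.inf,),
    rho=(4,),
    test_points=(0.5, 1.0, 2.0),
    Q: int = 10,
    T_f: float = 1e4,
    T_c: float = 1e2,
    seed: int = 0,
    known_factor=None,
    infinity_method: str = "covariate",
    initial_state=None,
    validation_threshold: float = 0.1,
    force_python: bool = False,
) -> PadePSDResult:
    """Estimate the output PSD of ``network`` by the multipoint rational
    approximation of the resolvent transform.

    ``s_points``/``rho`` give the interpolation points (``numpy.inf``
    allowed, conventionally last) and how many series terms to match at
    each; ``p`` is the order of the rational approximant; ``test_points``
    are held-out values of s at which the approximant is compared against
    direct register estimates of G(s).
    """
    s_points = tuple(float(s) for s in s_points)
    rho = tuple(int(r) for r in rho)
    if len(s_points) != len(rho):
        raise PadePSDError("s_points and rho must have equal length")
    finite = [(s, r) for s, r in zip(s_points, rho) if np.isfinite(s)]
    n_inf = sum(1 for s in s_points if np.isinf(s))
    if n_inf > 1:
        raise PadePSDError("at most one interpolation point at infinity")

    aug = augment(
        network,
        s_points=[s for s, _ in finite],
        rho=[r for _, r in finite],
        test_points=test_points,
    )
    cfg = EnsembleConfig(Q=Q, T_f=T_f, T_c=T_c, base_seed=seed)
    x0 = None
    if initial_state is not None:
        x0 = np.asarray(initial_state, dtype=np.int64)
        xn0 = x0[network.output_index]
        x0 = np.concatenate([x0, np.full(aug.d - network.d, xn0, dtype=np.int64)])
    result = run_ensemble(
        aug, cfg,
        collect_occupancy=(n_inf > 0 and infinity_method in ("covariate", "naive")),
        initial_state=x0,
        force_python=force_python,
    )
    derivs = estimate_derivatives(result, s_points, rho, infinity_method=infinity_method)
    rational = solve_pade(derivs.by_point(), p=p, known_factor=known_factor)
    report = validate(rational, derivs.direct, threshold=validation_threshold) if derivs.direct else None
    config = {
        "p": p,
        "s_points": ["inf" if np.isinf(s) else s for s in s_points],
        "rho": list(rho),
        "test_points": list(test_points),
        "Q": Q, "T_f": T_f, "T_c": T_c, "seed": seed,
        "known_factor": (list(known_factor) if known_factor is not None else None),
        "infinity_method": infinity_method,
    }
    return PadePSDResult(rational=rational, derivatives=derivs, validation=report,
                         ensemble=result, config=config)
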