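"""Network configuration files (YAML/JSON) and the propensity expression
language.

Schema::

    species: [mRNA, protein]
    output: protein
    initial_state: [10, 40]        # optional
    reactions:
      - name: transcription
        reactants: {}
        products: {mRNA: 1}
        rate: 10.0                 # mass action
      - name: feedback
        propensity: "max(50 - 0.5*protein, 0)"
        changes: {mRNA: 1}         # net displacement
      - name: division
        displacement:
          kind: cell_division
          stage: cycle_stage
          n_stages: 4
          partition: binomial
          species: [mRNA, protein]
        rate: 1.0

Expressions support arithmetic on species names, ``max(a, b)`` and
``hill(x; K0, K1, H)`` (= K0/(K1 + x^H)).  Affine and Hill-shaped
expressions are recognised and stored in parametric form (so they compile
into the fast engine); anything else becomes a callable propensity handled
by the reference simulator.
"""

from __future__ import annotations

import re

import numpy as np
import sympy as sp
import yaml

from .errors import NetworkSpecError
from .network import (
    AffineClamped,
    BinomialPartition,
    CellDivision,
    CustomPropensity,
    Fixed,
    Hill,
    JumpKernel,
    MassAction,
    Reaction,
    ReactionNetwork,
    StrictBinaryPartition,
)

__all__ = ["parse_propensity", "propensity_expression", "to_dict", "from_dict",
           "save_network", "load_network"]

_HILL_RE = re.compile(r"hill\(\s*([A-Za-z_]\w*)\s*;([^;)]*),([^;)]*),([^;)]*)\)")


def parse_propensity(expression: str, species_names: list[str]):
    """Parse an expression into the most specific propensity object."""
    expr_text = _HILL_RE.sub(r"((\2)/((\3) + (\1)**(\4)))", expression)
    symbols = {name: sp.Symbol(name, nonnegative=True) for name in species_names}
    local = dict(symbols)
    local["max"] = sp.Max
    local["Max"] = sp.Max
    try:
        expr = sp.sympify(expr_text, locals=local)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise NetworkSpecError(f"cannot parse propensity {expression!r}: {exc}") from exc
    free = expr.free_symbols - set(symbols.values())
    if free:
        raise NetworkSpecError(f"unknown names in propensity {expression!r}: {free}")

    syms = [symbols[n] for n in species_names]

    def affine_parts(e):
        e = sp.expand(e)
        try:
            poly = sp.Poly(e, *syms)
        except sp.PolynomialError:
            return None
        if poly.total_degree() > 1:
            return None
        intercept = float(poly.coeff_monomial(1))
        coeffs = tuple(float(poly.coeff_monomial(s)) for s in syms)
        return intercept, coeffs

    # max(affine, 0) -> clamped affine
    if isinstance(expr, sp.Max) and len(expr.args) == 2 and sp.S.Zero in expr.args:
        other = [a for a in expr.args if a is not sp.S.Zero][0]
        parts = affine_parts(other)
        if parts is not None:
            return AffineClamped(parts[0], parts[1])
    parts = affine_parts(expr)
    if parts is not None:
        intercept, coeffs = parts
        if all(c == 0 for c in coeffs) and intercept >= 0:
            return MassAction(intercept) if intercept > 0 else AffineClamped(0.0, coeffs)
        return AffineClamped(intercept, coeffs)
    # basal + amplitude/(K + x**H)
    x = sp.Wild("x")
    amp = sp.Wild("amp", exclude=list(syms))
    Kc = sp.Wild("Kc", exclude=list(syms))
    H = sp.Wild("H", exclude=list(syms))
    basal = sp.Wild("basal", exclude=list(syms))
    m = expr.match(basal + amp / (Kc + x**H))
    if m and m[x] in syms and m[H].is_number and m[Kc].is_number and m[amp].is_number:
        return Hill(
            species=syms.index(m[x]),
            amplitude=float(m[amp]),
            K=float(m[Kc]),
            H=float(m[H]),
            basal=float(m[basal]),
        )
    fn = sp.lambdify(syms, expr, modules="numpy")
    return CustomPropensity(fn=lambda state, _f=fn: float(_f(*state)), expression=expression)


def propensity_expression(prop, species_names: list[str]) -> str:
    """Canonical expression string for a parametric propensity."""
    if isinstance(prop, AffineClamped):
        terms = [repr(prop.intercept)]
        for c, name in zip(prop.coeffs, species_names):
            if c:
                terms.append(f"{c!r}*{name}")
        return f"max({' + '.join(terms)}, 0)"
    if isinstance(prop, Hill):
        name = species_names[prop.species]
        base = f"{prop.amplitude!r}/({prop.K!r} + {name}**{prop.H!r})"
        return f"{prop.basal!r} + {base}" if prop.basal else base
    if isinstance(prop, CustomPropensity):
        if prop.expression is None:
            raise NetworkSpecError("cannot serialise a callable propensity without its expression")
        return prop.expression
    raise NetworkSpecError(f"no expression form for {type(prop).__name__}")


def _kernel_to_dict(kernel: JumpKernel, names: list[str]) -> dict:
    if isinstance(kernel, CellDivision):
        return {
            "kind": "cell_division",
            "stage": names[kernel.stage_index],
            "n_stages": kernel.n_stages,
            "partition": ("strict_binary"
                          if isinstance(kernel.partition, StrictBinaryPartition) else "binomial"),
            "species": [names[j] for j in kernel.partition.species],
        }
    if isinstance(kernel, (BinomialPartition, StrictBinaryPartition)):
        return {
            "kind": kernel.kind,
            "species": [names[j] for j in kernel.species],
        }
    raise NetworkSpecError(f"cannot serialise kernel {type(kernel).__name__}")


def _kernel_from_dict(spec: dict, names: list[str]) -> JumpKernel:
    kind = spec.get("kind")
    idx = [names.index(s) for s in spec.get("species", [])]
    if kind == "binomial_partition":
        return BinomialPartition(idx)
    if kind == "strict_binary_partition":
        return StrictBinaryPartition(idx)
    if kind == "cell_division":
        part = (StrictBinaryPartition(idx) if spec.get("partition") == "strict_binary"
                else BinomialPartition(idx))
        return CellDivision(names.index(spec["stage"]), int(spec["n_stages"]), part)
    raise NetworkSpecError(f"unknown kernel kind {kind!r}")


def to_dict(network: ReactionNetwork) -> dict:
    names = network.species_names
    reactions = []
    for r in network.reactions:
        entry: dict = {"name": r.name}
        disp = r.displacement
        if isinstance(r.propensity, MassAction) and isinstance(disp, Fixed):
            entry["reactants"] = {names[j]: int(c) for j, c in enumerate(r.reactant_counts) if c}
            products = {}
            for j, (z, nu) in enumerate(zip(disp.zeta, r.reactant_counts)):
                tot = int(z) + int(nu)
                if tot:
                    products[names[j]] = tot
            entry["products"] = products
            entry["rate"] = float(r.propensity.rate_constant)
        elif isinstance(disp, Fixed):
            entry["propensity"] = propensity_expression(r.propensity, names)
            entry["changes"] = {names[j]: int(z) for j, z in enumerate(disp.zeta) if z}
        elif isinstance(disp, JumpKernel):
            entry["displacement"] = _kernel_to_dict(disp, names)
            if isinstance(r.propensity, MassAction):
                entry["rate"] = float(r.propensity.rate_constant)
                entry["reactants"] = {names[j]: int(c) for j, c in enumerate(r.reactant_counts) if c}
            else:
                entry["propensity"] = propensity_expression(r.propensity, names)
        else:
            raise NetworkSpecError("register-reset reactions are internal and not serialisable")
        reactions.append(entry)
    out = {"species": list(names), "output": network.output_species, "reactions": reactions}
    if network.initial_state is not None:
        out["initial_state"] = [int(v) for v in network.initial_state]
    return out


def from_dict(spec: dict) -> ReactionNetwork:
    try:
        names = list(spec["species"])
        output = spec["output"]
        rxn_specs = spec["reactions"]
    except KeyError as exc:
        raise NetworkSpecError(f"missing config field: {exc}") from exc
    d = len(names)
    reactions = []
    for i, r in enumerate(rxn_specs):
        name = r.get("name", f"reaction {i+1}")
        try:
            if "displacement" in r:
                kernel = _kernel_from_dict(r["displacement"], names)
                if "rate" in r:
                    nu = [0] * d
                    for sname, c in (r.get("reactants") or {}).items():
                        nu[names.index(sname)] = int(c)
                    prop = MassAction(float(r["rate"]))
                    reactions.append(Reaction(tuple(nu), prop, kernel, name=name))
                else:
                    prop = parse_propensity(r["propensity"], names)
                    reactions.append(Reaction((0,) * d, prop, kernel, name=name))
            elif "rate" in r:
                reactants = {names.index(s): int(c) for s, c in (r.get("reactants") or {}).items()}
                products = {names.index(s): int(c) for s, c in (r.get("products") or {}).items()}
                reactions.append(
                    Reaction.from_counts(d, reactants, products, MassAction(float(r["rate"])), name)
                )
            elif "propensity" in r:
                prop = parse_propensity(r["propensity"], names)
                zeta = [0] * d
                for sname, c in (r.get("changes") or {}).items():
                    zeta[names.index(sname)] = int(c)
                reactions.append(Reaction((0,) * d, prop, Fixed(tuple(zeta)), name=name))
            else:
                raise NetworkSpecError(f"reaction {name!r}: need 'rate' or 'propensity'")
        except ValueError as exc:
            raise NetworkSpecError(f"reaction {name!r}: {exc}") from exc
    x0 = spec.get("initial_state")
    return ReactionNetwork(names, reactions, output,
                           initial_state=np.asarray(x0, dtype=np.int64) if x0 is not None else None)


def save_network(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(network), fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
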