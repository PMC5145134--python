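"""Domain types for reaction-network models and the propensity machinery
shared by every solver.

A :class:`ReactionNetworkModel` is either *concentration* based (molar initial
values, deterministic rate constants) or *population* based (integer copy
numbers, stochastic rate constants).  Reactions are irreversible channels;
reversible reactions are stored as two channels.  Mass-action channels carry a
rate parameter; anything else carries a custom propensity expression.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .expressions import ExpressionError, PropensityExpression, parse_expression

__all__ = [
    "Species",
    "Parameter",
    "Reaction",
    "ReactionNetworkModel",
    "ValidationIssue",
    "validate_model",
    "mass_action_propensity",
    "build_stoichiometry",
]

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

#: 2019 SI exact value of the Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

MASS_ACTION = "mass_action"
CUSTOM = "custom"

#: Recognised unit tags for parameters.  Tags are carried for conversion of
#: mass-action constants but are not dimension-checked across expressions.
UNIT_TAGS = ("s^-1", "M^-1*s^-1", "M*s^-1", "dimensionless")


@dataclass
class Species:
    """A chemical species.

    ``initial_value`` is a molar concentration in concentration mode and an
    integer copy number in population mode.  ``diffusion_coefficient`` (m^2/s)
    and ``allowed_subdomains`` only matter for spatial models; an empty
    subdomain set means the species may occupy the whole domain.
    """

    name: str
    initial_value: float = 0.0
    diffusion_coefficient: float = 0.0
    allowed_subdomains: frozenset = frozenset()

    def __post_init__(self):
        self.allowed_subdomains = frozenset(self.allowed_subdomains)


@dataclass
class Parameter:
    name: str
    value: float
    unit: str = "dimensionless"


@dataclass
class Reaction:
    """One irreversible reaction channel.

    ``reactants`` and ``products`` map species names to positive integer
    stoichiometries.  Kinetics are either mass action (``rate_parameter``
    names a model parameter; total reactant order at most 2) or a custom
    propensity expression in the model's units.  ``restrict_to`` limits the
    channel to mesh subdomains in spatial models (empty = everywhere).
    """

    name: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    kinetics: str = MASS_ACTION
    rate_parameter: str | None = None
    propensity: str | PropensityExpression | None = None
    restrict_to: frozenset = frozenset()

    def __post_init__(self):
        self.restrict_to = frozenset(self.restrict_to)
        if self.kinetics == CUSTOM and isinstance(self.propensity, str):
            self.propensity = parse_expression(self.propensity)

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    def net_change(self) -> dict:
        net = dict(self.products)
        for name, stoich in self.reactants.items():
            net[name] = net.get(name, 0) - stoich
        return {k: v for k, v in net.items() if v != 0}


@dataclass
class ReactionNetworkModel:
    name: str
    units_mode: str = "population"  # "concentration" | "population"
    volume: float | None = None  # litres; required for population conversion
    species: list = field(default_factory=list)
    parameters: list = field(default_factory=list)
    reactions: list = field(default_factory=list)

    # -- lookup helpers ----------------------------------------------------
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def get_parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def parameter_values(self) -> dict:
        return {p.name: p.value for p in self.parameters}

    def initial_state(self) -> np.ndarray:
        values = np.array([s.initial_value for s in self.species], dtype=float)
        if self.units_mode == "population":
            return values.astype(np.int64)
        return values

    def rate_constant(self, reaction: Reaction) -> float:
        if reaction.kinetics != MASS_ACTION:
            raise ValueError(f"reaction {reaction.name!r} is not mass action")
        return self.get_parameter(reaction.rate_parameter).value


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    location: str  # e.g. "species:P", "reaction:binding"


def _check_identifier(name, kind, issues):
    if not IDENTIFIER_RE.match(name or ""):
        issues.append(
            ValidationIssue("error", f"invalid identifier {name!r}", f"{kind}:{name}")
        )


def validate_model(model: ReactionNetworkModel) -> list:
    """Check every model invariant; returns a deterministic, location-ordered
    list of issues (empty iff the model is valid).  Problems are reported, not
    raised."""
    issues: list[ValidationIssue] = []

    if model.units_mode not in ("concentration", "population"):
        issues.append(
            ValidationIssue("error", f"unknown units_mode {model.units_mode!r}", "model")
        )
    if model.volume is not None and not (model.volume > 0):
        issues.append(ValidationIssue("error", "volume must be positive", "model"))

    seen = set()
    for s in model.species:
        loc = f"species:{s.name}"
        _check_identifier(s.name, "species", issues)
        if s.name in seen:
            issues.append(ValidationIssue("error", f"duplicate species {s.name!r}", loc))
        seen.add(s.name)
        if not (s.initial_value >= 0):
            issues.append(ValidationIssue("error", "initial value must be nonnegative", loc))
        elif model.units_mode == "population" and s.initial_value != int(s.initial_value):
            issues.append(
                ValidationIssue(
                    "error",
                    f"population-mode initial value {s.initial_value} is not an integer",
                    loc,
                )
            )
        if s.diffusion_coefficient < 0:
            issues.append(
                ValidationIssue("error", "diffusion coefficient must be nonnegative", loc)
            )

    param_seen = set()
    for p in model.parameters:
        loc = f"parameter:{p.name}"
        _check_identifier(p.name, "parameter", issues)
        if p.name in param_seen:
            issues.append(ValidationIssue("error", f"duplicate parameter {p.name!r}", loc))
        param_seen.add(p.name)
        if not math.isfinite(p.value):
            issues.append(ValidationIssue("error", f"parameter value {p.value} not finite", loc))

    species_names = {s.name for s in model.species}
    param_names = {p.name for p in model.parameters}
    rxn_seen = set()
    for r in model.reactions:
        loc = f"reaction:{r.name}"
        _check_identifier(r.name, "reaction", issues)
        if r.name in rxn_seen:
            issues.append(ValidationIssue("error", f"duplicate reaction {r.name!r}", loc))
        rxn_seen.add(r.name)
        for role, stoich_map in (("reactant", r.reactants), ("product", r.products)):
            for name, stoich in stoich_map.items():
                if name not in species_names:
                    issues.append(
                        ValidationIssue("error", f"undeclared {role} species {name!r}", loc)
                    )
                if not (isinstance(stoich, (int, np.integer)) and stoich > 0):
                    issues.append(
                        ValidationIssue(
                            "error", f"{role} stoichiometry for {name!r} must be a positive integer", loc
                        )
                    )
        if r.kinetics == MASS_ACTION:
            if r.order > 2:
                issues.append(
                    ValidationIssue(
                        "error",
                        f"mass-action reaction of order {r.order} (maximum 2)",
                        loc,
                    )
                )
            if r.rate_parameter not in param_names:
                issues.append(
                    ValidationIssue(
                        "error", f"undeclared rate parameter {r.rate_parameter!r}", loc
                    )
                )
        elif r.kinetics == CUSTOM:
            expr = r.propensity
            if not isinstance(expr, PropensityExpression):
                try:
                    expr = parse_expression(str(expr))
                except ExpressionError as exc:
                    issues.append(ValidationIssue("error", str(exc), loc))
                    expr = None
            if expr is not None:
                unknown = expr.identifiers - species_names - param_names
                for name in sorted(unknown):
                    issues.append(
                        ValidationIssue("error", f"unknown identifier {name!r} in propensity", loc)
                    )
        else:
            issues.append(ValidationIssue("error", f"unknown kinetics {r.kinetics!r}", loc))

    issues.sort(key=lambda i: (i.location, i.message))
    return issues


def mass_action_propensity(reaction: Reaction, state, stochastic_rate: float) -> float:
    """Standard discrete mass-action propensity at a copy-number state.

    ``state`` maps species name -> copy number (or is a sequence paired with
    the reaction's reactant names via a dict).  Zeroth order -> c;
    A -> c*x_A; A+B -> c*x_A*x_B; 2A -> c*x_A*(x_A-1)/2.
    """
    if stochastic_rate < 0:
        raise ValueError("stochastic rate constant must be nonnegative")
    if reaction.order > 2:
        raise ValueError(
            f"mass-action propensity undefined for order {reaction.order} (reaction {reaction.name!r})"
        )
    a = float(stochastic_rate)
    for name, stoich in reaction.reactants.items():
        x = float(state[name])
        if stoich == 1:
            a *= x
        else:  # stoich == 2 (dimerization)
            a *= x * (x - 1.0) / 2.0
    return max(a, 0.0)


def build_stoichiometry(model: ReactionNetworkModel):
    """Net-change matrix and reaction dependency graph.

    Returns ``(S, depends)`` where ``S`` is the (n_reactions, n_species)
    integer net-change matrix (products minus reactants) and ``depends`` maps
    each reaction index ``r`` to the sorted list of reaction indices whose
    propensity may change when ``r`` fires (species shared between r's net
    change and the other reaction's reactants or custom expression).
    """
    names = model.species_names()
    index = {n: i for i, n in enumerate(names)}
    n_r, n_s = len(model.reactions), len(names)
    S = np.zeros((n_r, n_s), dtype=np.int64)
    for j, r in enumerate(model.reactions):
        for name, stoich in r.reactants.items():
            S[j, index[name]] -= stoich
        for name, stoich in r.products.items():
            S[j, index[name]] += stoich

    # species each reaction's propensity reads
    reads = []
    species_set = set(names)
    for r in model.reactions:
        if r.kinetics == MASS_ACTION:
            reads.append(set(r.reactants))
        else:
            expr = r.propensity
            if not isinstance(expr, PropensityExpression):
                expr = parse_expression(str(expr))
            reads.append(expr.identifiers & species_set)

    depends = {}
    for j in range(n_r):
        changed = {names[i] for i in np.nonzero(S[j])[0]}
        depends[j] = sorted(k for k in range(n_r) if changed & reads[k])
    return S, depends
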