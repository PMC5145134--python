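"""Model-level conversions between the three modelling levels, plus the
rate-constant unit helpers used to parametrize models from measured
quantities (half-lives, per-minute rates).

Concentration -> population conversion follows the standard mass-action
rules with N_A the 2019 SI exact Avogadro constant and system volume V in
litres:

========================  =========================  =====================
reaction order            deterministic constant     stochastic constant
========================  =========================  =====================
zeroth (M s^-1)           k                          k * N_A * V
first (s^-1)              k                          k (unchanged)
bimolecular A+B (1/M/s)   k                          k / (N_A V)
dimerization 2A (1/M/s)   k                          2 k / (N_A V)
========================  =========================  =====================

Species counts are round-half-to-even of c * N_A * V.  Custom-propensity
reactions cannot be converted automatically and are reported as needing user
input, with the expression left untouched.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

from .model import AVOGADRO, CUSTOM, MASS_ACTION, ReactionNetworkModel

__all__ = [
    "ConversionReport",
    "halflife_to_rate_constant",
    "per_minute_to_per_second",
    "concentration_to_population",
    "wellmixed_to_spatial",
]


@dataclass
class ParameterConversion:
    name: str
    old_value: float
    old_unit: str
    new_value: float
    new_unit: str
    rule: str


@dataclass
class ConversionReport:
    model: ReactionNetworkModel
    parameter_conversions: list = field(default_factory=list)
    needs_user_input: list = field(default_factory=list)  # custom-propensity reactions

    def as_text(self) -> str:
        lines = [f"conversion report for model {self.model.name!r}"]
        for pc in self.parameter_conversions:
            lines.append(
                f"  parameter {pc.name}: {pc.old_value!r} {pc.old_unit} -> "
                f"{pc.new_value!r} {pc.new_unit} ({pc.rule})"
            )
        for item in self.needs_user_input:
            lines.append(f"  NEEDS USER INPUT: {item}")
        return "\n".join(lines) + "\n"


def halflife_to_rate_constant(half_life: float) -> float:
    """First-order decay constant ln(2)/t_half (both in seconds)."""
    if not half_life > 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / half_life


def per_minute_to_per_second(rate: float) -> float:
    if not math.isfinite(rate):
        raise ValueError("rate must be finite")
    return rate / 60.0


def _conversion_rule(reaction):
    """(factor exponent on N_A*V, rule label) for a mass-action reaction."""
    order = reaction.order
    if order == 0:
        return lambda k, nav: k * nav, "zeroth order: k * N_A * V", "s^-1"
    if order == 1:
        return lambda k, nav: k, "first order: unchanged", "s^-1"
    # order 2: dimerization if a single reactant with stoichiometry 2
    if len(reaction.reactants) == 1 and next(iter(reaction.reactants.values())) == 2:
        return lambda k, nav: 2.0 * k / nav, "dimerization 2A: 2k / (N_A V)", "s^-1"
    return lambda k, nav: k / nav, "bimolecular A+B: k / (N_A V)", "s^-1"


def concentration_to_population(
    model: ReactionNetworkModel, volume: float
) -> ConversionReport:
    """Convert a concentration-based model to a population-based one.

    Species counts become round-half-to-even of c*N_A*V; mass-action rate
    constants are rescaled per reaction order.  A parameter shared by
    reactions of conflicting conversion rules is an error (it would need two
    different stochastic values).
    """
    if model.units_mode != "concentration":
        raise ValueError("model is not in concentration mode")
    if not volume > 0:
        raise ValueError("volume must be positive")
    nav = AVOGADRO * volume

    converted = copy.deepcopy(model)
    converted.units_mode = "population"
    converted.volume = volume

    for s in converted.species:
        # round-half-to-even, deterministic and unbiased
        s.initial_value = float(round(s.initial_value * nav))

    rules = {}  # parameter name -> (fn, label)
    report = ConversionReport(model=converted)
    for r in converted.reactions:
        if r.kinetics == CUSTOM:
            report.needs_user_input.append(
                f"reaction {r.name!r} has a custom propensity "
                f"({r.propensity.text!r}); convert it manually"
            )
            continue
        fn, label, unit = _conversion_rule(r)
        if r.rate_parameter in rules and rules[r.rate_parameter][1] != label:
            raise ValueError(
                f"parameter {r.rate_parameter!r} is shared by reactions with "
                "conflicting conversion rules"
            )
        rules[r.rate_parameter] = (fn, label, unit)

    for p in converted.parameters:
        if p.name in rules:
            fn, label, unit = rules[p.name]
            new_value = fn(p.value, nav)
            report.parameter_conversions.append(
                ParameterConversion(p.name, p.value, p.unit, new_value, unit, label)
            )
            p.value = new_value
            p.unit = unit
    return report


def population_to_concentration(
    model: ReactionNetworkModel, volume: float | None = None
) -> ConversionReport:
    """Inverse of :func:`concentration_to_population` (exact on rates; counts
    map to c = x/(N_A V), so the round trip is identity up to count rounding)."""
    if model.units_mode != "population":
        raise ValueError("model is not in population mode")
    volume = volume if volume is not None else model.volume
    if volume is None or not volume > 0:
        raise ValueError("a positive volume is required")
    nav = AVOGADRO * volume

    converted = copy.deepcopy(model)
    converted.units_mode = "concentration"
    converted.volume = volume
    for s in converted.species:
        s.initial_value = s.initial_value / nav

    inverse = {
        "zeroth order: k * N_A * V": (lambda c: c / nav, "M*s^-1"),
        "first order: unchanged": (lambda c: c, "s^-1"),
        "dimerization 2A: 2k / (N_A V)": (lambda c: c * nav / 2.0, "M^-1*s^-1"),
        "bimolecular A+B: k / (N_A V)": (lambda c: c * nav, "M^-1*s^-1"),
    }
    report = ConversionReport(model=converted)
    rules = {}
    for r in converted.reactions:
        if r.kinetics == CUSTOM:
            report.needs_user_input.append(
                f"reaction {r.name!r} has a custom propensity "
                f"({r.propensity.text!r}); convert it manually"
            )
            continue
        _, label, _ = _conversion_rule(r)
        rules[r.rate_parameter] = label
    for p in converted.parameters:
        if p.name in rules:
            fn, unit = inverse[rules[p.name]]
            new_value = fn(p.value)
            report.parameter_conversions.append(
                ParameterConversion(p.name, p.value, p.unit, new_value, unit, f"inverse of {rules[p.name]}")
            )
            p.value = new_value
            p.unit = unit
    return report


def wellmixed_to_spatial(model, mesh, placements, diffusion, restrict_to_voxels=None, seed=0):
    """Distribute a population-mode model onto a mesh (see
    :func:`stochcell.spatial.build_spatial_model`); total initial copy numbers
    are conserved exactly by placement, and bimolecular constants are
    rescaled per voxel volume inside the solver."""
    from .spatial import build_spatial_model

    return build_spatial_model(
        model, mesh, placements, diffusion, restrict_to_voxels=restrict_to_voxels, seed=seed
    )
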