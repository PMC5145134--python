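"""Exact and approximate discrete stochastic simulation of well-mixed models.

``simulate_ssa`` implements the Gillespie direct method (exponential waiting
time with rate a0, then cumulative-sum channel inversion) and the optimized
direct method (ODM), which uses the reaction dependency graph to recompute
only the propensities a fired channel can have changed; both sample the same
distribution.  ``simulate_tau_leap`` is an adaptive, non-negativity
preserving explicit tau-leaping scheme: candidate steps bound the expected
relative propensity change by ``epsilon``, channels within ``n_c`` firings of
exhausting a reactant are partitioned off as *critical* and fired exactly,
and whenever the selected step is smaller than ``fallback_multiple / a0`` the
solver falls back to a burst of exact SSA steps.

Output recording holds the state piecewise-constant between events
(right-continuous step function): the value at an output time is the state
after the last event at or before it.
"""

from __future__ import annotations

import math

import numpy as np

from .expressions import PropensityExpression
from .model import CUSTOM, MASS_ACTION, ReactionNetworkModel, build_stoichiometry, validate_model
from .results import Ensemble, Trajectory
from .rng import exponential, stream

__all__ = ["select_reaction", "simulate_ssa", "simulate_tau_leap", "run_ensemble"]

#: channel-count threshold of the documented size-based default: direct for
#: small models, optimized_direct otherwise
ODM_CHANNEL_THRESHOLD = 32

TAU_EPSILON = 0.03
TAU_N_CRITICAL = 10
TAU_FALLBACK_MULTIPLE = 10
TAU_SSA_STEPS_PER_FALLBACK = 100


def select_reaction(propensities, u: float) -> int:
    """Direct-method channel inversion: smallest j with cumsum_j >= u * a0.

    Ties resolve to the smallest index by the cumulative-sum convention.
    """
    a = np.asarray(propensities, dtype=float)
    total = a.sum()
    if not total > 0:
        raise ValueError("all propensities are zero")
    if not 0 < u < 1:
        raise ValueError("u must lie strictly in (0, 1)")
    return int(np.searchsorted(np.cumsum(a), u * total, side="left"))


class _PropensityEvaluator:
    """Per-channel propensity evaluation on an integer state vector."""

    def __init__(self, model: ReactionNetworkModel):
        issues = [i for i in validate_model(model) if i.severity == "error"]
        if issues:
            raise ValueError(f"invalid model: {issues[0].message} at {issues[0].location}")
        if model.units_mode != "population":
            raise ValueError(
                "stochastic simulation requires a population-mode model; "
                "convert the concentration model with a system volume first"
            )
        self.model = model
        self.names = model.species_names()
        self.index = {n: i for i, n in enumerate(self.names)}
        self.params = model.parameter_values()
        self.channels = []
        for r in model.reactions:
            if r.kinetics == MASS_ACTION:
                ridx = np.array([self.index[n] for n in r.reactants], dtype=np.int64)
                rst = np.array(list(r.reactants.values()), dtype=np.int64)
                self.channels.append(("ma", model.rate_constant(r), ridx, rst))
            else:
                expr = r.propensity
                if not isinstance(expr, PropensityExpression):
                    expr = PropensityExpression(str(expr))
                self.channels.append(("expr", expr, None, None))

    def propensity(self, j: int, x) -> float:
        kind, c, ridx, rst = self.channels[j]
        if kind == "ma":
            a = c
            for k, st in zip(ridx, rst):
                xk = x[k]
                a *= xk if st == 1 else xk * (xk - 1) / 2.0
            return max(float(a), 0.0)
        values = dict(self.params)
        for name, i in self.index.items():
            values[name] = float(x[i])
        a = c.evaluate(values)
        if a < 0:
            raise RuntimeError(
                f"propensity {c.text!r} negative ({a}) at state "
                f"{dict(zip(self.names, x))}"
            )
        return float(a)

    def all_propensities(self, x) -> np.ndarray:
        return np.array([self.propensity(j, x) for j in range(len(self.channels))])


def _record_until(frames, out_i, output_times, t_next, x):
    """Fill output frames for times strictly before t_next."""
    while out_i < len(output_times) and output_times[out_i] < t_next:
        frames[out_i] = x
        out_i += 1
    return out_i


def simulate_ssa(
    model: ReactionNetworkModel,
    t_end: float,
    output_times,
    seed: int,
    variant: str = "direct",
    replicate: int = 0,
) -> Trajectory:
    """One statistically exact SSA sample path recorded at ``output_times``.

    ``variant='optimized_direct'`` updates only dependency-graph neighbours
    of the fired channel; it samples the same distribution as ``'direct'``
    (not the same path).
    """
    if variant not in ("direct", "optimized_direct"):
        raise ValueError(f"unknown SSA variant {variant!r}")
    ev = _PropensityEvaluator(model)
    S, depends = build_stoichiometry(model)
    rng = stream(seed, replicate)
    output_times = np.asarray(output_times, dtype=float)
    x = model.initial_state().astype(np.int64).copy()
    n_r = len(model.reactions)
    frames = np.zeros((len(output_times), len(x)), dtype=np.int64)
    out_i = 0
    t = 0.0

    a = ev.all_propensities(x)
    while True:
        a0 = a.sum()
        if a0 <= 0:
            t_next = math.inf
        else:
            t_next = t + exponential(rng, a0)
        out_i = _record_until(frames, out_i, output_times, min(t_next, math.inf), x)
        if t_next > t_end:
            while out_i < len(output_times):
                frames[out_i] = x
                out_i += 1
            break
        t = t_next
        j = select_reaction(a, rng.uniform())
        x += S[j]
        if np.any(x < 0):
            raise RuntimeError(f"negative population after firing channel {j}")
        if variant == "direct" or n_r == 0:
            a = ev.all_propensities(x)
        else:
            for k in depends[j]:
                a[k] = ev.propensity(k, x)

    return Trajectory(
        times=output_times,
        values=frames,
        species_names=ev.names,
        metadata={"solver": f"ssa-{variant}", "seed": seed, "replicate": replicate},
    )


def _tau_candidate(x, a, S, ridx_by_channel, epsilon, noncritical):
    """Cao-style step selection bounding the expected relative change of every
    reactant species' population (g_i factors for orders 1 and 2)."""
    if not noncritical.any():
        return math.inf
    n_s = S.shape[1]
    mu = np.zeros(n_s)
    sigma2 = np.zeros(n_s)
    for j in np.nonzero(noncritical)[0]:
        mu += S[j] * a[j]
        sigma2 += (S[j].astype(float) ** 2) * a[j]

    # highest-order factors g_i per species appearing as a reactant
    g = np.ones(n_s)
    for j, (ridx, rst) in enumerate(ridx_by_channel):
        for k, st in zip(ridx, rst):
            if st == 2:
                xk = max(x[k], 2)
                g[k] = max(g[k], 2.0 + 1.0 / (xk - 1))
            else:
                g[k] = max(g[k], _order_of_channel(ridx_by_channel, j))

    tau = math.inf
    for i in range(n_s):
        if mu[i] == 0 and sigma2[i] == 0:
            continue
        bound = max(epsilon * x[i] / g[i], 1.0)
        if mu[i] != 0:
            tau = min(tau, bound / abs(mu[i]))
        if sigma2[i] != 0:
            tau = min(tau, bound * bound / sigma2[i])
    return tau


def _order_of_channel(ridx_by_channel, j):
    ridx, rst = ridx_by_channel[j]
    return max(1, int(rst.sum())) if len(ridx) else 1


def simulate_tau_leap(
    model: ReactionNetworkModel,
    t_end: float,
    output_times,
    seed: int,
    epsilon: float = TAU_EPSILON,
    replicate: int = 0,
) -> Trajectory:
    """Adaptive explicit tau-leaping; populations never go negative.

    Critical channels (within ``TAU_N_CRITICAL`` firings of exhausting a
    reactant) fire one at a time via the exact mechanism; leaps that would
    still drive a population negative are retried with half the step.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    ev = _PropensityEvaluator(model)
    S, _ = build_stoichiometry(model)
    rng = stream(seed, replicate)
    output_times = np.asarray(output_times, dtype=float)
    x = model.initial_state().astype(np.int64).copy()
    frames = np.zeros((len(output_times), len(x)), dtype=np.int64)
    out_i = 0
    t = 0.0
    n_r = len(model.reactions)
    ridx_by_channel = [
        (ch[2] if ch[0] == "ma" else np.array([], dtype=np.int64),
         ch[3] if ch[0] == "ma" else np.array([], dtype=np.int64))
        for ch in ev.channels
    ]

    def exact_steps(t, x, out_i, n_steps):
        """A burst of exact SSA steps (the fallback regime)."""
        for _ in range(n_steps):
            a = ev.all_propensities(x)
            a0 = a.sum()
            if a0 <= 0:
                return t, x, out_i, False
            t_next = t + exponential(rng, a0)
            out_i = _record_until(frames, out_i, output_times, t_next, x)
            if t_next > t_end:
                return t_next, x, out_i, False
            t = t_next
            j = select_reaction(a, rng.uniform())
            x += S[j]
        return t, x, out_i, True

    while t < t_end:
        a = ev.all_propensities(x)
        a0 = a.sum()
        if a0 <= 0:
            break

        # critical partition: channels that could exhaust a reactant soon
        critical = np.zeros(n_r, dtype=bool)
        for j in range(n_r):
            if a[j] <= 0:
                continue
            ridx, rst = ridx_by_channel[j]
            for k, st in zip(ridx, rst):
                consumed = -S[j, k]
                if consumed > 0 and x[k] // consumed < TAU_N_CRITICAL:
                    critical[j] = True
        noncritical = ~critical & (a > 0)

        tau1 = _tau_candidate(x, a, S, ridx_by_channel, epsilon, noncritical)
        a_crit = a[critical].sum()
        tau2 = exponential(rng, a_crit) if a_crit > 0 else math.inf
        tau = min(tau1, tau2)

        if tau < TAU_FALLBACK_MULTIPLE / a0:
            t, x, out_i, ok = exact_steps(t, x, out_i, TAU_SSA_STEPS_PER_FALLBACK)
            if not ok or t > t_end:
                break
            continue

        while True:  # retry loop halving tau on a would-be-negative leap
            step = min(tau, t_end - t)
            k_fires = np.zeros(n_r, dtype=np.int64)
            for j in np.nonzero(noncritical)[0]:
                k_fires[j] = rng.poisson(a[j] * step)
            if tau2 <= tau1 and tau2 == tau and a_crit > 0 and step == tau:
                # exactly one critical firing at the end of the leap
                jc = select_reaction(np.where(critical, a, 0.0), rng.uniform())
                k_fires[jc] += 1
            x_new = x + S.T @ k_fires
            if np.all(x_new >= 0):
                break
            tau /= 2.0
            if tau < TAU_FALLBACK_MULTIPLE / a0:
                break
        if tau < TAU_FALLBACK_MULTIPLE / a0:
            t, x, out_i, ok = exact_steps(t, x, out_i, TAU_SSA_STEPS_PER_FALLBACK)
            if not ok or t > t_end:
                break
            continue

        t_next = t + step
        out_i = _record_until(frames, out_i, output_times, t_next, x)
        t = t_next
        x = x_new
        if t >= t_end:
            break

    while out_i < len(output_times):
        frames[out_i] = x
        out_i += 1
    if np.any(frames < 0):  # defensive; the scheme guarantees nonnegativity
        raise RuntimeError("tau-leaping produced a negative population")
    return Trajectory(
        times=output_times,
        values=frames,
        species_names=ev.names,
        metadata={"solver": "tau-leap", "seed": seed, "epsilon": epsilon, "replicate": replicate},
    )


def default_ssa_variant(model: ReactionNetworkModel) -> str:
    """Documented size-based default: direct below 32 channels, ODM above."""
    return "direct" if len(model.reactions) < ODM_CHANNEL_THRESHOLD else "optimized_direct"


def run_ensemble(
    model: ReactionNetworkModel,
    solver: str,
    n_reps: int,
    seed: int,
    output_times,
    t_end: float | None = None,
    **solver_kwargs,
) -> Ensemble:
    """Independent replicates on a shared grid.

    Replicate ``r`` uses the stream derived from ``(seed, r)``; results are
    identical across runs regardless of scheduling.  ``solver`` is one of
    ``ssa``, ``ssa-direct``, ``ssa-optimized_direct``, ``tau-leap``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    output_times = np.asarray(output_times, dtype=float)
    if t_end is None:
        t_end = float(output_times[-1])
    trajectories = []
    for r in range(n_reps):
        if solver == "tau-leap":
            traj = simulate_tau_leap(
                model, t_end, output_times, seed, replicate=r, **solver_kwargs
            )
        else:
            if solver == "ssa":
                variant = default_ssa_variant(model)
            elif solver.startswith("ssa-"):
                variant = solver[len("ssa-"):]
            else:
                raise ValueError(f"unknown solver {solver!r}")
            traj = simulate_ssa(
                model, t_end, output_times, seed, variant=variant, replicate=r, **solver_kwargs
            )
        trajectories.append(traj)
    return Ensemble(
        trajectories=trajectories,
        seed=seed,
        metadata={"solver": solver, "n_reps": n_reps, "t_end": t_end},
    )
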