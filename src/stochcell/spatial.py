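"""Mesoscopic spatial stochastic simulation: the reaction-diffusion master
equation (RDME) solved with the Next Subvolume Method (NSM).

Space is the set of voxels (vertex-centred dual volumes) of a tetrahedral
mesh.  Molecules jump between neighbouring voxels at the rates assembled in
:mod:`stochcell.mesh` and react within voxels with volume-scaled mass-action
propensities: a bimolecular channel with well-mixed stochastic constant c
(derived from a molar constant k as c = k/(N_A V)) has per-voxel constant
c * V / v_i = k/(N_A v_i); zeroth-order channels are apportioned by volume,
c * v_i / V; first-order constants are volume free.

The NSM keeps one next-event time per voxel in an indexed priority queue.
Executing an event touches only the affected voxel (reaction) or voxel pair
(diffusion); their total event rates are recomputed and fresh event times are
drawn (times are recomputed, not rescaled, after each propensity change —
a documented simplification of the rescaling optimization).  Queue ties break
by voxel index.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, assemble_jump_rates
from .model import MASS_ACTION, ReactionNetworkModel
from .results import SpatialResult, Trajectory
from .rng import stream

__all__ = [
    "InitialPlacement",
    "SpatialModel",
    "build_spatial_model",
    "nsm_simulate",
    "reduce_to_total",
]


@dataclass
class InitialPlacement:
    """Where the initial copies of one species go.

    mode is one of ``place_at_point`` (all copies at the mesh vertex nearest
    ``point``, restricted to the species' allowed subdomains),
    ``scatter_in_subdomain`` (copies drawn across the voxels of ``subdomain``
    with probability proportional to voxel volume), or ``uniform_everywhere``
    (volume-proportional scatter over all allowed voxels).
    """

    species: str
    mode: str
    count: int
    point: tuple | None = None
    subdomain: str | None = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("placement count must be nonnegative")
        if self.mode not in ("place_at_point", "scatter_in_subdomain", "uniform_everywhere"):
            raise ValueError(f"unknown placement mode {self.mode!r}")


@dataclass
class SpatialModel:
    """A population-mode reaction network bound to a mesh.

    ``initial_counts`` is (n_voxels, n_species); ``diffusion`` maps species
    name to a diffusion coefficient (m^2/s).  ``restrict_to_voxels`` may pin a
    reaction to an explicit voxel set (e.g. a gene site), on top of the
    per-reaction subdomain restriction.
    """

    base: ReactionNetworkModel
    mesh: Mesh
    initial_counts: np.ndarray
    diffusion: dict
    restrict_to_voxels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.initial_counts = np.asarray(self.initial_counts, dtype=np.int64)
        n_v, n_s = self.mesh.n_vertices, len(self.base.species)
        if self.initial_counts.shape != (n_v, n_s):
            raise ValueError("initial_counts must be (n_voxels, n_species)")
        if np.any(self.initial_counts < 0):
            raise ValueError("negative initial counts")
        for s in self.base.species:
            if s.name not in self.diffusion:
                raise ValueError(f"diffusion map lacks species {s.name!r}")

    def species_allowed_mask(self, species) -> np.ndarray:
        if not species.allowed_subdomains:
            return np.ones(self.mesh.n_vertices, dtype=bool)
        return np.array([l in species.allowed_subdomains for l in self.mesh.subdomain_labels])

    def reaction_allowed_mask(self, reaction) -> np.ndarray:
        if reaction.restrict_to:
            mask = np.array([l in reaction.restrict_to for l in self.mesh.subdomain_labels])
        else:
            mask = np.ones(self.mesh.n_vertices, dtype=bool)
        if reaction.name in self.restrict_to_voxels:
            pin = np.zeros(self.mesh.n_vertices, dtype=bool)
            pin[np.asarray(self.restrict_to_voxels[reaction.name], dtype=np.int64)] = True
            mask &= pin
        return mask

    def per_voxel_rate(self, reaction, voxel: int) -> float:
        """Volume-scaled stochastic rate constant of a mass-action channel."""
        c = self.base.rate_constant(reaction)
        order = reaction.order
        V = self.base.volume
        v_i = self.mesh.voxel_volumes[voxel]
        if order == 2:
            return c * V / v_i
        if order == 0:
            return c * v_i / V
        return c


def _nearest_vertex(mesh: Mesh, point, allowed_mask) -> int:
    idx = np.nonzero(allowed_mask)[0]
    if len(idx) == 0:
        raise ValueError("no mesh vertex in the species' allowed subdomains")
    d2 = ((mesh.vertices[idx] - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    return int(idx[np.argmin(d2)])


def build_spatial_model(
    base: ReactionNetworkModel,
    mesh: Mesh,
    placements: list,
    diffusion: dict,
    restrict_to_voxels: dict | None = None,
    seed: int = 0,
) -> SpatialModel:
    """Distribute a well-mixed population model onto a mesh.

    Every species with a nonzero initial count must be covered by a
    placement; totals are conserved exactly.  Scatter placements draw voxels
    with probability proportional to voxel volume using the run seed.
    """
    if base.units_mode != "population":
        raise ValueError("spatial models require a population-mode base model")
    for r in base.reactions:
        if r.kinetics != MASS_ACTION:
            raise ValueError(
                f"custom-propensity reaction {r.name!r} cannot be placed on a mesh "
                "automatically; rewrite it as mass-action channels"
            )
    names = base.species_names()
    missing = [s.name for s in base.species if s.name not in diffusion]
    if missing:
        raise ValueError(f"diffusion map lacks species {missing}")
    placed = {p.species for p in placements}
    needs = [s.name for s in base.species if s.initial_value > 0 and s.name not in placed]
    if needs:
        raise ValueError(f"species with initial copies but no placement: {needs}")

    labels = set(mesh.subdomain_labels)
    rng = stream(seed, 0)
    counts = np.zeros((mesh.n_vertices, len(names)), dtype=np.int64)
    volumes = mesh.voxel_volumes
    for p in placements:
        j = names.index(p.species)
        species = base.get_species(p.species)
        allowed = np.array([l in (species.allowed_subdomains or labels)
                            for l in mesh.subdomain_labels])
        if p.mode == "place_at_point":
            counts[_nearest_vertex(mesh, p.point, allowed), j] += p.count
            continue
        if p.mode == "scatter_in_subdomain":
            if p.subdomain not in labels:
                raise ValueError(f"placement targets nonexistent subdomain {p.subdomain!r}")
            mask = allowed & np.array([l == p.subdomain for l in mesh.subdomain_labels])
        else:  # uniform_everywhere
            mask = allowed
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise ValueError(f"no voxels available for placement of {p.species!r}")
        prob = volumes[idx] / volumes[idx].sum()
        draw = rng.multinomial(p.count, prob)
        np.add.at(counts[:, j], idx, draw)

    return SpatialModel(
        base=base,
        mesh=mesh,
        initial_counts=counts,
        diffusion=dict(diffusion),
        restrict_to_voxels=dict(restrict_to_voxels or {}),
    )


class _NSMEngine:
    """Precomputed per-voxel channel tables and the indexed event queue."""

    def __init__(self, sm: SpatialModel):
        self.sm = sm
        mesh = sm.mesh
        base = sm.base
        self.names = base.species_names()
        n_v = mesh.n_vertices
        n_s = len(self.names)
        sidx = {n: i for i, n in enumerate(self.names)}

        # --- diffusion tables: per species, per voxel neighbour/rate arrays
        self.out_total = np.zeros((n_s, n_v))  # per-molecule outbound rate
        self.neighbours = []  # [species][voxel] -> (dest array, cumulative rates)
        for s in base.species:
            D = sm.diffusion[s.name]
            allowed = s.allowed_subdomains or None
            Q = assemble_jump_rates(mesh, D, allowed)
            per_species = []
            Qr = Q.tolil()
            for i in range(n_v):
                dests, rates = [], []
                for j, q in zip(Qr.rows[i], Qr.data[i]):
                    if j != i and q > 0:
                        dests.append(j)
                        rates.append(q)
                dests = np.array(dests, dtype=np.int64)
                rates = np.array(rates)
                per_species.append((dests, np.cumsum(rates)))
                self.out_total[sidx[s.name], i] = rates.sum()
            self.neighbours.append(per_species)

        # --- reaction tables: per voxel, lists of channels
        # channel = (c_voxel, [(species idx, stoich)], [(species idx, delta)])
        self.voxel_channels = [[] for _ in range(n_v)]
        for r in base.reactions:
            mask = sm.reaction_allowed_mask(r)
            for sp_name in r.reactants:
                mask &= sm.species_allowed_mask(base.get_species(sp_name))
            reacts = [(sidx[n], st) for n, st in r.reactants.items()]
            change = {}
            for n, st in r.reactants.items():
                change[sidx[n]] = change.get(sidx[n], 0) - st
            for n, st in r.products.items():
                change[sidx[n]] = change.get(sidx[n], 0) + st
            change = [(k, d) for k, d in change.items() if d]
            voxels = np.nonzero(mask)[0]
            if len(voxels) == 0:
                raise ValueError(
                    f"reaction {r.name!r} is restricted to a subdomain with zero voxels"
                )
            for i in voxels:
                self.voxel_channels[i].append(
                    (sm.per_voxel_rate(r, int(i)), reacts, change)
                )

        # plain-Python copies for the hot loop
        self.out_total_f = self.out_total.tolist()  # [species][voxel] -> float
        self.counts = [list(map(int, row)) for row in sm.initial_counts]
        self.n_v, self.n_s = n_v, n_s

    def voxel_rate(self, i: int):
        """(reaction propensity list, diffusion rate per species, total)."""
        x = self.counts[i]
        props = []
        total = 0.0
        for c, reacts, _change in self.voxel_channels[i]:
            a = c
            for k, st in reacts:
                xk = x[k]
                a *= xk if st == 1 else xk * (xk - 1) * 0.5
            a = a if a > 0.0 else 0.0
            props.append(a)
            total += a
        diff = []
        for s in range(self.n_s):
            d = x[s] * self.out_total_f[s][i]
            diff.append(d)
            total += d
        return props, diff, total


def nsm_simulate(
    spatial_model: SpatialModel,
    t_end: float,
    output_times,
    seed: int,
    replicate: int = 0,
) -> SpatialResult:
    """One NSM sample path recorded at ``output_times`` (state after the last
    event at or before each output time; right-continuous step function).

    The path is statistically equivalent to an SSA on the expanded
    voxel-by-reaction system.
    """
    eng = _NSMEngine(spatial_model)
    rng = stream(seed, replicate)
    output_times = np.asarray(output_times, dtype=float)
    n_v, n_s = eng.n_v, eng.n_s

    totals = np.zeros(n_v)
    version = np.zeros(n_v, dtype=np.int64)
    heap = []
    t = 0.0
    for i in range(n_v):
        _, _, a = eng.voxel_rate(i)
        totals[i] = a
        if a > 0:
            heapq.heappush(heap, (t - math.log1p(-rng.random()) / a, i, 0))

    def reschedule(i, now):
        _, _, a = eng.voxel_rate(i)
        totals[i] = a
        version[i] += 1
        if a > 0:
            heapq.heappush(heap, (now - math.log1p(-rng.random()) / a, i, version[i]))

    frames = np.zeros((len(output_times), n_v, n_s), dtype=np.int64)
    out_i = 0

    while True:
        # next valid event
        while heap:
            t_next, i, ver = heap[0]
            if ver == version[i]:
                break
            heapq.heappop(heap)
        if not heap or heap[0][0] > t_end:
            t_next = math.inf
        else:
            t_next, i, _ = heapq.heappop(heap)

        # record every output time strictly before the next event (the state is
        # right-continuous: an event at exactly an output time is recorded after
        # it executes, on the next pass)
        while out_i < len(output_times) and output_times[out_i] < t_next:
            frames[out_i] = eng.counts
            out_i += 1
        if not math.isfinite(t_next) or t_next > t_end:
            while out_i < len(output_times):
                frames[out_i] = eng.counts
                out_i += 1
            break

        t = t_next
        props, diff, total = eng.voxel_rate(i)
        if total <= 0:
            version[i] += 1
            continue
        u = rng.random() * total
        acc = 0.0
        fired = False
        row = eng.counts[i]
        for ch, a in enumerate(props):
            acc += a
            if u < acc:
                for k, delta in eng.voxel_channels[i][ch][2]:
                    row[k] += delta
                    if row[k] < 0:  # defensive; cannot occur with valid propensities
                        raise RuntimeError("negative count in NSM reaction event")
                reschedule(i, t)
                fired = True
                break
        if fired:
            continue
        # diffusion event: pick species then destination
        s = None
        for cand in range(n_s):
            acc += diff[cand]
            if u < acc:
                s = cand
                break
        if s is None:  # numerical slack at the top of the cumulative sum
            s = max(range(n_s), key=lambda c: diff[c])
        dests, cum = eng.neighbours[s][i]
        if diff[s] > 0:
            # reuse the uniform within the species block
            r = (min(u, acc) - (acc - diff[s])) / row[s]
            j = int(dests[min(np.searchsorted(cum, r, side="right"), len(dests) - 1)])
        else:  # numerical slack at the top of the cumulative sum
            j = int(dests[-1])
        row[s] -= 1
        eng.counts[j][s] += 1
        reschedule(i, t)
        reschedule(j, t)

    return SpatialResult(
        times=output_times,
        counts=frames,
        species_names=list(eng.names),
        mesh=spatial_model.mesh,
        metadata={"solver": "nsm", "seed": seed, "replicate": replicate, "t_end": t_end},
    )


def reduce_to_total(spatial_result: SpatialResult) -> Trajectory:
    """Per-time per-species sums over voxels (integer-exact)."""
    return spatial_result.reduce_to_total()
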