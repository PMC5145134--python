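"""Built-in mesh generators and the negative-feedback gene-expression model
at all three modelling levels.

The bundled example is a single self-repressing gene in a budding-yeast-sized
cell: a free promoter G_F is transcribed into mRNA (rate mu), mRNA is
translated into a transcription factor P (rate kappa), P binds the promoter
(k_a) giving an occupied state G_O that is transcriptionally silent, and can
unbind again (k_d); mRNA and P degrade first order (gamma_m, gamma_p).
Baseline parametrization: mu = 0.002 s^-1, kappa = 0.015 s^-1,
gamma_m = 6e-4 s^-1, gamma_p = gamma_m / 2, k_a = 1e7 M^-1 s^-1,
k_d = 0.01 s^-1, cell volume 37e-15 L (diploid yeast), nucleus 7% of the
cell volume, D = 1e-12 m^2/s for the mobile species.  The gene carries one
copy and is fixed (D = 0) at a site inside the nucleus.
"""

from __future__ import annotations

import itertools

import numpy as np

from .convert import concentration_to_population
from .mesh import L_PER_M3, Mesh
from .model import AVOGADRO, Parameter, Reaction, ReactionNetworkModel, Species
from .spatial import InitialPlacement, SpatialModel, build_spatial_model

__all__ = [
    "generate_cube_mesh",
    "generate_cell_geometry",
    "build_grn_model",
    "InitialPlacement",
    "GRN_CELL_VOLUME_L",
    "GRN_NUCLEUS_FRACTION",
    "GRN_DIFFUSION",
]

GRN_CELL_VOLUME_L = 37e-15
GRN_NUCLEUS_FRACTION = 0.07
GRN_DIFFUSION = 1e-12  # m^2/s for mRNA and P

#: the six permutations of (0,1,2) defining the Kuhn split of a cube cell
_KUHN_PERMS = list(itertools.permutations(range(3)))


def generate_cube_mesh(n_per_edge: int, edge_length: float = 1.0) -> Mesh:
    """Structured cube mesh: ``n_per_edge`` vertices per edge, each cell split
    into 6 tetrahedra (Kuhn triangulation).  Total volume is exactly
    ``edge_length ** 3`` (in mesh coordinate units, metres)."""
    if n_per_edge < 2:
        raise ValueError("n_per_edge must be at least 2")
    n = n_per_edge
    grid = np.linspace(0.0, edge_length, n)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def vid(i, j, k):
        return (i * n + j) * n + k

    tets = []
    for i in range(n - 1):
        for j in range(n - 1):
            for k in range(n - 1):
                origin = np.array([i, j, k])
                for perm in _KUHN_PERMS:
                    path = [origin.copy()]
                    cur = origin.copy()
                    for axis in perm:
                        cur = cur.copy()
                        cur[axis] += 1
                        path.append(cur)
                    tets.append([vid(*p) for p in path])
    return Mesh(vertices=vertices, tetrahedra=np.array(tets, dtype=np.int64))


def _cube_to_ball(points: np.ndarray) -> np.ndarray:
    """Radial map of the cube [-1, 1]^3 onto the unit ball: each point moves
    onto the sphere of radius max(|x|,|y|,|z|)."""
    linf = np.max(np.abs(points), axis=1)
    l2 = np.linalg.norm(points, axis=1)
    scale = np.where(l2 > 0, linf / np.where(l2 > 0, l2, 1.0), 0.0)
    return points * scale[:, None]


def generate_cell_geometry(
    cell_volume: float = GRN_CELL_VOLUME_L,
    nucleus_fraction: float = GRN_NUCLEUS_FRACTION,
    resolution: int = 9,
) -> Mesh:
    """Two concentric spheres: an inner ``nucleus`` holding the requested
    fraction of the cell volume, surrounded by ``cytoplasm``.

    The ball is meshed deterministically by mapping a structured cube mesh
    radially onto the sphere, then rescaled uniformly so the summed
    tetrahedron volume equals ``cell_volume`` exactly.  Vertices are labelled
    nucleus inside the sorted-radius cut whose cumulative voxel volume best
    matches ``nucleus_fraction``; the gene site is the nucleus vertex nearest
    the point at half the nuclear radius along +x.

    ``cell_volume`` is in litres; ``resolution`` is the number of vertices
    per cube edge (odd values place a vertex at the centre).
    """
    if not 0 < nucleus_fraction < 1:
        raise ValueError("nucleus_fraction must lie in (0, 1)")
    if resolution < 3:
        raise ValueError("resolution too coarse to contain a nucleus vertex")
    cube = generate_cube_mesh(resolution, 2.0)
    points = _cube_to_ball(cube.vertices - 1.0)

    radius_m = (3.0 * (cell_volume / L_PER_M3) / (4.0 * np.pi)) ** (1.0 / 3.0)
    mesh = Mesh(vertices=points * radius_m, tetrahedra=cube.tetrahedra)
    # uniform rescale so the discrete volume equals the requested cell volume
    factor = (cell_volume / mesh.total_volume) ** (1.0 / 3.0)
    vertices = mesh.vertices * factor

    tmp = Mesh(vertices=vertices, tetrahedra=cube.tetrahedra)
    volumes = tmp.voxel_volumes
    radii = np.linalg.norm(vertices, axis=1)
    order = np.argsort(radii, kind="stable")
    cum = np.cumsum(volumes[order])
    target = nucleus_fraction * cum[-1]
    # cut after k vertices, 1 <= k < n, minimizing |share - fraction|
    k = int(np.argmin(np.abs(cum[:-1] - target))) + 1
    labels = np.array(["cytoplasm"] * len(vertices), dtype=object)
    labels[order[:k]] = "nucleus"

    nominal_r_nucleus = factor * radius_m * nucleus_fraction ** (1.0 / 3.0)
    site_point = np.array([nominal_r_nucleus / 2.0, 0.0, 0.0])
    nucleus_idx = order[:k]
    d2 = ((vertices[nucleus_idx] - site_point) ** 2).sum(axis=1)
    gene_site = int(nucleus_idx[np.argmin(d2)])

    return Mesh(
        vertices=vertices,
        tetrahedra=cube.tetrahedra,
        subdomain_labels=list(labels),
        gene_site_vertex=gene_site,
        metadata={
            "cell_volume": cell_volume,
            "nucleus_fraction": nucleus_fraction,
            "resolution": resolution,
        },
    )


def _grn_concentration_model() -> ReactionNetworkModel:
    V = GRN_CELL_VOLUME_L
    one_copy = 1.0 / (AVOGADRO * V)  # molar concentration of a single molecule
    gamma_m = 6e-4
    return ReactionNetworkModel(
        name="negative_feedback_gene_expression",
        units_mode="concentration",
        volume=V,
        species=[
            Species("G_F", one_copy, 0.0, frozenset({"nucleus"})),
            Species("G_O", 0.0, 0.0, frozenset({"nucleus"})),
            Species("mRNA", 0.0, GRN_DIFFUSION),
            Species("P", 0.0, GRN_DIFFUSION),
        ],
        parameters=[
            Parameter("mu", 0.002, "s^-1"),
            Parameter("kappa", 0.015, "s^-1"),
            Parameter("gamma_m", gamma_m, "s^-1"),
            Parameter("gamma_p", gamma_m / 2.0, "s^-1"),
            Parameter("k_a", 1e7, "M^-1*s^-1"),
            Parameter("k_d", 0.01, "s^-1"),
        ],
        reactions=[
            Reaction("transcription", {"G_F": 1}, {"G_F": 1, "mRNA": 1},
                     rate_parameter="mu"),
            Reaction("binding", {"G_F": 1, "P": 1}, {"G_O": 1}, rate_parameter="k_a"),
            Reaction("unbinding", {"G_O": 1}, {"G_F": 1, "P": 1}, rate_parameter="k_d"),
            Reaction("translation", {"mRNA": 1}, {"mRNA": 1, "P": 1},
                     rate_parameter="kappa"),
            Reaction("mrna_decay", {"mRNA": 1}, {}, rate_parameter="gamma_m"),
            Reaction("p_decay", {"P": 1}, {}, rate_parameter="gamma_p"),
        ],
    )


def build_grn_model(level: str = "ode", resolution: int = 9):
    """The bundled gene-expression example.

    ``level='ode'`` returns the concentration model; ``'wellmixed'`` the
    population model obtained by conversion at the 37 fL cell volume;
    ``'spatial'`` a :class:`SpatialModel` on the concentric-sphere geometry
    with the gene fixed at the gene site (transcription, binding and
    unbinding pinned to that voxel), translation restricted to the
    cytoplasm, and D = 1e-12 m^2/s for the mobile species.
    """
    ode = _grn_concentration_model()
    if level == "ode":
        return ode
    wellmixed = concentration_to_population(ode, GRN_CELL_VOLUME_L).model
    if level == "wellmixed":
        return wellmixed
    if level != "spatial":
        raise ValueError(f"unknown level {level!r}")

    mesh = generate_cell_geometry(GRN_CELL_VOLUME_L, GRN_NUCLEUS_FRACTION, resolution)
    for r in wellmixed.reactions:
        if r.name == "translation":
            r.restrict_to = frozenset({"cytoplasm"})
    site = mesh.gene_site_vertex
    site_point = tuple(mesh.vertices[site])
    placements = [InitialPlacement("G_F", "place_at_point", 1, point=site_point)]
    diffusion = {"G_F": 0.0, "G_O": 0.0, "mRNA": GRN_DIFFUSION, "P": GRN_DIFFUSION}
    return build_spatial_model(
        wellmixed,
        mesh,
        placements,
        diffusion,
        restrict_to_voxels={
            "transcription": [site],
            "binding": [site],
            "unbinding": [site],
        },
    )
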