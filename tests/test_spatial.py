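import copy

import numpy as np
import pytest
from scipy import stats

from stochcell import (
    InitialPlacement,
    Mesh,
    Parameter,
    Reaction,
    ReactionNetworkModel,
    Species,
    build_grn_model,
    build_spatial_model,
    generate_cube_mesh,
    nsm_simulate,
    reduce_to_total,
    simulate_ssa,
)

from conftest import immigration_death


def diffusion_only_model(count=1000, D=1e-12):
    return ReactionNetworkModel(
        "diffusion",
        "population",
        volume=1e-15,
        species=[Species("A", count, D)],
        parameters=[],
        reactions=[],
    )


class TestPlacements:
    def test_scatter_conserves_total_and_subdomain(self):
        mesh = generate_cube_mesh(4, 1e-6)
        labels = ["inner" if 0.2e-6 < x < 0.9e-6 else "outer" for x in mesh.vertices[:, 0]]
        mesh = Mesh(mesh.vertices, mesh.tetrahedra, subdomain_labels=labels)
        m = diffusion_only_model(137)
        sm = build_spatial_model(
            m, mesh, [InitialPlacement("A", "scatter_in_subdomain", 137, subdomain="inner")],
            {"A": 1e-12}, seed=3,
        )
        counts = sm.initial_counts[:, 0]
        assert counts.sum() == 137
        outer = mesh.subdomain_vertices("outer")
        assert counts[outer].sum() == 0

    def test_place_at_point_single_vertex(self):
        mesh = generate_cube_mesh(3, 1e-6)
        m = diffusion_only_model(42)
        sm = build_spatial_model(
            m, mesh,
            [InitialPlacement("A", "place_at_point", 42, point=(0.5e-6, 0.5e-6, 0.5e-6))],
            {"A": 1e-12},
        )
        counts = sm.initial_counts[:, 0]
        assert counts.sum() == 42
        assert np.count_nonzero(counts) == 1

    def test_missing_diffusion_entry_names_species(self):
        mesh = generate_cube_mesh(3, 1e-6)
        with pytest.raises(ValueError, match="A"):
            build_spatial_model(
                diffusion_only_model(), mesh,
                [InitialPlacement("A", "uniform_everywhere", 1000)], {},
            )

    def test_nonexistent_subdomain_rejected(self):
        mesh = generate_cube_mesh(3, 1e-6)
        with pytest.raises(ValueError, match="golgi"):
            build_spatial_model(
                diffusion_only_model(), mesh,
                [InitialPlacement("A", "scatter_in_subdomain", 1000, subdomain="golgi")],
                {"A": 1e-12},
            )

    def test_unplaced_species_with_copies_rejected(self):
        mesh = generate_cube_mesh(3, 1e-6)
        with pytest.raises(ValueError, match="no placement"):
            build_spatial_model(diffusion_only_model(), mesh, [], {"A": 1e-12})


class TestNSM:
    def test_diffusion_conserves_molecules_exactly(self):
        mesh = generate_cube_mesh(3, 1e-6)
        sm = build_spatial_model(
            diffusion_only_model(500), mesh,
            [InitialPlacement("A", "uniform_everywhere", 500)], {"A": 1e-12}, seed=1,
        )
        res = nsm_simulate(sm, 2.0, np.linspace(0, 2, 5), seed=2)
        assert np.all(res.counts.sum(axis=(1, 2)) == 500)

    def test_stationary_occupancy_proportional_to_volume(self):
        """Free diffusion started from a point relaxes to voxel occupancy
        proportional to voxel volume (chi-square at alpha = 0.01)."""
        mesh = generate_cube_mesh(3, 1e-6)
        sm = build_spatial_model(
            diffusion_only_model(1000), mesh,
            [InitialPlacement("A", "place_at_point", 1000, point=(0.5e-6,) * 3)],
            {"A": 1e-12},
        )
        res = nsm_simulate(sm, 6.0, [0.0, 6.0], seed=7)
        observed = res.counts[-1, :, 0].astype(float)
        expected = 1000 * mesh.voxel_volumes / mesh.voxel_volumes.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=len(expected) - 1)

    def test_restricted_species_never_leaves_subdomain(self):
        sm = build_grn_model("spatial", resolution=5)
        res = nsm_simulate(sm, 600.0, np.linspace(0, 600, 4), seed=5)
        mesh = sm.mesh
        cyto = mesh.subdomain_vertices("cytoplasm")
        for name in ("G_F", "G_O"):
            j = res.species_names.index(name)
            assert res.counts[:, cyto, j].sum() == 0

    def test_single_voxel_equals_wellmixed_ssa(self, grn_wellmixed):
        """With everything pinned to one voxel and its volume as the system
        volume, the NSM end-state distribution matches the SSA's (KS test)."""
        tet = Mesh(
            vertices=np.array([[0, 0, 0], [1e-6, 0, 0], [0, 1e-6, 0], [0, 0, 1e-6]]),
            tetrahedra=np.array([[0, 1, 2, 3]]),
            subdomain_labels=["site", "rest", "rest", "rest"],
        )
        base = copy.deepcopy(grn_wellmixed)
        base.volume = float(tet.voxel_volumes[0])
        for s in base.species:
            s.allowed_subdomains = frozenset()
        placements = [InitialPlacement("G_F", "place_at_point", 1, point=(0, 0, 0))]
        diffusion = {s.name: 0.0 for s in base.species}
        sm = build_spatial_model(
            base, tet, placements, diffusion,
            restrict_to_voxels={r.name: [0] for r in base.reactions},
        )
        n = 800
        t_end = 1500.0
        nsm_ends = np.array([
            reduce_to_total(nsm_simulate(sm, t_end, [0.0, t_end], seed=60, replicate=r))["P"][-1]
            for r in range(n)
        ])
        ssa_ends = np.array([
            simulate_ssa(base, t_end, [0.0, t_end], seed=61, replicate=r)["P"][-1]
            for r in range(n)
        ])
        ks = stats.ks_2samp(nsm_ends, ssa_ends)
        assert ks.pvalue > 0.01

    def test_nsm_equals_expanded_system_ssa(self):
        """On a small mesh, NSM matches an exact SSA on the expanded
        voxel-by-species system in which diffusion jumps are first-order
        channels (independent dual-route check)."""
        mesh = generate_cube_mesh(2, 1e-6)  # 8 voxels
        D = 1e-12
        decay = 0.5
        base = ReactionNetworkModel(
            "dd",
            "population",
            volume=1e-15,
            species=[Species("A", 200, D)],
            parameters=[Parameter("gamma", decay)],
            reactions=[Reaction("deg", {"A": 1}, {}, rate_parameter="gamma")],
        )
        sm = build_spatial_model(
            base, mesh, [InitialPlacement("A", "place_at_point", 200, point=(0, 0, 0))],
            {"A": D},
        )
        # independent oracle: expanded well-mixed model with per-voxel species
        from stochcell.mesh import assemble_jump_rates

        Q = assemble_jump_rates(mesh, D).tocoo()
        species = [Species(f"A_{i}", 0) for i in range(mesh.n_vertices)]
        species[sm.initial_counts[:, 0].argmax()].initial_value = 200
        params = [Parameter("gamma", decay)]
        reactions = [
            Reaction(f"deg_{i}", {f"A_{i}": 1}, {}, rate_parameter="gamma")
            for i in range(mesh.n_vertices)
        ]
        k = 0
        for i, j, q in zip(Q.row, Q.col, Q.data):
            if i != j and q > 0:
                params.append(Parameter(f"q{k}", q))
                reactions.append(
                    Reaction(f"jump{k}", {f"A_{i}": 1}, {f"A_{j}": 1}, rate_parameter=f"q{k}")
                )
                k += 1
        expanded = ReactionNetworkModel(
            "expanded", "population", species=species, parameters=params, reactions=reactions
        )
        n, t_end = 600, 1.5
        nsm_tot = np.array([
            nsm_simulate(sm, t_end, [0.0, t_end], seed=70, replicate=r).counts[-1, :, 0]
            for r in range(n)
        ])
        ssa_tot = np.array([
            simulate_ssa(expanded, t_end, [0.0, t_end], seed=71, replicate=r).values[-1]
            for r in range(n)
        ])
        # compare the survival total and one voxel marginal
        ks_total = stats.ks_2samp(nsm_tot.sum(axis=1), ssa_tot.sum(axis=1))
        assert ks_total.pvalue > 0.01
        ks_voxel = stats.ks_2samp(nsm_tot[:, 3], ssa_tot[:, 3])
        assert ks_voxel.pvalue > 0.01


class TestReduceToTotal:
    def test_diffusion_totals_constant(self):
        mesh = generate_cube_mesh(3, 1e-6)
        sm = build_spatial_model(
            diffusion_only_model(250), mesh,
            [InitialPlacement("A", "uniform_everywhere", 250)], {"A": 1e-12}, seed=9,
        )
        res = nsm_simulate(sm, 1.0, np.linspace(0, 1, 4), seed=10)
        totals = reduce_to_total(res)
        assert np.all(totals["A"] == 250)

    def test_grn_gene_copy_conserved(self):
        sm = build_grn_model("spatial", resolution=5)
        res = nsm_simulate(sm, 900.0, np.linspace(0, 900, 4), seed=12)
        totals = reduce_to_total(res)
        assert np.all(totals["G_F"] + totals["G_O"] == 1)

    def test_empty_result(self):
        mesh = generate_cube_mesh(2, 1.0)
        from stochcell.results import SpatialResult

        res = SpatialResult(
            times=np.array([]), counts=np.zeros((0, mesh.n_vertices, 1), dtype=int),
            species_names=["A"], mesh=mesh,
        )
        traj = reduce_to_total(res)
        assert traj.values.shape == (0, 1)
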