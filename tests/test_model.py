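import numpy as np
import pytest

from stochcell import (
    Parameter,
    Reaction,
    ReactionNetworkModel,
    Species,
    build_stoichiometry,
    mass_action_propensity,
    validate_model,
)


class TestValidation:
    def test_grn_model_is_valid(self, grn_ode):
        assert validate_model(grn_ode) == []

    def test_dangling_species_reference(self):
        m = ReactionNetworkModel(
            "m",
            "population",
            species=[Species("A", 1)],
            parameters=[Parameter("k", 1.0)],
            reactions=[Reaction("r", {"X": 1}, {}, rate_parameter="k")],
        )
        issues = validate_model(m)
        assert len(issues) == 1
        assert issues[0].severity == "error"
        assert "X" in issues[0].message

    def test_non_integer_population_count(self):
        m = ReactionNetworkModel("m", "population", species=[Species("A", 2.5)])
        issues = validate_model(m)
        assert len(issues) == 1 and issues[0].severity == "error"

    def test_issues_ordered_by_location(self):
        m = ReactionNetworkModel(
            "m",
            "population",
            species=[Species("B", -1), Species("A", 0.5)],
            parameters=[Parameter("k", float("inf"))],
        )
        issues = validate_model(m)
        assert [i.location for i in issues] == sorted(i.location for i in issues)

    def test_mass_action_order_cap(self):
        m = ReactionNetworkModel(
            "m",
            "population",
            species=[Species("A", 3)],
            parameters=[Parameter("k", 1.0)],
            reactions=[Reaction("r", {"A": 3}, {}, rate_parameter="k")],
        )
        assert any("order 3" in i.message for i in validate_model(m))


class TestMassActionPropensity:
    def test_unimolecular(self):
        # mRNA decay constant at 100 copies
        r = Reaction("decay", {"A": 1}, {}, rate_parameter="k")
        assert mass_action_propensity(r, {"A": 100}, 6e-4) == pytest.approx(0.06)

    def test_bimolecular_empty_pool(self):
        r = Reaction("bind", {"A": 1, "B": 1}, {}, rate_parameter="k")
        assert mass_action_propensity(r, {"A": 0, "B": 7}, 1.0) == 0.0

    def test_dimerization_at_two_copies(self):
        r = Reaction("dimer", {"A": 2}, {}, rate_parameter="k")
        c = 0.37
        assert mass_action_propensity(r, {"A": 2}, c) == pytest.approx(c)

    @pytest.mark.parametrize("x", [0, 1])
    def test_dimerization_below_two_copies_is_zero(self, x):
        r = Reaction("dimer", {"A": 2}, {}, rate_parameter="k")
        assert mass_action_propensity(r, {"A": x}, 1.0) == 0.0

    def test_order_three_rejected(self):
        r = Reaction("tri", {"A": 2, "B": 1}, {}, rate_parameter="k")
        with pytest.raises(ValueError):
            mass_action_propensity(r, {"A": 5, "B": 5}, 1.0)

    def test_nonnegative_on_random_states(self):
        rng = np.random.default_rng(0)
        reactions = [
            Reaction("uni", {"A": 1}, {}, rate_parameter="k"),
            Reaction("bi", {"A": 1, "B": 1}, {}, rate_parameter="k"),
            Reaction("dimer", {"B": 2}, {}, rate_parameter="k"),
        ]
        for _ in range(200):
            state = {"A": int(rng.integers(0, 50)), "B": int(rng.integers(0, 50))}
            for r in reactions:
                assert mass_action_propensity(r, state, rng.uniform(0, 10)) >= 0


class TestStoichiometry:
    def test_grn_structure(self, grn_ode):
        S, _ = build_stoichiometry(grn_ode)
        assert S.shape == (6, 4)  # reversible binding stored as two channels
        names = grn_ode.species_names()
        transcription = S[0]
        assert transcription[names.index("mRNA")] == 1
        assert np.count_nonzero(transcription) == 1  # net change is +1 mRNA only

    def test_empty_model(self):
        m = ReactionNetworkModel("m", "population", species=[Species("A", 1)])
        S, depends = build_stoichiometry(m)
        assert S.shape == (0, 1)
        assert depends == {}

    def test_chain_dependencies(self):
        m = ReactionNetworkModel(
            "chain",
            "population",
            species=[Species("A", 10), Species("B", 0)],
            parameters=[Parameter("k", 1.0)],
            reactions=[
                Reaction("conv", {"A": 1}, {"B": 1}, rate_parameter="k"),
                Reaction("deg", {"B": 1}, {}, rate_parameter="k"),
            ],
        )
        _, depends = build_stoichiometry(m)
        assert depends == {0: [0, 1], 1: [1]}

    def test_dependency_graph_matches_brute_force(self):
        """The dependency graph equals the graph found by perturbing each
        species and checking which propensities change, on random small
        models."""
        rng = np.random.default_rng(42)
        names = ["S0", "S1", "S2", "S3", "S4", "S5"]
        for _ in range(25):
            n_s = int(rng.integers(2, 7))
            n_r = int(rng.integers(1, 9))
            species = [Species(n, int(rng.integers(1, 20))) for n in names[:n_s]]
            reactions = []
            for j in range(n_r):
                reactants = {}
                for _ in range(int(rng.integers(0, 3))):
                    name = names[int(rng.integers(0, n_s))]
                    if sum(reactants.values()) < 2:
                        reactants[name] = min(reactants.get(name, 0) + 1, 2)
                products = {names[int(rng.integers(0, n_s))]: 1}
                reactions.append(
                    Reaction(f"r{j}", reactants, products, rate_parameter="k")
                )
            m = ReactionNetworkModel(
                "rand", "population", species=species,
                parameters=[Parameter("k", 0.5)], reactions=reactions,
            )
            S, depends = build_stoichiometry(m)

            def prop(j, state):
                return mass_action_propensity(reactions[j], state, 0.5)

            base = {s.name: 5 for s in species}
            brute = {}
            for j in range(n_r):
                changed = {names[i] for i in np.nonzero(S[j])[0]}
                affected = set()
                for k in range(n_r):
                    for sp in changed:
                        bumped = dict(base)
                        bumped[sp] += 1
                        if prop(k, bumped) != prop(k, base):
                            affected.add(k)
                brute[j] = sorted(affected)
            assert depends == brute
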