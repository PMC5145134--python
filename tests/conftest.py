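import numpy as np
import pytest

from stochcell import (
    Parameter,
    Reaction,
    ReactionNetworkModel,
    Species,
    build_grn_model,
)

# baseline parametrization of the bundled gene-expression example
MU = 0.002
KAPPA = 0.015
GAMMA_M = 6e-4
GAMMA_P = 3e-4
K_A = 1e7
K_D = 0.01
CELL_VOLUME = 37e-15
AVOGADRO = 6.02214076e23


@pytest.fixture(scope="session")
def grn_ode():
    return build_grn_model("ode")


@pytest.fixture(scope="session")
def grn_wellmixed():
    return build_grn_model("wellmixed")


def immigration_death(mu: float, gamma: float, x0: int = 0) -> ReactionNetworkModel:
    """Birth-death process with constant immigration; stationary law is
    Poisson(mu/gamma)."""
    return ReactionNetworkModel(
        "immigration_death",
        "population",
        species=[Species("A", x0)],
        parameters=[Parameter("mu", mu), Parameter("gamma", gamma)],
        reactions=[
            Reaction("immigration", {}, {"A": 1}, rate_parameter="mu"),
            Reaction("death", {"A": 1}, {}, rate_parameter="gamma"),
        ],
    )


def grn_steady_state_protein_molar():
    """Independent algebraic root solve of the steady-state balance:
    mu*G_F = gamma_m*m, kappa*m = gamma_p*P, k_a*G_F*P = k_d*G_O,
    G_F + G_O = G_tot, which reduces to K*P^2 + P - alpha*G_tot = 0 with
    K = k_a/k_d and alpha = kappa*mu/(gamma_m*gamma_p)."""
    g_tot = 1.0 / (AVOGADRO * CELL_VOLUME)
    K = K_A / K_D
    alpha = KAPPA * MU / (GAMMA_M * GAMMA_P)
    return (-1.0 + np.sqrt(1.0 + 4.0 * K * alpha * g_tot)) / (2.0 * K)
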