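# Methods

## Model representation

A reaction network is a list of species, parameters and irreversible
reaction channels; reversible reactions are stored as two channels, since
every solver operates on irreversible channels.  Models are either
*concentration* based (molar initial values, deterministic rate constants)
or *population* based (integer copy numbers, stochastic rate constants).
Mass-action channels are limited to total reactant order ≤ 2 (zeroth order,
A, A+B, 2A); anything else is a custom propensity written in a small
expression grammar: identifiers (`[A-Za-z_][A-Za-z0-9_]*`, case-sensitive),
numeric literals, `+ - * / ^`, parentheses, and `exp`, `log`, `pow`, `min`,
`max`.  Expressions are pure functions of the state and parameters;
time-dependent propensities are not supported.  Unit tags on parameters are
carried through conversions but not dimension-checked inside expressions —
custom propensities are the user's responsibility, and the conversion tools
flag them for manual treatment rather than guessing.

Discrete mass-action propensities are the standard combinatorial forms:
c, c·x_A, c·x_A·x_B, c·x_A(x_A−1)/2.  Deterministic rate laws are
k·∏c^stoich in concentration mode; in population mode the mean-field of the
discrete propensity is used, so ODE/SSA mean comparisons are exact for
first-order networks.

## Unit and level conversion

Concentration → population at system volume V (litres) uses the 2019 SI
exact Avogadro constant N_A = 6.02214076×10²³.  Counts are
round-half-to-even of c·N_A·V (deterministic and unbiased).  Rate rules:
zeroth order k → k·N_A·V; first order unchanged; bimolecular A+B
k → k/(N_A·V); dimerization 2A k → 2k/(N_A·V).  A parameter shared by
reactions with conflicting rules is an error.  Population → spatial
conversion conserves total copies exactly by placement; inside the spatial
solver, bimolecular constants are rescaled per voxel (c·V/v_i, equivalently
k/(N_A·v_i) — the standard mesoscopic convention) and zeroth-order rates
are apportioned by voxel volume.

Helper conversions used by the bundled parametrization: ln 2 / t_half for
half-lives and /60 for per-minute rates.

## Deterministic solver

`simulate_ode` integrates dx/dt = Sᵀa(x) with scipy's BDF method and an
analytic Jacobian assembled symbolically (sympy) from the rate laws.
Defaults rtol = 10⁻⁶, atol = 10⁻⁹.  Because local-error control does not
bound global error, the integrator runs at tolerances tighter than
requested by a fixed factor of 500; delivered global accuracy then tracks
the user-facing tolerances (verified against closed forms and a tolerance
halving self-consistency check).  A trajectory is flagged as steady when
‖dx/dt‖∞ < 10⁻¹²·max(1, ‖x‖∞).

Forward sensitivities solve the augmented system dS/dt = J·S + ∂f/∂p with
S(0) = 0 (parameters do not enter initial conditions).  Scaled
sensitivities are reported as (p/x)·∂x/∂p with 0/0 guarded to 0.
Expressions containing `min`/`max` are rejected as non-differentiable.

A structural note on the bundled example: the steady-state protein level
depends on μ, κ, γ_m, γ_p only through the combination κμ/(γ_m γ_p), so
the four scaled sensitivities tie in magnitude at steady state (≈0.59),
ahead of the binding pair (≈0.41).  "The degradation rates are the most
sensitive" therefore holds as a tie with the production rates, and the
tests assert exactly that.

## Stochastic well-mixed solvers

*Direct method*: exponential waiting time with rate a₀ = Σa_j (inverse
transform, −log1p(−u)/a₀), then channel inversion — smallest j with
cumulative sum ≥ u·a₀, ties to the smallest index.  *Optimized direct
method* recomputes only the propensities reachable from the fired channel
in the reaction dependency graph (r′ depends on r iff r changes a species
read by r′'s propensity); it samples the same distribution.  The documented
size-based default picks direct below 32 channels, ODM above.

*Tau-leaping* is adaptive, explicit and non-negativity preserving: the
candidate step bounds the expected relative propensity change by ε
(default 0.03) using highest-order g_i factors; channels within n_c = 10
firings of exhausting a reactant are partitioned off as critical and fired
one at a time; when the selected step falls below 10/a₀ the solver falls
back to bursts of 100 exact SSA steps; leaps that would still drive a
population negative are retried with half the step.

Every stochastic solver records the state at an output time as the value
after the last event at or before it (right-continuous step function).
Randomness comes from a counter-based Philox generator; replicate r of a
run with seed s uses `Philox(SeedSequence(entropy=s, spawn_key=(r,)))`, so
ensembles are bitwise reproducible regardless of scheduling or replicate
order.

## Spatial solver (RDME / next subvolume method)

Voxels are mesh vertices with lumped-mass dual volumes (a quarter of every
incident tetrahedron; volumes sum exactly to the mesh volume).  Diffusive
jump rates are assembled from the P1 finite-element stiffness matrix K of
the Laplacian: q_ij = D·max(−K_ij, 0)/v_i; positive off-diagonal entries
(possible on poor-quality meshes, including the mapped ball meshes below)
are truncated to zero with a warning.  On uniform Cartesian-derived meshes
the rates satisfy detailed balance v_i·q_ij = v_j·q_ji exactly, and a 1D
interval assembly path reproduces the classical D/h² nearest-neighbour
rate for verification.

The NSM keeps one next-event time per voxel in an indexed priority queue
(binary heap with lazy invalidation; ties break by voxel index).  An event
either fires a reaction channel in its voxel or moves one molecule of a
chosen species to a neighbour drawn proportionally to the jump rates.
Affected voxels get freshly drawn event times (recomputed, not rescaled — a
deliberate simplification of the rescaling optimization, traded for
clarity; the sampled law is unchanged).  Species restricted to subdomains
get their jump matrices zeroed outside those subdomains; reactions can be
restricted to subdomains or pinned to explicit voxel sets (used for the
gene site).  The solver handles mass-action channels only; custom
propensities must be rewritten before spatial conversion.

## Built-in geometries and the example model

The cube mesh is a structured grid with each cell split into six
tetrahedra (Kuhn triangulation); its volume is exact.  The cell geometry
maps a refined cube radially onto a ball (deterministic and
dependency-free, rather than requiring an external mesher), then rescales
uniformly so the summed tetrahedron volume equals the requested cell
volume exactly.  The nucleus is the set of innermost vertices (sorted by
radius) whose cumulative voxel volume best matches the requested fraction,
so the discrete nuclear share is accurate to voxel granularity; at the
default resolution (9 vertices per cube edge, 729 voxels) the 7% request
yields 7.08%, i.e. 7% to the nearest percent.  The gene site is the
nucleus vertex nearest the point at half the nuclear radius along +x.

The bundled gene-expression model carries one gene copy (the single-copy
reading of the example; a diploid variant would place two).  In the
spatial variant the gene species are restricted to the nucleus and fixed
(D = 0) at the gene site; transcription, binding and unbinding are pinned
to the gene-site voxel; translation is restricted to the cytoplasm (mRNA
must leave the nucleus before it is translated — the membrane is modelled
as freely passable rather than as an explicit species); mRNA and P diffuse
everywhere at D = 10⁻¹² m²/s.  κ = 0.015 s⁻¹ is taken as given rather than
re-derived from elongation-rate assumptions.

## Verification strategy and problem sizes

The suite checks each solver against an independent route: closed forms
(exponential decay, linear growth, decay sensitivities), an algebraic root
solve of the example's steady-state balance, the analytic Poisson
stationary law of an immigration–death process (chi-square on 10⁴ end
states at α = 0.01), categorical sampling for channel selection, SSA as
the oracle for tau-leaping (3-SE ensemble agreement at 500 replicates),
and an exact SSA on the expanded voxel-by-species system as the oracle for
the NSM (two-sample KS).  The fast-diffusion limit check scales every
diffusion constant by 100 on a coarse (27-voxel) cell mesh and compares
the total-P ensemble mean with the well-mixed SSA at 200 replicates over
240 s — sizes chosen so the Monte Carlo band dominates the small bias that
cytoplasm-restricted translation introduces (effective κ is reduced by the
nuclear volume share).  These simulated checks exercise well-mixed
kinetics, diffusion and their coupling, but synthetic models at these
scales cannot stand in for real meshes from imaging data or for networks
with stiff bimolecular cascades; on poor-quality meshes the truncation of
negative jump rates biases diffusion slightly toward the better-shaped
elements.

## Known limitations

Mass-action order ≤ 2; no events, assignments or rule-based expansion; one
well-mixed compartment; SBML import is a subset (functions, events, rules
and extra compartments are ignored with warnings; kinetic laws matching
k·∏reactants import as mass action, others become custom propensities
verbatim, with local parameters namespaced `reactionid_paramname`); SBML
export and spatial SBML are not supported; meshes are 3D tetrahedral only
(the 1D path exists solely for verification); no microscale
particle-tracking or spatial deterministic (PDE) solvers; tau-leaping uses
the explicit scheme only.
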