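# Methods

This note records the model, the numerical choices, and the reasoning behind
the defaults, at the level of detail a maintainer or reviewer needs.

## Scope and assumptions

The simulator couples four layers on nested time steps (diffusion ⊂
mechanics ⊂ phenotype): systemic PK, a 2D reaction-diffusion
microenvironment, per-cell damage PD, and a minimal off-lattice cell
population. Assumptions worth keeping in mind:

- All dosing is intravenous bolus into the central compartment; no
  absorption compartment, no nonlinear elimination.
- The tissue couples to the circulation only through Dirichlet boundary
  voxels (perivascular concentration = Biot × circulation, Biot default 1).
  There is no explicit vasculature inside the domain.
- Damage is an abstract, nonnegative, per-cell quantity; the internalized
  substrate feeds it with proportionality 1. Under the concentration-based
  damage model ("AUC") the internalized variable is a concentration; under
  the amount-based model ("AUC_amount") it is a raw amount.
- The domain is 2D; a fictitious slab thickness (default = voxel size)
  converts concentrations to masses for conservation bookkeeping.

## Pharmacokinetics

One- and two-compartment models are advanced exactly. For the
two-compartment generator M = [[−(k12+λ), k21/R], [k12·R, −k21]] the
propagator expm(M·dt) is built from the closed-form eigendecomposition of
the 2×2 system. Its eigenvalues are always real here (the discriminant is a
sum of squares for nonnegative rates). When the discriminant falls below
1e−12·trace² the repeated-root limit e^μ(I + (B − μI)) is used instead of
the two-point form — the two-eigenvalue formula divides by μ₁−μ₂ and would
cancel catastrophically. The propagator is cached per (params, dt) so that a
million steps cost a million 2×2 multiplies, and repeated stepping is
bit-identical to fresh computation.

C + P/R is the conserved total when λ = 0; with λ > 0 it is non-increasing.
These are used as invariant tests rather than assumptions.

PK state advances on the diffusion step (the finest cadence), so Dirichlet
values are always current; the closed forms make this essentially free.
Doses that fall exactly on a step boundary are applied before the ODE step
of that interval.

### SBML-defined PK

The SBML reader supports the subset needed for PK models with dosing:
compartments, species, constant parameters, rate rules, reactions with
arithmetic kinetic laws, and events triggered by `time >= t0` whose
assignments may reference current state (so `C + 10` expresses a bolus).
Everything else — algebraic/assignment rules, function definitions, event
delays — raises an explicit unsupported-feature error naming the construct.
The reader is a small MathML-arithmetic interpreter over lxml; the package
also writes minimal valid SBML for its own fixtures, and the two round-trip.

The circulation readout is the species named `circulation_concentration`
when present, else the first listed species. The name match is the less
ambiguous rule, the positional rule is the fallback.

Between events the system is integrated with LSODA at rtol 1e−10/atol
1e−12; integration is split exactly at each trigger time. The model keeps
its own clock but stepped loops should drive it through `advance_to(t)`
with an exact (index × dt) time: accumulating `+= dt` drifts by ulps and
can pull a boundary-triggered event into the wrong interval. File time
units are converted to minutes when declared; undeclared time is assumed
minutes, matching the rest of the simulator.

## Dosing schedules

A schedule expands to events at start + i·interval, i < max_number_doses,
truncated at t_end; the first number_loading_doses carry the loading
amount. Missing-parameter policy: loading-dose count defaults to 0 and the
loading amount to the regular amount (warnings); a missing dose amount, or
a missing interval with more than one dose, is a hard error. With the
confluence trigger the first dose time is the first *phenotype-step* time at
which confluence ≥ threshold — the trigger quantizes to that grid because
that is when the population is re-measured; if the threshold is never
reached, no doses are given and a warning is logged (not an error).

Confluence is Σπr²/area over the whole rectangular domain, capped at 1; no
overlap correction is attempted (it is a trigger heuristic, not a measure).

## Microenvironment numerics

∂u/∂t = D∇²u − λu is advanced by first-order operator splitting: an
implicit decay factor 1/(1+λ·dt), then implicit tridiagonal solves along x,
then along y (backward-Euler in each direction; unconditionally stable).
The x-then-y order is fixed; symmetric inputs stay symmetric to solver
round-off (regression-tested). Dirichlet voxels get identity rows in the
banded systems, so they hold their value exactly through the solves;
non-Dirichlet edges are zero-flux via the reflected-ghost diagonal
modification (1+α instead of 1+2α), which makes the scheme exactly
mass-conserving without decay — the banded matrices have unit column sums.
Rows sharing a Dirichlet pattern share one matrix, so each step is a few
batched `solve_banded` calls regardless of grid size. A line with a single
voxel has no neighbors and must reduce to the identity (the edge formula
would otherwise leak mass).

The scheme's steady state carries an O(λ·dt) splitting bias on top of the
O(h²) spatial error. The steady-state validation against the analytic
profile u₀·cosh(√(λ/D)(L−y))/cosh(√(λ/D)L) therefore refines dt together
with h² when demonstrating second-order convergence.

Cellular exchange treats all sinks in a voxel simultaneously: with weights
aᵢ = dt·ρᵢ·V_cell/V_voxel the voxel relaxes to u/(1+Σaᵢ) and each cell
receives its share aᵢ·u′·V_voxel, so field + internalized mass is conserved
to round-off for uptake-only steps. Secretion (available in the API, unused
by the packaged samples) is a net source toward a target concentration and
deliberately does not drain the internalized pool. A cell occupies exactly
one voxel (the one containing its center).

## Pharmacodynamics

dA/dt = −mA, dD/dt = A − r₁D − r₀ has the affine solution

    A′ = A·e^{−m·dt}
    D′ = D·e^{−r₁·dt} + A·T(m, r₁, dt) + R(r₀, r₁, dt)

with transfer coefficient T = e^{−m·dt}(1 − e^{−(r₁−m)dt})/(r₁−m) and
repair term R = (r₀/r₁)(e^{−r₁·dt} − 1) (−r₀·dt when r₁ = 0). T is
evaluated through expm1 so the limit branches r₁ = m, r₁ = 0 and m = 0 are
approached smoothly; the explicit repeated-rate branch (T = dt·e^{−m·dt})
engages below a 1e−12 relative gap. D is clamped at 0 after each step: the
zero-order repair r₀ makes the affine solution go negative at low A, and
damage is defined as nonnegative. The four coefficients depend only on
(params, dt) and are precomputed once per (substrate, cell type) pair; the
non-precomputed path recomputes them per call and is bit-identical, so
per-cell heterogeneous parameters give the same trajectories.

Each pair may solve PD on its own step (a positive integer multiple of the
mechanics step, default equal to it), tracked by a per-pair counter.

### Effects

The Hill factor f = 1 + (f_sat−1)·x/(1+x), x = (D/EC50)ⁿ, is monotone in D
and bounded between 1 and f_sat; its input is the damage, not the
instantaneous internalized amount. For proliferation, apoptosis and
motility (migration speed — the clearest single motility parameter), f_sat
= saturation_rate/base_rate and per-substrate factors multiply. A
multiplicative MOA on a zero base rate is rejected at configuration time
(f_sat undefined) with a pointer to the additive pattern. Necrosis adds
saturation_rate·x/(1+x) per substrate onto the base rate, which is well
defined at the customary base of 0. Rates are reset to base before every
application, making the update idempotent and order-independent; this
discharges, inside the engine, the no-stacking obligation that open
host-platform designs leave to the user.

At division, concentration-kind A and damage D are inherited by both
daughters (intensive quantities); amount-kind A and D are split equally
(extensive, conserving totals). The partitioning of damage at division is a
modeling choice — nothing forces either convention — and is flagged as such.

## Cell population

Cells are circles with type-level radius and base rates. Division/death per
phenotype step uses competing exponential waiting times (the earliest event
within dt wins), which is unbiased for small rate·dt and correctly breaks
ties between division and death. Daughters are placed one radius apart at a
uniform random angle, symmetric about the parent. Dead cells are removed
immediately — death-stage modeling (lysis, shrinking) is out of scope.
Mechanics is a persistent random walk (direction redrawn with probability
dt/τ_persist) plus a pairwise linear repulsion that removes half the
overlap per step, with positions clamped to the domain.

Randomness comes from a single numpy Generator seeded by the config seed.
Every step draws a fixed, population-sized batch of variates in a fixed
order, whether or not each variate is used, so identical seed + config give
bit-identical trajectories, and running PD bookkeeping with all MOAs
disabled provably cannot perturb the phenotype stream (it consumes no
randomness). This single-stream design was chosen over per-cell
counter-based streams for simplicity; the determinism contract it must
satisfy is tested byte-for-byte on full runs.

The two-drug damage display maps (D₁, D₂), each saturated as D/(D+EC50),
through a bilinear blend between a base gray, a per-drug color, and a
both-saturated corner color; it is deterministic and monotone per channel.

## Configuration surface

YAML with structural sections (`domain`, `time`, `substrates`,
`cell_types`, `user_parameters`) whose leaf keys follow the `S_...` naming
convention with the substrate/MOA/cell-type names substituted
(`drugA_central_elimination_rate`, `drugA_prolif_EC50`, `drugA_dt_tumor`,
`PKPD_pk_substrate_names`, ...). Defaults applied with a warning (each
recorded exactly once): PK model "2C", Biot 1, damage model "AUC", Hill
power 1, loading-dose fields. Hard errors are collected and reported
together: unknown PK model or MOA, EC50 ≤ 0, missing dose amount/interval,
missing saturation rate or EC50 for an active MOA, dangling substrate
references, PD step not a multiple of the mechanics step. MOA flags are
double-typed: values > 0.5 activate (boolean-in-a-double convention).

## Loop ordering

Per diffusion step: apply due doses → advance PK → update Dirichlet →
diffuse/decay → cell exchange. Per mechanics step additionally: PD updates
→ rate recomputation → mechanics. Per phenotype step: division/death →
confluence check (may trigger dosing) → snapshot. The dose/Dirichlet/
diffusion order within an interval is pinned by an instrumentation test.
Whether a dose precedes or follows the PK advance within its interval is
not externally forced; dose-before-advance is chosen and pinned by test.

## Default parameters and the samples

Library defaults follow common tissue-scale conventions: 20 µm voxels on an
800 µm square domain, diffusion step 0.01 min, mechanics 0.1 min, phenotype
6 min. The packaged samples and the dose sweep run at a documented reduced
scale — diffusion 0.1 min, mechanics 0.5 min, ~300 initial cells in a
250 µm disc, 48 simulated hours — sized so a full sample takes seconds and
the 8-dose × 5-seed sweep a few minutes on one CPU.

Sample PKPD parameters are plausible round numbers for a slowly cycling
line and a systemically cleared small molecule, not a fit to any dataset:
base cycle entry 4.8e−4/min (~24 h doubling), apoptosis 1e−5/min, cell
radius 8.4 µm; drug diffusion 6e4 µm²/min, microenvironment decay
0.01/min, elimination 2.5e−3/min with k12 = 5e−3, k21 = 2e−3, R = 1.5;
uptake 0.02/min, metabolism 0.02/min, r₁ = 2e−3/min, r₀ = 1e−4, EC50 = 1000
damage units with Hill power 2. With 20 a.u. boluses these put mid-tumor
damage within an order of magnitude of the EC50, so the dose sweep spans
no-effect to saturation across 0.1–100 a.u.

## What the synthetic experiments do and do not show

The samples emulate a drug gradient entering a growing monolayer from a
vessel-like boundary. They do not emulate oxygen/nutrient limitation,
pressure-dependent growth arrest, death-phase volume dynamics, 3D
geometry, or heterogeneous vasculature; passing tests therefore validate
the transport-damage-effect machinery and its conservation/determinism
contracts, not any quantitative biology. Figure-level claims are
deliberately qualitative (drug on < drug off; dose-response monotone).

## Known limitations

- First-order splitting couples decay/diffusion; steady profiles carry an
  O(λ·dt) bias (quantified above, ~1e−3 relative at default steps).
- The SBML subset excludes assignment rules and function definitions;
  models using them must be rewritten with rate rules.
- Overlap relaxation is not force-based mechanics; dense packings relax
  geometrically, with no adhesion or pressure feedback.
- Confluence ignores overlap, so it can overestimate coverage in dense
  regions; it is used only as a dosing trigger.
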