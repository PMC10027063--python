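# pkpdsim

An agent-based 2D tumor simulator with systemic pharmacokinetics (PK) and
damage-based pharmacodynamics (PD), for modelers who want to ask "what does
this dosing schedule do to this cell population?" without writing a solver.
Drugs are dosed as intravenous boluses into a virtual circulation, reach the
tissue through vessel-adjacent Dirichlet boundary voxels, diffuse and decay
across a voxelized microenvironment, are taken up and metabolized by
off-lattice cell agents, and accumulate as abstract intracellular *damage*
that shifts the cells' proliferation, apoptosis, necrosis and motility rates
through Hill-type effect functions.

## The model

**Pharmacokinetics.** Each substrate follows one of three systemic models:

- one-compartment: dC/dt = −λC
- two-compartment: dC/dt = (k21/R)·P − (k12 + λ)·C,  dP/dt = k12·R·C − k21·P
- any SBML-defined ODE model with time-triggered dose events (a restricted
  but validated subset of SBML Level 3 core)

where C and P are the circulation and periphery concentrations (a.u.), λ the
elimination rate, k12/k21 the intercompartmental clearance rates and R the
central-to-peripheral volume ratio. The linear models are advanced by their
exact solutions (the 2×2 propagator is built by closed-form
eigendecomposition and cached), so stepping is fast and has no integration
error. Doses are instantaneous increases of C, at a fixed interval with
optional loading doses; the first dose is given at a fixed time or when the
monolayer confluence first reaches a threshold. The microenvironment's
Dirichlet voxels are pinned each step to Biot × C, the perivascular
concentration.

**Microenvironment.** ∂u/∂t = D∇²u − λ_d·u on a 2D voxel grid, advanced by
implicit operator splitting (tridiagonal solves along x then y,
unconditionally stable); non-Dirichlet edges are zero-flux. Each cell is a
point sink: voxel concentration relaxes implicitly and the removed mass is
credited to the cell's internalized pool, conserving mass exactly.

**Pharmacodynamics.** Per (substrate, cell type), internalized substrate A
and damage D obey

    dA/dt = −m·A        dD/dt = A − r₁·D − r₀

(metabolism rate m, first-order repair r₁, zero-order repair r₀; the
A-into-D proportionality is 1 and D is clamped at 0). The update uses the
exact affine solution with precomputed coefficients. Damage drives each
configured mechanism of action (MOA) through

    f = 1 + (f_sat − 1)·(D/EC50)ⁿ / (1 + (D/EC50)ⁿ),   f_sat = saturation rate / base rate

Factors from multiple drugs multiply for proliferation, apoptosis and
motility; necrosis effects add on the rate itself (its base rate is usually
0, where f_sat is undefined). Rates are reset to base before every
application, so effects never stack across steps.

## Worked example

```python
from pkpdsim import run_sample

log = run_sample("prolif_sample", seed=1, output_dir="output")
print(log.final_cell_count, log.dose_events[0])
```

This runs the packaged anti-proliferative sample — 300 tumor cells in an
800 µm square domain, a two-compartment drug entering from the bottom
boundary, three 20 a.u. doses 12 h apart — for 48 simulated hours, and prints

```
392 (0.0, 'drugA', 20.0, False)
```

i.e. 392 cells remain at 48 h (the same seed without drug grows to 1122),
and the first bolus of 20 a.u. was given at t = 0. `output/` contains
`pk_trajectory.csv`, `doses.csv`, per-snapshot cell and field tables, and
`summary.csv` with cell counts and the mean ± SD of log₁₀ damage over
damaged cells.

The same experiment as a dose sweep (an in-silico IC50 curve):

```bash
pkpdsim sweep --replicates 5 --seed 1 --output sweep.csv
```

Other entry points: `pkpdsim run config.yaml` for your own YAML
configuration (parameter names follow the `S_...` convention, e.g.
`drugA_central_elimination_rate`, `drugA_prolif_EC50`), and
`pkpdsim sample --list` for the packaged samples (one per MOA, a two-drug
combination, a confluence-triggered start, an SBML-defined PK variant, and
two templates). See `docs/methods.md` for the numerical scheme, parameter
meanings and defaults.

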