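# Methods

## Model and assumptions

The pipeline couples per-organism flux balance analysis to extracellular
batch mass balances (dFBA, direct-coupling form: the LP is solved inside
every derivative evaluation). The assumptions inherited from that framework:

- **Pseudo-steady intracellular state.** Each species' fluxes satisfy
  `A v = 0` with bounds at every instant; only extracellular pools carry
  dynamics.
- **Noninteracting species.** The coculture LP is block diagonal, so the
  joint growth optimum equals the two independent optima; `solve_coculture`
  builds the block form for fidelity and the dynamic loop uses the
  per-species solves (the equivalence is asserted in tests).
- **Lexicographic resolution of alternate optima.** Growth LPs are
  degenerate; reported fluxes are the ethanol-maximal point of the growth
  optimum. Stage 2 fixes growth with a relative slack of 1e-12 rather than
  the more customary 1e-6..1e-9: the stage-1 optimum is a basic solution of
  the same problem so only round-off needs absorbing, and slack here is
  traded into spurious ethanol at a steep exchange ratio (growth given up
  buys sugar and ATP for fermentation), which would otherwise swamp a 1e-8
  comparison against the enumeration oracle. If stage 2 still fails, the
  solver falls back to the stage-1 vertex.
- **Degeneracy beyond stage 2** (e.g. by-product splits among
  ethanol-optimal vertices) is reported as the solver's vertex;
  `variability_at_optimum` computes flux ranges at the (optionally
  ethanol-fixed) optimum and any range above 1e-6 marks the value as
  vertex-dependent rather than unique.
- **Oxygen as a control, not a state.** Dissolved oxygen is clamped at
  0.29 mM during the aerobic phase and 0 afterwards; there is no oxygen ODE
  or mass-transfer model. Uptake parameters are the same in both phases.
- **Unit bridge.** Exchange fluxes (mmol/gDW/h) convert to mass balances via
  `dC/dt = (M_w/1000) v X`, with glucose 180.16, xylose 150.13, ethanol
  46.07 g/mol, etc. Working volume defaults to 1 L so grams equal g/L; the
  reactor-scale inputs/outputs are only mutually consistent at that volume.
- **Yield basis.** `Y_eth` divides by sugar *supplied*, not consumed; at the
  default horizons ~99% of sugar is consumed so the two bases differ by
  ~1%, and the supplied basis is the one the reference arithmetic uses.

## Parameters

Defaults in `cofba.config` (one organism each):

| parameter | yeast | bacterium | units | meaning |
|---|---|---|---|---|
| v_g,max / v_z,max | 22.4 | 12 | mmol/gDW/h | maximal sugar uptake |
| K_g / K_z | 0.8 | 0.25 | g/L | sugar half-saturation |
| v_o,max | 2.5 | 20 | mmol/gDW/h | maximal O2 uptake |
| K_o | 0.003 | 0.024 | mM | O2 half-saturation |
| K_ie | 10 | 20 | g/L | ethanol inhibition constant |
| X_0 | 0.044 | 0.006 | gDW/L | inoculum |

Feed mixtures hold total sugar at 75 g/L: 50/50 (t_f 14 h), 60/40 (16 h),
70/30 (17 h); the horizons grow with glucose share so both sugars reach
~99% consumption. The aerobic DO setpoint is 0.29 mM (~98% saturation, above
the level where ethanol production becomes oxygen-sensitive). Switch-time
optimization defaults: bounds (0, t_f), tolerance 0.01 h (printed switch
times carry 0.1 h precision), a 10-point grid pre-scan to bracket the basin
before golden-section/parabolic refinement (`scipy.optimize.minimize_scalar`,
bounded). Unimodality is assumed — the switch curve on every system examined
rises to one interior maximum — and the grid guards against stray local
maxima; the returned point is the best of everything evaluated including
both bounds.

## Synthetic networks: what they emulate and what they do not

`synthetic_data` builds carbon-balanced toys whose optima have closed forms:

- **yeast-like** (glucose only): fermentation (glc -> 2 ethanol + 2 CO2,
  2 ATP), respiration (glc + 6 O2 -> 6 CO2, ATP yield derived from the
  requested aerobic biomass yield), and a biomass reaction co-producing
  glycerol (0.3 mol/mol by default) as the growth-coupled redox sink.
- **bacterium-like** (xylose only): fermentation branches are NADH-balanced
  elementary modes of a lumped glycolysis/PFL/PDH/ADH/ACK network — a
  PFL-dependent mixed-acid mode (5/6 ethanol + 5/6 acetate + 5/3 formate
  per xylose, ATP 2 + acetate) with the best anaerobic ATP yield, a
  PFL-independent all-ethanol mode (5/3 ethanol + 5/3 CO2, ATP 2), and a
  never-optimal succinate branch. Deleting the mixed-acid mode (the `pfl`,
  `ack` and `pta` aliases all map onto it at toy scale) therefore zeroes
  formate and strictly raises optimal ethanol while lowering growth — the
  knockout phenotype of interest. Lumping whole modes instead of single
  enzymes keeps every oracle-checked toy within the 12-column vertex
  enumeration bound.

Biomass is carried as 1-carbon units of 25 g/mol, so the biomass "molar
mass" exercises the same unit bridge as every other compound. Given the
requested anaerobic and aerobic biomass yields, the generator inverts the
energy balance to set the ATP cost of biomass `a = p_ferm (Y_max - Y_an)/Y_an`
and the respiratory ATP yield `q = a Y_aer/(Y_max - Y_aer)` (with
`Y_max = 0.025 x biomass carbon` the carbon ceiling); the requested yields
are then realized exactly at zero maintenance, and `Y_aer >= Y_an` implies
`q >= p_ferm`, so aerobic metabolism always dominates. Default yields are
literature-typical: yeast 0.018/0.090 gDW per mmol glucose (anaerobic /
aerobic, i.e. ~0.10/0.50 g/g), bacterium 0.015/0.077 gDW per mmol xylose
(~0.10/0.51 g/g). Under the standard oxygen caps these give aerobic growth
of ~0.50 1/h (yeast) and ~0.82 1/h (bacterium) — the regime where the
bacterium accumulates a few g/L of cells during a 7–8 h aerobic phase and
then finishes its sugar anaerobically, which is how the substrate-selective
coculture is operated.

The toys deliberately do *not* emulate genome-scale features: no
gene–protein–reaction logic, one abstract energy currency (ATP without
carbon) and implicit redox (folded into mode stoichiometry), no Crabtree
overflow, no distinct NADH/NADPH pools (so the yeast insertion strategies
R00845/R01058 only apply at genome scale — on toys they fail loudly for lack
of the NADP metabolites). Passing tests on toys validates the machinery
(LP, lexicographic resolution, integration, unit conversions, optimization,
scan bookkeeping), not any genome-scale prediction.

### Oracles

Three independent routes must agree on every toy: (1) the production solver
(persistent GLPK, cross-checked against scipy/HiGHS and cobrapy), (2)
exhaustive vertex enumeration of `{Av=b, bounds}` (fix `n - rank(A)` fluxes
at finite bounds, solve, verify; stage 2 enumerates the growth-fixed face),
restricted to <=12 columns, and (3) the closed-form energy-allocation
optimum (respiration first up to the O2 cap, then the best fermentation
mode; growth solves `a x + m = ATP(S - x)` segment by segment; ties among
equal-ATP modes are broken toward ethanol, which is exactly what stage 2
does). A seeded family of 100 random specs (degenerate and
maintenance-bearing variants included) agrees across all three routes to
better than 1e-8 in both objectives.

## Numerical choices

- **LP engines.** `solve_growth`/`solve_lexicographic` use scipy's HiGHS
  (deterministic); the dynamic loop uses `TwoStageLP`, a persistent GLPK
  problem re-solved from the previous basis (~3 us/solve vs ~2 ms one-shot),
  selected by `SimulationConfig.solver`. Both paths are tested to agree to
  1e-8.
- **Integration.** RK23 (adaptive low-order embedded pair), rtol 1e-7,
  atol 1e-9, max step 0.25 h; the integration is split exactly at t_s so the
  oxygen discontinuity is never stepped across. Concentrations below 1e-9
  g/L are treated as zero before the kinetics (avoiding LP bounds of
  ~1e-12), states are clamped at zero, and an infeasible species LP (e.g.
  unmet ATP maintenance with no substrate) contributes zero rates rather
  than aborting. A fixed-step explicit Euler fallback (0.01 h) exists for
  debugging. Halving tolerances moves final ethanol by <0.1%.
- **Insertions** get bounds (-1000, 1000) if reversible, (0, 1000)
  otherwise, in the cytosolic compartment — the genome-scale convention.
- **Strategy resolution.** Strategies name enzymes; `data/aliases.yaml`
  lists candidate reaction ids per enzyme across model versions (plus the
  toy-mode ids), and resolution demands exactly one candidate present in the
  loaded model — zero or several is a hard error, with near-miss suggestions.
- **ATP maintenance** is the lower bound of the ATP-drain reaction, which is
  structurally a boundary reaction and is listed as an exchange.
- **`make_xylose_selective`** zeroes glucose exchange and glucokinase; in
  non-strict mode a model containing none of the glucose candidates is
  treated as already selective (the toy bacterium is glucose-free by
  construction), while strict mode errors — both behaviours are tested.

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
networks: 100-model oracle sweeps, 14–17 h batch simulations (~500 stored
points each, two LP solves per derivative evaluation), and switch
optimizations of ~20 simulations per row. Genome-scale runs (iND750-class
yeast and iAF1260-class bacterium networks) use the same code paths through
`read_model`/`check_dimensions` but require the published model files,
which this repository does not redistribute.

## Known limitations

- Batch only: no fed-batch feeds, volume dynamics, or k_La-based oxygen
  transfer; no dissolved-oxygen mass balance at all.
- No gene-level (GPR) knockout logic: strategies edit reactions directly.
- No MOMA-style knockout objectives; pure FBA throughout.
- Single switch time; no multi-phase or continuous DO schedules.
- The closed-form oracle covers growth-positive optima; at maintenance-dominated
  corners (no feasible growth) it reports feasibility but not the full
  product split, where the vertex oracle remains the reference.
- Toy by-product profiles are mode-locked: acetate/formate ratios move in
  fixed proportion, unlike genome-scale solutions where degeneracy can
  reshuffle them (the variability check exists for exactly that case).
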