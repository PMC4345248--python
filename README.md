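# cofba — dynamic FBA of a substrate-selective coculture

Lignocellulosic hydrolysates are glucose/xylose mixtures, and fermenting
them with a single organism runs into glucose catabolite repression: xylose
sits untouched until the glucose is gone. One way around it is a coculture
of substrate-selective microbes — a glucose-selective yeast together with a
xylose-selective bacterium (a glucose-transport-negative strain that grows
on xylose only) — so both sugars are consumed simultaneously. `cofba` is a
tested pipeline for analysing bioethanol production in such a batch
coculture with dynamic flux balance analysis (dFBA), for people studying
*in silico* strain and process design: which reaction knockouts/insertions
raise ethanol yield, and when to switch the reactor from aerobic growth to
anaerobic fermentation.

## The model

Each organism is a stoichiometric network solved as a linear program at
every instant (fast intracellular dynamics). For the two noninteracting
species the coculture LP is block diagonal:

    max  mu = mu_SC + mu_EC = w_SC' v_SC + w_EC' v_EC
    s.t. A_SC v_SC = 0,  A_EC v_EC = 0,  v_min <= v <= v_max

Because growth LPs have alternate optima, every solve is lexicographic:
growth is maximized, fixed, and ethanol secretion is re-maximized on the
optimal face. Substrate uptake bounds come from Michaelis–Menten kinetics
with non-competitive ethanol inhibition,

    v_g = v_g,max * G/(K_g + G) * 1/(1 + E/K_ie),      v_o = v_o,max * O/(K_o + O),

and the extracellular batch balances close the loop:

    dX/dt = mu X,   dG/dt = -v_g X,   dZ/dt = -v_z X,   dE/dt = v_e,SC X_SC + v_e,EC X_EC

with dissolved oxygen an external control: 0.29 mM before the switching
time `t_s`, zero after. Batch performance is measured by the ethanol yield
`Y_eth = E V(t_f) / (sugar supplied)` and the productivity
`Pr_eth = E V(t_f) / t_f`; the switching time is chosen by bounded scalar
maximization of `Pr_eth` with a full batch simulation per objective
evaluation.

Genome-scale networks (SBML L3 FBC or COBRA model-JSON) load through
cobrapy; reaction-level engineering strategies (e.g. acetate kinase or
pyruvate-formate-lyase knockouts in the bacterium, NADP-dependent
dehydrogenase insertions in the yeast) are named by enzyme and resolved to
model ids through a YAML alias map. The package also generates small
carbon-balanced toy networks for both species whose two-stage optima have
closed forms, plus an exhaustive vertex-enumeration oracle, so the entire
pipeline runs and is validated without downloading any model.

## Worked example

```python
import dataclasses
from cofba import SimulationConfig, optimize_switch, simulate_batch, summarize
from cofba.synthetic_data import toy_coculture

yeast, bacterium, _ = toy_coculture()          # standard operating conditions
conf = SimulationConfig(t_f=14.0, t_s=7.0, glucose_0=37.5, xylose_0=37.5)
sw = optimize_switch(conf, yeast, bacterium, tol=0.01)
traj = simulate_batch(dataclasses.replace(conf, t_s=sw.t_s_opt), yeast, bacterium)
m = summarize(traj)
print(f"t_s*={sw.t_s_opt:.2f} h  ethanol={m.ethanol_total:.1f} g "
      f"Y={m.yield_eth:.3f} g/g  Pr={m.productivity:.3f} g/h")
```

prints

    t_s*=8.52 h  ethanol=22.6 g Y=0.302 g/g  Pr=1.616 g/h

i.e. on the 50/50 mixture (75 g/L total sugar, 14 h batch) the optimal
aerobic phase lasts ~8.5 h and the culture makes 22.6 g ethanol, 15.9 g from
the yeast and 6.7 g from the bacterium, at a yield of 0.30 g per g of sugar
supplied. Deleting the bacterium's formate-producing branch
(`strategies.catalogue()` entry `dpfl`) eliminates formate entirely and
raises ethanol to 28.7 g (+27%), because carbon that paid for the knocked-out
branch's extra ATP is redirected to ethanol at the cost of slower growth —
which is also why the optimal switch moves later (8.9 h).

The numbered drivers under `analysis/` run the full study on the synthetic
networks: `01_base_case.py` (the three 50/50, 60/40, 70/30 mixtures at their
optimal switch times), `02_switch_curve.py` (productivity vs `t_s`),
`03_strategy_scan.py` (knockouts x mixtures), and `04_oracle_validation.py`
(solver vs brute-force and closed-form oracles). Each writes its tables to
`results/`.

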