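#!/usr/bin/env python
"""Validation sweep: LP solver vs brute-force and closed-form oracles.

Generates a seeded family of random toy networks (both species kinds,
degenerate and maintenance-bearing variants included), solves each with the
two-stage LP, and compares growth and ethanol against (a) exhaustive vertex
enumeration and (b) the generator's closed-form energy-allocation optimum.
Writes per-model deviations to results/oracle_validation.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cofba.fba_core import solve_lexicographic
from cofba.synthetic_data import (make_toy_model, oracle_lexicographic,
                                  random_toy_spec)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20240917)
    parser.add_argument("--n", type=int, default=100)
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(args.seed)
    rows = []
    for i in range(args.n):
        spec = random_toy_spec(rng)
        model, oracle = make_toy_model(spec)
        sugar_ex = "EX_glc" if spec.sugar == "glucose" else "EX_xyl"
        caps = {sugar_ex: float(rng.uniform(1.0, 25.0))}
        o2 = 0.0
        if "EX_o2" in model.exchange_ids:
            o2 = float(rng.uniform(0.0, 20.0))
            caps["EX_o2"] = o2
        mu_o, eth_o = oracle_lexicographic(model, caps, "EX_etoh")
        sol = solve_lexicographic(model, caps, "EX_etoh")
        ana = oracle.analytic_optimum(caps[sugar_ex], o2)
        rows.append({
            "model": i, "kind": spec.species_kind,
            "degenerate": spec.degenerate, "maintenance": spec.maintenance,
            "n_reactions": model.n_reactions,
            "mu_lp": sol.mu, "mu_vertex": mu_o, "mu_closed_form": ana.mu,
            "eth_lp": sol.flux("EX_etoh"), "eth_vertex": eth_o,
            "eth_closed_form": ana.ethanol,
            "dev_mu": max(abs(sol.mu - mu_o), abs(ana.mu - mu_o)),
            "dev_eth": max(abs(sol.flux("EX_etoh") - eth_o),
                           abs(ana.ethanol - eth_o)),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "oracle_validation.csv", index=False)
    print(f"{args.n} random networks "
          f"({int(table.degenerate.sum())} with degenerate growth optima)")
    print(f"worst growth deviation:  {table.dev_mu.max():.2e}")
    print(f"worst ethanol deviation: {table.dev_eth.max():.2e}")
    print(f"Wrote {OUT / 'oracle_validation.csv'}")


if __name__ == "__main__":
    main()
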