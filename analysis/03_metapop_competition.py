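#!/usr/bin/env python
"""Metapopulation competition: heterogeneous vs homogeneous arms, 2 transfers.

Runs the paired-microcosm competition analogue (12 pairs per arm, equal
mean resource level, 50:50 cooperator:cheat start) under hard and soft
pooling across 20 simulation seeds and compares the pooled cooperator
frequency between arms.

Finding: under hard pooling the heterogeneous arm ends with a distinctly
higher cooperator frequency; under soft pooling the arm difference collapses
to below the plating-noise resolution.  Writes results/metapop_competition.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from coopscape.metapop import run_metapopulation_experiment
from coopscape.synth import SyntheticDesign, gen_metapop_config

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(20)


def arm_frequency(design, treatment, regime, seed):
    cfg = gen_metapop_config(design, treatment, regime=regime,
                             n_transfers=2, stochastic=True)
    _, pools = run_metapopulation_experiment(cfg, seed=seed)
    final = pools[pools["transfer"] == 2]
    coop = final["fraction"].where(final["x"] > 0, 0.0)
    return float(coop.groupby(final["pair"]).sum().mean())


def main() -> None:
    design = SyntheticDesign()
    rows = []
    for regime in ("hard", "soft"):
        for seed in SEEDS:
            het = arm_frequency(design, "heterogeneous", regime, seed)
            hom = arm_frequency(design, "homogeneous", regime, seed)
            rows.append(dict(regime=regime, seed=seed, het=het, hom=hom,
                             diff=het - hom))
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "metapop_competition.csv", index=False)

    for regime, sub in table.groupby("regime"):
        print(f"{regime} pooling: coop freq het = {sub.het.mean():.4f}, "
              f"hom = {sub.hom.mean():.4f}, diff = {sub['diff'].mean():+.4f} "
              f"(+/- {sub['diff'].std(ddof=1) / np.sqrt(len(sub)):.5f} MC-SE, "
              f"het > hom in {(sub['diff'] > 0).sum()}/{len(sub)} seeds)")
    print(f"wrote {OUT / 'metapop_competition.csv'}")


if __name__ == "__main__":
    main()
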