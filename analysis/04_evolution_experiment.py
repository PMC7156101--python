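#!/usr/bin/env python
"""Evolution experiment: 20 transfers of de-novo cheat invasion, CAS read-out.

Runs the full reproduction chain — pure-cooperator metapopulations in both
arms, cheats arising by mutation, 20 seasons of paired mixing under hard
pooling, then the CAS-analogue plate assay with ANOVA/Tukey against the
ancestral producer.

Finding: cooperation erodes in both arms, but the heterogeneous arm retains
the higher mean investment and per-capita chelator activity (the
productivity-covariance mechanism).  Writes results/evolution/.
"""

import json
from pathlib import Path

from coopscape.cli import reproduce_headline

OUT = Path(__file__).resolve().parents[1] / "results" / "evolution"
SEED = 1


def main() -> None:
    report = reproduce_headline(OUT, seed=SEED)
    print(f"seed {SEED}, {report['n_transfers']} transfers, "
          f"{report['regime']} pooling")
    print("mean final investment:",
          {k: round(v, 5) for k, v in report["mean_investment"].items()})
    print("mean CAS-analogue activity:",
          {k: round(v, 3) for k, v in report["mean_activity"].items()})
    a = report["anova"]
    print(f"ANOVA (ancestral vs arms): F({a['df_between']},{a['df_within']}) "
          f"= {a['F']:.2f}, p = {a['p']:.2e}")
    for row in report["tukey"]:
        print(f"  Tukey {row['group_a']} vs {row['group_b']}: "
              f"p_adj = {row['p_adj']:.4f}")
    print("heterogeneous > homogeneous:",
          report["heterogeneous_gt_homogeneous"])
    print(f"wrote {OUT / 'report.json'}")


if __name__ == "__main__":
    main()
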