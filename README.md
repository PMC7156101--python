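# coopscape

Evolution of public-goods cooperation in resource-heterogeneous
metapopulations: analytic and numeric ESS theory for siderophore
investment under hard vs. soft selection, a serial-transfer
paired-microcosm simulator, and the wet-lab assay statistics — with a
synthetic-data generator standing in for experimental data.

## The problem

Siderophore production by *Pseudomonas aeruginosa* is a classic microbial
public good: producers pay a growth cost to secrete an iron-chelating
molecule that benefits every cell in the culture, so non-producing
"cheats" outgrow producers within any well-mixed patch. Whether
cooperation survives in a *metapopulation* of patches depends on how
patches contribute offspring to the next generation. When resource-rich
patches are both more productive **and** more cooperation-friendly, that
positive covariance lets productivity-weighted ("hard") mixing maintain
cooperation at levels that equal-contribution ("soft") mixing cannot.

## The model

A cell with investment `x`, experiencing neighbour siderophore
availability `y` in a patch with resources `R`, grows at rate

```
γ = R^a · y − x²,          w_R = exp(γ)
```

With relatedness `r = dy/dx`, the within-patch selection gradient on a
monomorphic resident `z` is `R^a·r − 2z`, so a single patch stabilises at
`z* = r·R^a/2`. Across a metapopulation with resource density `p_R` and
ancestry weights `c_R`, selection follows `∫ c_R (dW_R/dx) dR`:

* **soft selection** (`c_R = p_R`): `z* = r·E[R^a]/2` — heterogeneity has
  no effect for `a = 1`;
* **hard selection** (`c_R = p_R·w̄_R/w̄`): richer patches are
  overweighted and `z* ≈ (R̄r/2)(1 + r·σ_R²/2)` for `a = 1` —
  heterogeneity favours more cooperation.

For `a ≠ 1` a Jensen term appears in both regimes (diminishing returns
`a < 1` push the soft ESS below the homogeneous value, accelerating
returns above).

## Worked example

```python
from coopscape import ResourceDistribution, TraitModel, ess_solve, ess_approx

dist = ResourceDistribution.two_point(0.5, 1.5)   # paired patches, mean 1
model = TraitModel(r=1.0)
print(ess_solve(dist, model, "soft").z_star)       # 0.5
print(ess_solve(dist, model, "hard").z_star)       # 0.569300925903311
print(ess_approx(1.0, 0.25, model, "hard").z_star) # 0.5625
```

Soft selection sits exactly at `R̄r/2 = 0.5`; hard selection raises the
stable investment to 0.5693, close to the first-order prediction
`0.5·(1 + 0.25/2) = 0.5625` (the gap is O(σ⁴)).

The simulation analogue of the competition experiment
(`python analysis/03_metapop_competition.py`) prints:

```
hard pooling: coop freq het = 0.3529, hom = 0.2796, diff = +0.0734 (het > hom in 20/20 seeds)
soft pooling: coop freq het = 0.2865, hom = 0.2796, diff = +0.0070
```

Two serial transfers of 12 paired microcosms at the same mean resource
level: under hard (equal-volume) pooling the heterogeneous arm keeps a
clearly higher cooperator frequency; under soft (density-equalised)
pooling the difference collapses by an order of magnitude, below the
resolution of the emulated plating assay.

The other drivers follow the same pattern: `analysis/01_ess_theory.py`
(ESS landscape over spreads, regimes and exponents),
`analysis/02_single_patch_competition.py` (cooperator relative fitness
W = 0.96/0.93/0.81 in high/intermediate/low media — all below 1,
increasing with resources), `analysis/04_evolution_experiment.py`
(20 transfers with de-novo cheats, then the chrome-azurol-S
chelator-activity read-out and its ANOVA).

## Command line

```
coopscape ess --config scenario.yaml --out result.json
coopscape simulate --config sim.yaml --seed 17 --out runs/
coopscape synth competition --seed 3 --out data/
coopscape analyze competition --in data/counts.csv --out fitness.csv
coopscape reproduce --seed 1 --out results/evolution/
```

Every run writes a manifest (config hash, seed, version) and is
byte-reproducible for a fixed seed.

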