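# Methods

## Model

Growth of a focal cell is `γ = R^a·y − x²`: benefit proportional to local
resources `R` and to ambient siderophore `y` (the density-weighted mean
investment of the patch), cost quadratic in own investment `x`. Fitness
is `w_R = exp(γ)`. The quadratic cost makes the relative cost of
production fall with resource availability, and for `a = 1` both the
selection gradient and the equilibrium are linear in `R`. Relatedness
`r` enters as the regression slope `dy/dx` of neighbour production on
focal production; it is an exogenous parameter, not derived from
demography. The resident population is treated as monomorphic
("vanishingly little variation"): no polymorphic equilibria are sought.

Within a patch the gradient of relative fitness at `x = y = z` is
`R^a·r − 2z`, with root `z* = r·R^a/2`. Across patches, selection
integrates this gradient against ancestry weights `c_R`: `c_R = p_R`
under soft selection (every patch contributes equally) and
`c_R = p_R·w̄_R/w̄` under hard selection (contribution proportional to
patch mean fitness `w̄_R = exp(R^a z − z²)`). The hard gradient is
returned normalised by `w̄`; the normalisation rescales but cannot move
the root because `w̄ > 0`. First-order expansions in the resource
variance give `z* ≈ (r·R̄^a/2)(1 + ½a(a−1)R̄⁻²σ²)` (soft) and
`z* ≈ (r·R̄^a/2)(1 + a(a−1+a·r·R̄^{2a})/(2R̄²)·σ²)` (hard); at `a = 1`
these reduce to `R̄r/2` and `(R̄r/2)(1 + rσ²/2)`. The intermediate
algebraic steps of the hard expansion are not re-derived here; the final
forms are validated against the numeric solver, with the error shrinking
as O(σ⁴).

## Numerics

* Resource distributions: atomic support is summed exactly; continuous
  densities are integrated by adaptive quadrature on `[Rmin, Rmax]`
  (absolute tolerance 1e-12, relative 1e-10). Moments are always
  computed from the support, never taken on trust.
* ESS solving: Brent's method on `[0, r·Rmax^a]`, xtol 1e-10. The
  gradient is non-negative at 0 and strictly negative at the upper end
  (the weighted integrand is bounded by `Rmax^a·r − 2z`), so the bracket
  always holds a sign change; `r = 0` short-circuits to `z* = 0`.
* Trait substitution: from resident `z`, mutants at `z ± step` invade if
  their ancestry-weighted relative fitness exceeds one, with the mutant
  experiencing `y = r·z_mut + (1−r)·z_res`. The walk takes the stronger
  invading direction, breaks exact ties randomly (seeded), and stops
  when neither direction invades or when a proposal would revisit the
  previous resident (a two-cycle straddling the root). The quadratic
  cost guarantees both directions fail within one step of the gradient
  root. Non-convergence raises with the trajectory attached.

## Serial-transfer simulator

The bench-scale experiment is mirrored directly: patches are 6-mL
microcosms at fixed resource levels, seasons last 48 h, matched pairs
are mixed at season end, and a 1% bottleneck founds the next season.
Pooling maps the regimes onto bench operations: equal-volume mixing
(hard — contribution tracks final density) versus rescaling each culture
to a common density before mixing (soft).

The within-season law is the model's growth rate used as a Malthusian
rate, `γ_i = κ(R·y − x_i²)` per hour, with `y` recomputed each Euler
step (960 steps per 48-h season on log-densities; halving the step moves
end-of-season frequencies by < 1e-4) and a hard ceiling `K·R` on total
density — carrying capacity proportional to resources. The ceiling does
the ecological work: richer patches grow faster *and* saturate earlier,
which shortens the window during which cheats gain on cooperators, so
the cooperator's Malthusian-ratio fitness rises with `R` while staying
below 1. That is the positive covariance between cooperation,
productivity and resources that hard pooling converts into
metapopulation-level maintenance of cooperation.

Defaults (calibrated once to the qualitative experimental patterns, then
frozen): `κ = 32 h⁻¹`, `K = 1e9 cells·mL⁻¹` per unit `R`, producer
investment `x = 0.02`, inoculum `5e5 cells·mL⁻¹` per strain, bottleneck
0.01. These give within-patch cooperator fitness W = 0.96/0.93/0.81 and
saturating densities in high/intermediate/low media, a hard-pooling arm
difference of +0.073 in pooled cooperator frequency after two transfers,
and a soft-pooling difference of +0.007 — an order of magnitude smaller
and below the plating-noise resolution of the emulated assay. The soft
null is exact only at the gradient level; a discrete 50:50 competition
carries higher-order terms, which is why the soft difference is small
rather than zero.

Founder sampling at the bottleneck is optional (Poisson total,
multinomial composition); the default is exact fractional densities,
because ~1e7-cell bottlenecks make drift negligible. Seeds expand to
per-stage child seeds through one `numpy` Generator.

De-novo cheats (the evolution experiment) arise as a per-division flux
`μ` from producer births into an `x = 0` strain. The default for the
evolution scenario is `μ = 2e-3` per division, read as the aggregate
loss-of-function supply to the large pyoverdine/pyochelin target; this
puts cheats at intermediate frequencies within the 20-transfer horizon,
where the covariance mechanism differentiates the arms (heterogeneous
retains cooperator frequency ≈ 0.10 vs homogeneous ≈ 0.06 at transfer
20). Much smaller supplies leave cheats invisible on that horizon.

Two intrinsic features of the growth law deserve note. First, because
non-producers cannot grow at all when `y = 0`, a cheat-dominated culture
cannot regrow a 1% bottleneck: a 50:50 two-strain metapopulation run
long enough collapses entirely (tragedy of the commons), so long-horizon
comparisons use the evolution scenario, as the original experimental
design does. Second, cooperation erodes in *both* arms by transfer 20 —
the simulator reproduces the direction (heterogeneous retains more
cooperation) but not a heterogeneous arm indistinguishable from the
ancestor.

## Assay statistics

Malthusian parameter `m = ln(n_end/n_start)`; cooperator relative
fitness `W = m_coop/m_cheat`. Zero colony counts are rejected outright
rather than pseudocounted. Per-capita CAS activity is read as
`(1 − A_i/A_ref)/(OD600·dilution)`: the chelation fraction normalised by
the undiluted density back-calculated from the 1:10 diluted OD read (the
formula's printed grouping is ambiguous; the per-capita reading is
adopted, and the dilution factor is configurable for the alternative).
ANOVA, Tukey-HSD and one-sample t-tests run through `scipy.stats`
(two-sided, α = 0.05, no correction beyond Tukey); the test suite checks
them against independent oracles — explicit sums of squares,
studentized-range tails, hand t-formulas, and a vectorised 1e5-draw
permutation null (agreement within the small-sample permutation-vs-F
gap, up to ~0.05 for 5-per-group samples).

## Synthetic data

The generator encodes the study design: three media at relative resource
levels 1.0 / 0.625 / 0.25 (the 1:4 and 1:16 casamino-acid dilutions and
their 1:1 mix — only ratios matter, absolute scale is a knob), 12
replicates per group, 48-h seasons. Measurement error is multiplicative
lognormal, σ = 0.1 on plated densities and σ = 0.05 on plate-reader
absorbances (positive, right-skewed quantities; no Poisson colony layer
since plate counts were large). Noise is median-unbiased (`exp(σZ)`), so
log-scale estimators are unbiased. CAS plates are generated from known
chelation fractions with `A_i = A_ref(1 − p)`; with noise off, every
downstream estimator returns ground truth exactly, and each generator
returns its ground truth with the table.

What the generator does *not* emulate: the empirically linear W-vs-R
relationship is only approximate here — the growth law makes ground
truth `W ≈ 1 − x²/(R·ȳ)`, mildly convex in `R`, so the midpoint contrast
|(W_high + W_low)/2 − W_int| is bounded (< 8% of W_int at defaults)
rather than zero; plate-reader artefacts, edge effects and contamination
are out of scope. Passing tests therefore demonstrate the mechanism and
the pipeline's correctness on model-generated data, not distributional
fidelity to real plate reads.

## Problem sizes

The checks run at the experiment's own scale wherever feasible: 12
pairs per arm, 2-transfer competitions across 100 simulation seeds,
20-transfer evolution runs across 100 seeds, 50 random distributions for
the soft-invariance sweep, 10 scenarios × both regimes for
trait-substitution convergence, 100-replicate designs for recovery
error, and 1e5 permutation draws per dataset for the distribution-free
null.

## Limitations

No spatial structure or siderophore diffusion; iron chemistry is not
mechanistic; relatedness is exogenous; the within-season law is invented
plumbing constrained only by the model's rate and the printed
qualitative patterns; evolutionary branching and clone-level variance
decomposition are out of scope.
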