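"""Serial-transfer metapopulation simulator and adaptive trait-substitution walk.

Mirrors the paired-microcosm design: patches (microcosms) at fixed resource
levels grow for a 48-h season, matched pairs are mixed, and a 1% bottleneck
founds the next season.  Two pooling schemes map onto the selection regimes:

* hard  -- equal-volume mixing, so a patch contributes cells in proportion
           to its final density (productivity-weighted ancestry);
* soft  -- each patch is rescaled to a common density before mixing, so
           contributions are equalised regardless of productivity.

Within a season, strain ``i`` grows at the Malthusian rate
``gamma_i = kappa * (R**a * y - x_i**2)`` where ``y`` is the
density-weighted mean investment in the patch (the public good is fully
shared in a well-mixed microcosm), with a hard ceiling ``K * R`` on total
density: carrying capacity scales with resource level.  Growth in richer
patches is faster and saturates earlier, which shortens the window over
which cheats gain on cooperators -- the positive covariance between
cooperation, productivity and resource level that hard pooling exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from coopscape.theory import (
    EssResult,
    ResourceDistribution,
    SelectionRegime,
    TraitModel,
)

__all__ = [
    "SeasonParams",
    "PatchState",
    "TransferPlan",
    "ExperimentConfig",
    "NonConvergenceError",
    "season_growth",
    "pooled_transfer",
    "run_metapopulation_experiment",
    "pool_cooperator_frequency",
    "trait_substitution_run",
]


@dataclass(frozen=True)
class SeasonParams:
    """Within-season growth parameters.

    rate_scale
        kappa, converts the dimensionless model rate ``R**a * y - x**2``
        into a per-hour Malthusian rate.
    carrying_coefficient
        K, cells/mL of ceiling per unit of resource level.
    duration_h / n_steps
        season length (hours) and Euler steps used to integrate it.
    mutation_rate
        per-division probability that a producer's offspring is a
        non-producing (x = 0) cheat; 0 disables de-novo cheats.
    """

    rate_scale: float = 32.0
    carrying_coefficient: float = 1e9
    duration_h: float = 48.0
    n_steps: int = 960
    exponent: float = 1.0
    mutation_rate: float = 0.0
    volume_ml: float = 6.0

    def __post_init__(self) -> None:
        if self.rate_scale <= 0 or self.carrying_coefficient <= 0:
            raise ValueError("rate_scale and carrying_coefficient must be positive")
        if self.duration_h <= 0 or self.n_steps < 1:
            raise ValueError("duration_h must be positive and n_steps >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class PatchState:
    """One microcosm: resource level, strain investments and densities."""

    R: float
    x: np.ndarray  # per-strain investment
    n: np.ndarray  # per-strain density, cells/mL
    season_time: float = 0.0  # elapsed fraction of the current season

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.R <= 0:
            raise ValueError(f"resource level must be positive, got {self.R}")
        if self.x.shape != self.n.shape or self.x.ndim != 1:
            raise ValueError("x and n must be 1-d arrays of equal length")
        if np.any(self.x < 0) or np.any(self.n < 0):
            raise ValueError("investments and densities must be non-negative")

    @property
    def total_density(self) -> float:
        return float(self.n.sum())

    @property
    def mean_investment(self) -> float:
        """Density-weighted mean investment = the public-good level y."""
        tot = self.total_density
        return float((self.x * self.n).sum() / tot) if tot > 0 else 0.0

    def cooperator_frequency(self, threshold: float = 0.0) -> float:
        tot = self.total_density
        if tot == 0:
            return 0.0
        return float(self.n[self.x > threshold].sum() / tot)


@dataclass(frozen=True)
class TransferPlan:
    """Pairing and pooling scheme for one serial-transfer experiment."""

    pairing: tuple[tuple[int, int], ...]
    regime: SelectionRegime
    bottleneck: float = 0.01
    n_transfers: int = 20

    def __post_init__(self) -> None:
        seen = [i for pair in self.pairing for i in pair]
        if len(set(seen)) != len(seen):
            raise ValueError("every patch index may appear in exactly one pair")
        if not (0.0 < self.bottleneck < 1.0):
            raise ValueError("bottleneck fraction must lie in (0, 1)")
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")


def _grow_many(
    R: np.ndarray,
    x: np.ndarray,
    N: np.ndarray,
    params: SeasonParams,
    duration: float | None = None,
) -> np.ndarray:
    """Integrate one season for many patches sharing a strain list.

    ``R``: (P,) resource levels; ``x``: (S,) investments; ``N``: (P, S)
    densities.  Fixed-step Euler on log-densities with ``y`` recomputed
    each step per patch; a patch stops growing once its total reaches
    ``K * R`` (truncated at the ceiling, preserving within-step
    composition).  When mutation is enabled the caller must provide an
    x = 0 strain slot; a fraction ``mu`` of every producer's births lands
    there.  Returns the (P, S) end-of-season densities.
    """
    if duration is None:
        duration = params.duration_h
    N = N.astype(float).copy()
    totals = N.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("cannot grow a patch with an all-zero inoculum")
    mu = params.mutation_rate
    cheat_slot = -1
    if mu > 0:
        zero = np.flatnonzero(x == 0.0)
        if zero.size == 0:
            raise ValueError(
                "mutation_rate > 0 requires an x = 0 strain slot"
            )
        cheat_slot = int(zero[0])
    cap = params.carrying_coefficient * R
    dt = duration / params.n_steps
    kappa = params.rate_scale
    Ra = R**params.exponent
    cost = x**2
    active = totals < cap
    for _ in range(params.n_steps):
        if not np.any(active):
            break
        sub = N[active]
        y = (sub @ x) / sub.sum(axis=1)
        gamma = kappa * (Ra[active, None] * y[:, None] - cost[None, :])
        new_sub = sub * np.exp(gamma * dt)
        if mu > 0:
            births = np.clip(new_sub - sub, 0.0, None)
            births[:, x == 0.0] = 0.0
            flux = mu * births
            new_sub = new_sub - flux
            new_sub[:, cheat_slot] += flux.sum(axis=1)
        new_tot = new_sub.sum(axis=1)
        over = new_tot > cap[active]
        if np.any(over):
            new_sub[over] *= (cap[active][over] / new_tot[over])[:, None]
        N[active] = new_sub
        still = np.array(active)
        still[active] = ~over
        active = still
    return N


def season_growth(
    patch: PatchState, params: SeasonParams, duration: float | None = None
) -> PatchState:
    """Grow one patch for a season and return the end-of-season state.

    Fixed-step Euler on log-densities; the public-good level ``y`` is
    recomputed each step as frequencies shift.  Growth is truncated once
    total density reaches the ceiling ``K * R``.  When mutation is enabled,
    a fraction ``mu`` of every producer's births is diverted to an x = 0
    cheat strain.
    """
    x = patch.x.copy()
    n = patch.n.copy()
    if params.mutation_rate > 0 and not np.any(x == 0.0):
        x = np.append(x, 0.0)
        n = np.append(n, 0.0)
    N = _grow_many(np.array([patch.R]), x, n[None, :], params, duration)
    return PatchState(R=patch.R, x=x, n=N[0], season_time=1.0)


def _pool(pa: PatchState, pb: PatchState, regime: SelectionRegime) -> np.ndarray:
    """Per-strain densities of the mixed pool (strain lists must align)."""
    if pa.x.shape != pb.x.shape or not np.allclose(pa.x, pb.x):
        raise ValueError("paired patches must share the same strain list")
    ta, tb = pa.total_density, pb.total_density
    if ta + tb <= 0:
        raise ValueError("cannot pool two empty patches")
    if regime is SelectionRegime.HARD:
        # equal-volume mix: contribution proportional to final density
        return (pa.n + pb.n) / 2.0
    # soft: rescale each patch to the common mean density, then mix
    target = (ta + tb) / 2.0
    na = pa.n * (target / ta) if ta > 0 else pa.n
    nb = pb.n * (target / tb) if tb > 0 else pb.n
    return (na + nb) / 2.0


def pooled_transfer(
    pa: PatchState,
    pb: PatchState,
    plan: TransferPlan,
    rng: np.random.Generator | None = None,
    volume_ml: float = 6.0,
) -> tuple[PatchState, PatchState]:
    """Mix a matched pair per the pooling scheme and found two fresh patches.

    Fresh patches keep the pair's resource levels; each receives the
    bottleneck fraction of the pool.  With ``rng`` given, founder cells are
    drawn multinomially from the pool composition (demographic sampling at
    the bottleneck); otherwise exact fractional densities are used.
    """
    pool = _pool(pa, pb, SelectionRegime.coerce(plan.regime))
    inoc = plan.bottleneck * pool
    if rng is not None:
        total_cells = inoc.sum() * volume_ml
        n_found = int(rng.poisson(total_cells))
        if n_found > 0 and pool.sum() > 0:
            counts = rng.multinomial(n_found, pool / pool.sum())
            inoc = counts / volume_ml
    fresh_a = PatchState(R=pa.R, x=pa.x.copy(), n=inoc.copy())
    fresh_b = PatchState(R=pb.R, x=pb.x.copy(), n=inoc.copy())
    return fresh_a, fresh_b


@dataclass(frozen=True)
class ExperimentConfig:
    """A full serial-transfer experiment over matched pairs of patches.

    ``pairs`` lists the (R_a, R_b) resource levels of each matched pair --
    e.g. 12 x (high, low) for the heterogeneous arm, 12 x (intermediate,
    intermediate) for the homogeneous arm.  Every patch starts with the
    same strain inocula.
    """

    pairs: tuple[tuple[float, float], ...]
    strains: tuple[tuple[float, float], ...]  # (investment x, density)
    regime: SelectionRegime
    n_transfers: int = 2
    bottleneck: float = 0.01
    season: SeasonParams = field(default_factory=SeasonParams)
    stochastic: bool = False

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("at least one pair of patches is required")
        if not self.strains:
            raise ValueError("at least one strain is required")
        if any(R <= 0 for pair in self.pairs for R in pair):
            raise ValueError("all resource levels must be positive")
        if any(x < 0 or n < 0 for x, n in self.strains):
            raise ValueError("strain investments and densities must be >= 0")
        if not (0.0 < self.bottleneck < 1.0):
            raise ValueError("bottleneck fraction must lie in (0, 1)")
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")

    @property
    def mean_resource(self) -> float:
        flat = [R for pair in self.pairs for R in pair]
        return float(np.mean(flat))


def run_metapopulation_experiment(
    config: ExperimentConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a serial-transfer experiment; deterministic given (config, seed).

    Returns ``(patches, pools)``:

    * ``patches`` -- one row per pair x transfer x patch x strain with the
      end-of-season density;
    * ``pools`` -- one row per pair x transfer x strain with the strain's
      fraction of the mixed pool (the evolutionarily relevant composition
      that seeds the next season).
    """
    rng = np.random.default_rng(seed) if config.stochastic else None
    regime = SelectionRegime.coerce(config.regime)
    x = np.array([xs for xs, _ in config.strains], dtype=float)
    n0 = np.array([ns for _, ns in config.strains], dtype=float)
    if config.season.mutation_rate > 0 and not np.any(x == 0.0):
        x = np.append(x, 0.0)
        n0 = np.append(n0, 0.0)
    n_pairs = len(config.pairs)
    R = np.array([Rv for pair in config.pairs for Rv in pair], dtype=float)
    N = np.tile(n0, (2 * n_pairs, 1))
    volume = config.season.volume_ml

    patch_rows: list[dict] = []
    pool_rows: list[dict] = []
    for transfer in range(1, config.n_transfers + 1):
        N = _grow_many(R, x, N, config.season)
        tot = N.sum(axis=1)
        if np.any(tot[0::2] + tot[1::2] <= 0):
            raise ValueError("cannot pool two empty patches")
        if regime is SelectionRegime.HARD:
            pools = 0.5 * (N[0::2] + N[1::2])  # equal-volume mix
        else:
            target = 0.5 * (tot[0::2] + tot[1::2])
            scaled = N * np.where(tot > 0, 1.0 / tot, 0.0)[:, None]
            pools = 0.5 * (scaled[0::2] + scaled[1::2]) * target[:, None]
        for pair_id in range(n_pairs):
            for patch_idx in (0, 1):
                row = 2 * pair_id + patch_idx
                for xi, ni in zip(x, N[row]):
                    patch_rows.append(
                        dict(pair=pair_id, transfer=transfer, patch=patch_idx,
                             R=float(R[row]), x=float(xi), density=float(ni))
                    )
            ptot = pools[pair_id].sum()
            for xi, ni in zip(x, pools[pair_id]):
                pool_rows.append(
                    dict(pair=pair_id, transfer=transfer, x=float(xi),
                         fraction=float(ni / ptot) if ptot > 0 else 0.0)
                )
        if transfer < config.n_transfers:
            inocula = config.bottleneck * pools
            if rng is not None:
                for pair_id in range(n_pairs):
                    cells = inocula[pair_id].sum() * volume
                    ptot = pools[pair_id].sum()
                    n_found = int(rng.poisson(cells))
                    if n_found > 0 and ptot > 0:
                        counts = rng.multinomial(n_found, pools[pair_id] / ptot)
                        inocula[pair_id] = counts / volume
                    else:
                        inocula[pair_id] = 0.0
            N = np.repeat(inocula, 2, axis=0)
            if np.any(N.sum(axis=1) <= 0):
                raise ValueError(
                    f"metapopulation extinct at transfer {transfer}: "
                    "a bottleneck founded no cells"
                )
    return pd.DataFrame(patch_rows), pd.DataFrame(pool_rows)


def pool_cooperator_frequency(
    pools: pd.DataFrame, transfer: int | None = None
) -> float:
    """Mean pooled producer (x > 0) frequency across pairs at a transfer."""
    t = pools["transfer"].max() if transfer is None else transfer
    sub = pools[pools["transfer"] == t]
    per_pair = (
        sub.assign(coop=lambda d: d["fraction"].where(d["x"] > 0, 0.0))
        .groupby("pair")["coop"].sum()
    )
    return float(per_pair.mean())


class NonConvergenceError(RuntimeError):
    """Trait-substitution walk exhausted max_iter; trajectory attached."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


def _invasion_score(
    dist: ResourceDistribution,
    model: TraitModel,
    regime: SelectionRegime,
    z_res: float,
    z_mut: float,
) -> float:
    """Ancestry-weighted relative fitness of a rare mutant, minus one.

    The mutant experiences neighbour siderophore availability
    ``y = r * z_mut + (1 - r) * z_res`` (relatedness as the slope dy/dx),
    so its within-patch fitness ratio is
    ``exp(R**a * r * (z_mut - z_res) - (z_mut**2 - z_res**2))``.
    """
    a, r = model.a, model.r
    dz = z_mut - z_res
    dc = z_mut**2 - z_res**2

    def ratio(R: float) -> float:
        return math.exp(R**a * r * dz - dc)

    if regime is SelectionRegime.SOFT:
        return dist.expect(ratio) - 1.0
    wbar = dist.expect(lambda R: math.exp(R**a * z_res - z_res**2))
    num = dist.expect(
        lambda R: math.exp(R**a * z_res - z_res**2) * ratio(R)
    )
    return num / wbar - 1.0


def trait_substitution_run(
    dist: ResourceDistribution,
    model: TraitModel,
    regime: SelectionRegime | str,
    z0: float = 0.0,
    step: float = 0.01,
    max_iter: int = 100_000,
    seed: int | None = None,
) -> tuple[list[float], float]:
    """Iterated invasion-substitution walk on the investment trait.

    From resident ``z`` propose mutants at ``z + step`` and ``z - step``;
    the resident is replaced by an invading mutant (positive
    ancestry-weighted invasion score), preferring the stronger invader.
    Terminates when neither direction invades, which happens within one
    step of the selection-gradient root because the quadratic investment
    cost penalises both directions there.  Returns (trajectory, z_final).
    """
    if step <= 0:
        raise ValueError("mutation step must be positive")
    if z0 < 0:
        raise ValueError("initial investment must be >= 0")
    regime = SelectionRegime.coerce(regime)
    rng = np.random.default_rng(seed)
    z = float(z0)
    trajectory = [z]
    for _ in range(max_iter):
        candidates = [z + step]
        if z - step >= 0.0:
            candidates.append(z - step)
        scores = [_invasion_score(dist, model, regime, z, zc) for zc in candidates]
        best = int(np.argmax(scores))
        if len(scores) == 2 and scores[0] == scores[1]:
            best = int(rng.integers(0, 2))  # exact tie: random direction
        if scores[best] <= 0.0:
            return trajectory, z
        z_new = candidates[best]
        if len(trajectory) >= 2 and z_new == trajectory[-2]:
            return trajectory, z  # two-cycle straddling the root
        z = z_new
        trajectory.append(z)
    raise NonConvergenceError(
        f"no equilibrium within {max_iter} substitutions (last z={z})",
        trajectory,
    )


def theoretical_ess(
    dist: ResourceDistribution,
    model: TraitModel,
    regime: SelectionRegime | str,
    tol: float = 1e-10,
) -> EssResult:
    """Convenience re-export of the numeric ESS the walk should reach."""
    from coopscape.theory import ess_solve

    return ess_solve(dist, model, regime, tol=tol)
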