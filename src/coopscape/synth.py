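"""Synthetic assay data with known ground truth.

Generates everything the analysis pipeline consumes, with no external data:
single-patch competition count tables, metapopulation experiment
configurations, and CAS plate tables.  The defaults emulate the wet-lab
design: three media whose resource levels follow the casamino-acid dilution
fractions (high 1:4 -> 1.0, low 1:16 -> 0.25, intermediate their 1:1 mix ->
0.625, on a relative scale), 12 replicates per group, 48-h seasons, and
multiplicative lognormal noise on plated densities (sigma_log = 0.1) and
plate-reader absorbances (sigma_log = 0.05).

Noise-free output round-trips exactly through the assay estimators, so every
generator returns its ground truth alongside the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coopscape.metapop import (
    ExperimentConfig,
    PatchState,
    SeasonParams,
    season_growth,
)
from coopscape.theory import SelectionRegime

__all__ = [
    "SyntheticDesign",
    "gen_competition_counts",
    "gen_metapop_config",
    "gen_cas_plate",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design mirrored by every generator.

    media
        label -> relative resource level; defaults follow the 1:4 / 1:1-mix
        / 1:16 dilution series (1.0, 0.625, 0.25).
    cooperator_investment
        the producer strain's siderophore investment x; the cheat's is 0.
        Calibrated jointly with the season parameters so that within-patch
        cooperator relative fitness spans roughly 0.8-0.96 across the media
        (all below 1, increasing with resource level) and densities rise
        with resource level.
    inoculum_density
        starting density of each strain, cells/mL.
    sigma_density / sigma_absorbance
        sigma of the multiplicative lognormal measurement error applied to
        densities (plating) and absorbances (plate reader).
    """

    media: tuple[tuple[str, float], ...] = (
        ("high", 1.0),
        ("intermediate", 0.625),
        ("low", 0.25),
    )
    replicates: int = 12
    cooperator_investment: float = 0.02
    inoculum_density: float = 5e5
    season: SeasonParams = field(default_factory=SeasonParams)
    sigma_density: float = 0.1
    sigma_absorbance: float = 0.05
    cas_reference_absorbance: float = 0.8
    cas_od600: float = 0.05
    cas_dilution: float = 10.0
    cas_wt_chelation: float = 0.6  # chelation fraction of the ancestral producer

    def __post_init__(self) -> None:
        levels = dict(self.media)
        if set(levels) != {"high", "intermediate", "low"}:
            raise ValueError("media must define high, intermediate and low")
        if not (levels["high"] > levels["intermediate"] > levels["low"] > 0):
            raise ValueError("media levels must be ordered high > intermediate > low > 0")
        if self.replicates < 2:
            raise ValueError("need at least two replicates per group")
        if self.cooperator_investment <= 0 or self.inoculum_density <= 0:
            raise ValueError("cooperator investment and inoculum must be positive")
        if self.sigma_density < 0 or self.sigma_absorbance < 0:
            raise ValueError("noise sigmas must be non-negative")

    @property
    def levels(self) -> dict[str, float]:
        return dict(self.media)


def _noise(rng: np.random.Generator, sigma: float, size=None) -> np.ndarray:
    """Median-unbiased multiplicative lognormal error factor."""
    if sigma == 0.0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(sigma * rng.standard_normal(size))


def gen_competition_counts(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Single-patch cooperator-vs-cheat competition counts for each media.

    One 48-h season per media via the within-patch growth model; per
    replicate, every plated density carries independent multiplicative
    lognormal error.  Ground truth holds the noise-free Malthusian
    parameters and relative fitness per media.
    """
    rng = np.random.default_rng(seed)
    xc = design.cooperator_investment
    n0 = design.inoculum_density
    truth: dict = {"W": {}, "m_cooperator": {}, "m_cheat": {}, "end_density": {}}
    rows = []
    for label, R in design.media:
        patch = PatchState(R=R, x=np.array([xc, 0.0]), n=np.array([n0, n0]))
        grown = season_growth(patch, design.season)
        m_c = math.log(grown.n[0] / n0)
        m_ch = math.log(grown.n[1] / n0)
        truth["W"][label] = m_c / m_ch
        truth["m_cooperator"][label] = m_c
        truth["m_cheat"][label] = m_ch
        truth["end_density"][label] = float(grown.total_density)
        for rep in range(design.replicates):
            for strain, n_start, n_end in (
                ("cooperator", n0, grown.n[0]),
                ("cheat", n0, grown.n[1]),
            ):
                for timepoint, dens in (("start", n_start), ("end", n_end)):
                    rows.append(
                        dict(
                            replicate=f"{label}_{rep:02d}",
                            media=label,
                            strain=strain,
                            timepoint=timepoint,
                            density=float(dens * _noise(rng, design.sigma_density)),
                        )
                    )
    return pd.DataFrame(rows), truth


def gen_metapop_config(
    design: SyntheticDesign,
    treatment: str,
    regime: SelectionRegime | str = SelectionRegime.HARD,
    n_transfers: int = 2,
    n_pairs: int | None = None,
    stochastic: bool = False,
    mutation_rate: float = 0.0,
    pure_cooperator: bool = False,
) -> ExperimentConfig:
    """Simulator configuration for one treatment arm.

    ``heterogeneous`` pairs (high, low); ``homogeneous`` pairs
    (intermediate, intermediate).  Mean resource level is identical across
    arms by construction.  ``pure_cooperator`` starts patches from the
    producer strain only (the evolution-experiment design, where cheats
    arise de novo via ``mutation_rate``).
    """
    if treatment not in ("heterogeneous", "homogeneous"):
        raise ValueError(
            f"treatment must be 'heterogeneous' or 'homogeneous', got {treatment!r}"
        )
    levels = design.levels
    n_pairs = design.replicates if n_pairs is None else n_pairs
    if treatment == "heterogeneous":
        pairs = ((levels["high"], levels["low"]),) * n_pairs
    else:
        pairs = ((levels["intermediate"], levels["intermediate"]),) * n_pairs
    xc = design.cooperator_investment
    n0 = design.inoculum_density
    if pure_cooperator:
        strains: tuple[tuple[float, float], ...] = ((xc, 2 * n0),)
    else:
        strains = ((xc, n0), (0.0, n0))
    season = design.season
    if mutation_rate != season.mutation_rate:
        from dataclasses import replace

        season = replace(season, mutation_rate=mutation_rate)
    return ExperimentConfig(
        pairs=pairs,
        strains=strains,
        regime=SelectionRegime.coerce(regime),
        n_transfers=n_transfers,
        season=season,
        stochastic=stochastic,
    )


def gen_cas_plate(
    production: dict[str, list[float]] | dict[str, np.ndarray],
    design: SyntheticDesign,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """CAS plate table for populations with known chelation fractions.

    ``production`` maps population label -> chelation fractions in [0, 1]
    (one per sample).  The sample absorbance is
    ``A_i = A_ref * (1 - p)`` with multiplicative noise on ``A_i`` and on
    the diluted OD600.  Ground truth holds the noise-free per-capita
    activity ``p / (OD600 * dilution)`` per sample.
    """
    rng = np.random.default_rng(seed)
    a_ref = design.cas_reference_absorbance
    od = design.cas_od600
    dil = design.cas_dilution
    rows = []
    truth: dict = {"activity": {}}
    for pop, values in production.items():
        values = np.asarray(values, dtype=float)
        if np.any((values < 0) | (values > 1)):
            raise ValueError(
                f"chelation fractions for {pop!r} must lie in [0, 1]"
            )
        truth["activity"][pop] = [float(p / (od * dil)) for p in values]
        for i, p in enumerate(values):
            rows.append(
                dict(
                    population=pop,
                    sample=i,
                    a_i=float(a_ref * (1.0 - p) * _noise(rng, design.sigma_absorbance)),
                    a_ref=a_ref,
                    od600=float(od * _noise(rng, design.sigma_absorbance)),
                    dilution=dil,
                )
            )
    return pd.DataFrame(rows), truth
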