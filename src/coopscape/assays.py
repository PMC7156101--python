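"""Experimental read-out computations for competition and CAS assay data.

Covers the three quantities the wet-lab protocol produces:

* the Malthusian parameter ``m = ln(n_end / n_start)`` of a strain over a
  growth period, and cooperator relative fitness ``W = m_coop / m_cheat``;
* per-capita iron-chelator (CAS) activity,
  ``(1 - A_i / A_ref) / (OD600 * dilution)`` -- the chelation fraction of
  the sample normalised by its back-calculated undiluted density;
* the routine comparison statistics: one-way ANOVA, Tukey-HSD post hoc
  contrasts and one-sample t-tests (two-sided, alpha = 0.05 conventions).

Tabular pipelines consume tidy delimited tables (one row per replicate x
strain x timepoint for competition; one row per sample for CAS) and emit
per-replicate estimates plus test summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CASRecord",
    "FitnessEstimate",
    "malthusian",
    "relative_fitness",
    "per_capita_cas",
    "one_way_anova",
    "tukey_hsd",
    "one_sample_t",
    "analyze_competition",
    "analyze_cas",
    "competition_test_summary",
]


@dataclass(frozen=True)
class CASRecord:
    """One CAS plate read: sample and reference absorbance at 630 nm plus
    the OD600 of the diluted sample."""

    a_i: float
    a_ref: float
    od600: float
    dilution: float = 10.0

    def __post_init__(self) -> None:
        if self.a_ref <= 0:
            raise ValueError("reference absorbance must be positive")
        if self.od600 <= 0:
            raise ValueError("OD600 must be positive")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.a_i < 0:
            raise ValueError("sample absorbance must be non-negative")


@dataclass(frozen=True)
class FitnessEstimate:
    replicate: str
    m_cooperator: float
    m_cheat: float
    W: float


def malthusian(n_start: float, n_end: float) -> float:
    """Malthusian parameter ``ln(n_end / n_start)`` over one growth period."""
    if n_start <= 0 or n_end <= 0:
        raise ValueError(
            f"densities must be positive, got start={n_start}, end={n_end}"
        )
    return math.log(n_end / n_start)


def relative_fitness(m_coop: float, m_cheat: float) -> float:
    """Cooperator relative fitness ``W = m_coop / m_cheat``.

    ``W < 1`` (with both rates positive) means the cheat outgrew the
    cooperator over the assay period.
    """
    if m_cheat == 0:
        raise ZeroDivisionError(
            "relative fitness undefined: cheat Malthusian parameter is zero"
        )
    return m_coop / m_cheat


def per_capita_cas(rec: CASRecord) -> float:
    """Per-capita iron-chelator activity of one sample.

    The chelation fraction ``1 - A_i / A_ref`` (loss of CAS absorbance at
    630 nm relative to sterile medium) divided by the undiluted culture
    density, back-calculated as ``OD600 * dilution`` from the diluted read.
    """
    return (1.0 - rec.a_i / rec.a_ref) / (rec.od600 * rec.dilution)


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    pooled_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if pooled_within == 0.0:
        raise ValueError("zero within-group variance: F statistic undefined")
    return arrays


def one_way_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns ``(F, df_between, df_within, p)``."""
    arrays = _validate_groups(groups)
    f, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    return float(f), df_between, df_within, float(p)


def tukey_hsd(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise contrasts.

    Returns a table with one row per unordered pair of groups:
    mean difference, studentized-range adjusted p-value, and the group
    indices compared.
    """
    arrays = _validate_groups(groups)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        rows.append(
            dict(
                group_a=i,
                group_b=j,
                mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                p_adj=float(res.pvalue[i, j]),
            )
        )
    return pd.DataFrame(rows)


def one_sample_t(
    values: Sequence[float], mu0: float
) -> tuple[float, int, float]:
    """Two-sided one-sample t-test; returns ``(t, df, p)``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    if np.allclose(arr, arr[0]):
        raise ValueError("zero sample variance: t statistic undefined")
    res = stats.ttest_1samp(arr, mu0)
    return float(res.statistic), int(arr.size - 1), float(res.pvalue)


# -- tabular pipelines ---------------------------------------------------------

_COMP_COLUMNS = {"replicate", "media", "strain", "timepoint", "density"}


def analyze_competition(
    counts: pd.DataFrame,
    cooperator: str = "cooperator",
    cheat: str = "cheat",
) -> pd.DataFrame:
    """Per-replicate fitness estimates from a tidy competition count table.

    Expects columns (replicate, media, strain, timepoint, density) with
    timepoint in {'start', 'end'}; returns one row per replicate with
    ``m_cooperator``, ``m_cheat`` and ``W``.
    """
    missing = _COMP_COLUMNS - set(counts.columns)
    if missing:
        raise ValueError(f"competition table missing columns: {sorted(missing)}")
    if (counts["density"] <= 0).any():
        raise ValueError(
            "non-positive density in competition table; zero colony counts "
            "are rejected rather than pseudocounted"
        )
    wide = counts.pivot_table(
        index=["media", "replicate"],
        columns=["strain", "timepoint"],
        values="density",
    )
    rows = []
    for (media, rep), row in wide.iterrows():
        m_c = malthusian(row[(cooperator, "start")], row[(cooperator, "end")])
        m_ch = malthusian(row[(cheat, "start")], row[(cheat, "end")])
        rows.append(
            dict(media=media, replicate=rep, m_cooperator=m_c, m_cheat=m_ch,
                 W=relative_fitness(m_c, m_ch))
        )
    return pd.DataFrame(rows)


def competition_test_summary(
    fitness_table: pd.DataFrame, order: Sequence[str] | None = None
) -> dict:
    """ANOVA across media, Tukey contrasts, and per-media t-tests vs W = 1."""
    media = list(order) if order else sorted(fitness_table["media"].unique())
    groups = [
        fitness_table.loc[fitness_table["media"] == m, "W"].to_numpy()
        for m in media
    ]
    f, dfb, dfw, p = one_way_anova(groups)
    tukey = tukey_hsd(groups)
    tukey["group_a"] = [media[i] for i in tukey["group_a"]]
    tukey["group_b"] = [media[i] for i in tukey["group_b"]]
    t_vs_one = {
        m: dict(zip(("t", "df", "p"), one_sample_t(g, 1.0)))
        for m, g in zip(media, groups)
    }
    return dict(
        media=media,
        anova=dict(F=f, df_between=dfb, df_within=dfw, p=p),
        tukey=tukey,
        t_vs_one=t_vs_one,
        mean_W={m: float(np.mean(g)) for m, g in zip(media, groups)},
    )


_CAS_COLUMNS = {"population", "a_i", "a_ref", "od600", "dilution"}


def analyze_cas(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-capita chelator activity from a tidy CAS table.

    Expects columns (population, a_i, a_ref, od600, dilution); extra
    columns (e.g. clone identifiers, treatment labels) pass through.
    """
    missing = _CAS_COLUMNS - set(plate.columns)
    if missing:
        raise ValueError(f"CAS table missing columns: {sorted(missing)}")
    out = plate.copy()
    out["activity"] = [
        per_capita_cas(
            CASRecord(a_i=row.a_i, a_ref=row.a_ref, od600=row.od600,
                      dilution=row.dilution)
        )
        for row in plate.itertuples()
    ]
    return out
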