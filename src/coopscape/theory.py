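"""Evolutionarily stable siderophore investment in single patches and metapopulations.

The model: a cell growing at basic rate ``gamma = R**a * y - x**2``, where
``R`` is local resource availability, ``y`` the siderophore availability it
experiences (the average production of its neighbours), ``x`` its own
investment, and ``a`` an exponent allowing nonlinear returns of resources on
growth.  Fitness is ``w_R = exp(gamma)``.  Relatedness ``r`` is the
regression slope dy/dx of neighbour production on focal production, so the
marginal gradient of relative fitness at a monomorphic resident ``z`` is
``R**a * r - 2 z``, vanishing at the single-patch ESS ``z* = r R**a / 2``.

In a metapopulation with resource density ``p_R``, selection integrates the
within-patch gradient against ancestry weights ``c_R``: under *soft*
selection every patch contributes equally (``c_R = p_R``); under *hard*
selection patches contribute in proportion to their mean fitness
(``c_R = p_R * wbar_R / wbar``).  Hard selection therefore overweights
resource-rich, cooperation-favouring patches and pushes the ESS above the
soft-selection value ``r E[R**a] / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "TraitModel",
    "ResourceDistribution",
    "SelectionRegime",
    "EssResult",
    "QuadratureError",
    "growth_rate",
    "fitness",
    "mean_fitness",
    "selection_gradient",
    "single_patch_ess",
    "metapop_gradient",
    "ess_solve",
    "ess_approx",
]

_MOMENT_TOL = 1e-9


class SelectionRegime(str, Enum):
    """How patches contribute ancestry to the next generation.

    ``SOFT``: every patch contributes equally, regardless of productivity.
    ``HARD``: contribution is proportional to the patch's mean fitness.
    """

    SOFT = "soft"
    HARD = "hard"

    @classmethod
    def coerce(cls, value: "SelectionRegime | str") -> "SelectionRegime":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown selection regime {value!r}; expected 'soft' or 'hard'"
            ) from None


class QuadratureError(RuntimeError):
    """Raised when numeric integration over the resource density fails."""


@dataclass(frozen=True)
class TraitModel:
    """Trait-level parameters: relatedness ``r`` and resource exponent ``a``.

    ``r`` is the slope dy/dx of neighbour siderophore production on focal
    production (a supplied regression coefficient, not derived from
    demography).  ``a`` bends the resource-benefit relationship:
    ``a < 1`` diminishing returns, ``a = 1`` linear, ``a > 1`` accelerating.
    """

    r: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise ValueError(f"relatedness r must lie in [0, 1], got {self.r}")
        if not self.a > 0.0:
            raise ValueError(f"resource exponent a must be positive, got {self.a}")


@dataclass(frozen=True)
class ResourceDistribution:
    """Distribution ``p_R`` of resource availability across patches.

    Either a finite set of atoms ``(R, weight)`` (the experimental case:
    paired high/low microcosms) or a continuous density on ``[rmin, rmax]``.
    Moments are computed from the support; construction validates that
    weights are non-negative and normalised.
    """

    atoms: tuple[tuple[float, float], ...] | None = None
    density: Callable[[float], float] | None = field(default=None, compare=False)
    rmin: float = 0.0
    rmax: float = 0.0

    def __post_init__(self) -> None:
        if (self.atoms is None) == (self.density is None):
            raise ValueError("provide exactly one of atoms= or density=")
        if self.atoms is not None:
            if len(self.atoms) == 0:
                raise ValueError("atomic support must be non-empty")
            rs = np.array([R for R, _ in self.atoms], dtype=float)
            ws = np.array([w for _, w in self.atoms], dtype=float)
            if np.any(rs <= 0.0):
                raise ValueError("all resource levels must be positive")
            if np.any(ws < 0.0):
                raise ValueError("atom weights must be non-negative")
            total = float(ws.sum())
            if abs(total - 1.0) > _MOMENT_TOL:
                raise ValueError(f"atom weights must sum to 1, got {total}")
            object.__setattr__(self, "rmin", float(rs.min()))
            object.__setattr__(self, "rmax", float(rs.max()))
        else:
            if not (0.0 < self.rmin < self.rmax):
                raise ValueError("continuous support needs 0 < rmin < rmax")
            total = self._quad(lambda R: self.density(R))
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"density must integrate to 1, got {total}")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_atoms(
        cls, pairs: Iterable[tuple[float, float]]
    ) -> "ResourceDistribution":
        """Finite support from ``(R, weight)`` pairs (weights renormalised)."""
        pairs = [(float(R), float(w)) for R, w in pairs]
        total = sum(w for _, w in pairs)
        if total <= 0:
            raise ValueError("total weight must be positive")
        return cls(atoms=tuple((R, w / total) for R, w in pairs))

    @classmethod
    def two_point(cls, r_low: float, r_high: float, p_high: float = 0.5):
        """The paired-microcosm case: two resource levels."""
        return cls.from_atoms([(r_low, 1.0 - p_high), (r_high, p_high)])

    @classmethod
    def degenerate(cls, R: float) -> "ResourceDistribution":
        return cls.from_atoms([(R, 1.0)])

    @classmethod
    def from_density(
        cls, pdf: Callable[[float], float], rmin: float, rmax: float
    ) -> "ResourceDistribution":
        return cls(density=pdf, rmin=rmin, rmax=rmax)

    # -- expectation machinery ------------------------------------------------

    def _quad(self, integrand: Callable[[float], float]) -> float:
        try:
            value, err = integrate.quad(
                integrand, self.rmin, self.rmax, epsabs=1e-12, epsrel=1e-10, limit=200
            )
        except Exception as exc:  # pragma: no cover - scipy raises rarely
            raise QuadratureError(
                f"quadrature failed on [{self.rmin}, {self.rmax}]: {exc}"
            ) from exc
        if not math.isfinite(value):
            raise QuadratureError(
                f"non-finite integral on [{self.rmin}, {self.rmax}]"
            )
        return value

    def expect(self, func: Callable[[float], float]) -> float:
        """E[func(R)] under ``p_R`` (exact weighted sum on atoms)."""
        if self.atoms is not None:
            return float(sum(w * func(R) for R, w in self.atoms))
        return self._quad(lambda R: self.density(R) * func(R))

    @property
    def mean(self) -> float:
        return self.expect(lambda R: R)

    @property
    def variance(self) -> float:
        mu = self.mean
        return self.expect(lambda R: (R - mu) ** 2)


@dataclass(frozen=True)
class EssResult:
    """An equilibrium investment level and how it was obtained."""

    z_star: float
    method: str  # closed_form | first_order_approx | numeric_root
    residual_gradient: float = 0.0

    def __post_init__(self) -> None:
        if self.z_star < 0:
            raise ValueError("ESS investment must be non-negative")


# -- within-patch primitives ---------------------------------------------------


def _check_domain(R: float, a: float) -> None:
    if not R > 0:
        raise ValueError(f"resource level R must be positive, got {R}")
    if not a > 0:
        raise ValueError(f"exponent a must be positive, got {a}")


def growth_rate(R: float, y: float, x: float, a: float = 1.0) -> float:
    """Basic growth rate ``gamma = R**a * y - x**2``.

    Benefit is proportional to resources and to ambient siderophore ``y``;
    the cost of own investment ``x`` accelerates quadratically.
    """
    _check_domain(R, a)
    if y < 0:
        raise ValueError(f"siderophore availability y must be >= 0, got {y}")
    if x < 0:
        raise ValueError(f"investment x must be >= 0, got {x}")
    return R**a * y - x**2


def fitness(R: float, y: float, x: float, a: float = 1.0) -> float:
    """Absolute fitness ``w_R = exp(R**a * y - x**2)``."""
    return math.exp(growth_rate(R, y, x, a))


def mean_fitness(R: float, z: float, a: float = 1.0) -> float:
    """Mean fitness of a monomorphic resident: ``exp(R**a z - z**2)``."""
    return fitness(R, z, z, a)


def selection_gradient(R: float, r: float, z: float, a: float = 1.0) -> float:
    """Marginal relative-fitness gradient ``dW_R/dx`` at ``x = y = z``.

    By the chain rule with dy/dx = r this is ``R**a * r - 2 z``; its sign
    gives the direction of selection on investment within a patch.
    """
    _check_domain(R, a)
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"relatedness r must lie in [0, 1], got {r}")
    if z < 0:
        raise ValueError(f"resident investment z must be >= 0, got {z}")
    return R**a * r - 2.0 * z


def single_patch_ess(R: float, r: float, a: float = 1.0) -> EssResult:
    """Closed-form single-patch ESS ``z* = r R**a / 2``."""
    _check_domain(R, a)
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"relatedness r must lie in [0, 1], got {r}")
    z = r * R**a / 2.0
    return EssResult(z_star=z, method="closed_form",
                     residual_gradient=selection_gradient(R, r, z, a))


# -- metapopulation gradient and solvers --------------------------------------


def metapop_gradient(
    dist: ResourceDistribution,
    model: TraitModel,
    z: float,
    regime: SelectionRegime | str,
) -> float:
    """Ancestry-weighted selection gradient ``int c_R (dW_R/dx) dR``.

    Soft selection: ``c_R = p_R`` so the gradient is ``E[R**a] r - 2 z``.
    Hard selection: ``c_R = p_R wbar_R / wbar`` with
    ``wbar_R = exp(R**a z - z**2)``; returned in the wbar-normalised form
    (normalisation rescales but never moves the root, since wbar > 0).
    """
    if z < 0:
        raise ValueError(f"resident investment z must be >= 0, got {z}")
    regime = SelectionRegime.coerce(regime)
    a, r = model.a, model.r
    if regime is SelectionRegime.SOFT:
        return dist.expect(lambda R: R**a) * r - 2.0 * z

    def weighted(R: float) -> float:
        return mean_fitness(R, z, a) * (R**a * r - 2.0 * z)

    num = dist.expect(weighted)
    den = dist.expect(lambda R: mean_fitness(R, z, a))
    if not (math.isfinite(num) and math.isfinite(den)) or den <= 0:
        raise QuadratureError(
            f"hard-selection gradient ill-conditioned at z={z}: "
            f"numerator={num}, mean fitness={den}"
        )
    return num / den


def ess_solve(
    dist: ResourceDistribution,
    model: TraitModel,
    regime: SelectionRegime | str,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-10,
) -> EssResult:
    """Numeric root of the metapopulation gradient.

    The default bracket is ``[0, r * rmax**a]``: the gradient is
    ``>= 0`` at 0 and strictly negative at the upper end because the
    weighted integrand ``R**a r - 2 z`` is everywhere below
    ``rmax**a r - 2 z``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    regime = SelectionRegime.coerce(regime)
    if model.r == 0.0:
        return EssResult(0.0, "numeric_root",
                         metapop_gradient(dist, model, 0.0, regime))
    if bracket is None:
        bracket = (0.0, model.r * dist.rmax**model.a)
    lo, hi = bracket
    g = lambda z: metapop_gradient(dist, model, z, regime)
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return EssResult(lo, "numeric_root", glo)
    if ghi == 0.0:
        return EssResult(hi, "numeric_root", ghi)
    if glo * ghi > 0:
        raise ValueError(
            f"gradient does not change sign on bracket {bracket}: "
            f"g({lo})={glo}, g({hi})={ghi}"
        )
    z_star = optimize.brentq(g, lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps)
    return EssResult(float(z_star), "numeric_root", g(float(z_star)))


def ess_approx(
    r_mean: float,
    r_var: float,
    model: TraitModel,
    regime: SelectionRegime | str,
) -> EssResult:
    """First-order (in sigma_R**2) approximation to the metapopulation ESS.

    Soft:  ``z* ~ (r Rbar**a / 2) (1 + a (a-1) Rbar**-2 sigma**2 / 2)``
    Hard:  ``z* ~ (r Rbar**a / 2) (1 + a (a - 1 + a r Rbar**(2a)) /
    (2 Rbar**2) * sigma**2)``

    For ``a = 1`` these reduce to ``Rbar r / 2`` (heterogeneity has no
    effect under soft selection) and ``(Rbar r / 2)(1 + r sigma**2 / 2)``.
    """
    if not r_mean > 0:
        raise ValueError(f"mean resource level must be positive, got {r_mean}")
    if r_var < 0:
        raise ValueError(f"resource variance must be >= 0, got {r_var}")
    regime = SelectionRegime.coerce(regime)
    a, r = model.a, model.r
    base = r * r_mean**a / 2.0
    if regime is SelectionRegime.SOFT:
        correction = 0.5 * a * (a - 1.0) * r_mean**-2 * r_var
    else:
        correction = (a * (a - 1.0 + a * r * r_mean ** (2 * a))
                      / (2.0 * r_mean**2)) * r_var
    return EssResult(max(base * (1.0 + correction), 0.0), "first_order_approx")
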