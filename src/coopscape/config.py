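"""Scenario configuration loading and validation (YAML/JSON).

An ESS scenario file looks like::

    distribution:
      atoms: [[0.25, 0.5], [1.0, 0.5]]   # or density: {name: uniform, ...}
    r: 0.5
    a: 1.0
    regime: hard
    solver: {tol: 1.0e-10}               # optional

A simulation scenario file mirrors ExperimentConfig::

    pairs: [[1.0, 0.25], [1.0, 0.25]]
    strains: [[0.02, 5.0e5], [0.0, 5.0e5]]
    regime: hard
    n_transfers: 2
    season: {rate_scale: 32.0, carrying_coefficient: 1.0e9}
    stochastic: false
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from coopscape.metapop import ExperimentConfig, SeasonParams
from coopscape.theory import ResourceDistribution, SelectionRegime, TraitModel


class ConfigError(ValueError):
    """A scenario file failed validation."""


def load_mapping(path: str | Path) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read scenario {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"scenario {path} must be a mapping")
    return data


def _density_from_spec(spec: dict) -> ResourceDistribution:
    name = spec.get("name")
    rmin, rmax = spec.get("rmin"), spec.get("rmax")
    if name == "uniform":
        if not (rmin and rmax and 0 < rmin < rmax):
            raise ConfigError("uniform density needs 0 < rmin < rmax")
        width = rmax - rmin
        return ResourceDistribution.from_density(lambda R: 1.0 / width, rmin, rmax)
    if name == "triangular":
        mode = spec.get("mode", 0.5 * (rmin + rmax))
        if not (0 < rmin <= mode <= rmax):
            raise ConfigError("triangular density needs rmin <= mode <= rmax")

        def pdf(R: float) -> float:
            if R < mode:
                return 2 * (R - rmin) / ((rmax - rmin) * (mode - rmin))
            return 2 * (rmax - R) / ((rmax - rmin) * (rmax - mode))

        return ResourceDistribution.from_density(pdf, rmin, rmax)
    raise ConfigError(f"unknown density name {name!r} (supported: uniform, triangular)")


def parse_ess_scenario(
    data: dict,
) -> tuple[ResourceDistribution, TraitModel, SelectionRegime, dict]:
    try:
        dist_spec = data["distribution"]
        if "atoms" in dist_spec:
            dist = ResourceDistribution.from_atoms(
                [(float(R), float(w)) for R, w in dist_spec["atoms"]]
            )
        elif "density" in dist_spec:
            dist = _density_from_spec(dist_spec["density"])
        else:
            raise ConfigError("distribution needs 'atoms' or 'density'")
        model = TraitModel(r=float(data["r"]), a=float(data.get("a", 1.0)))
        regime = SelectionRegime.coerce(data["regime"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid ESS scenario: {exc}") from exc
    solver = data.get("solver", {})
    if not isinstance(solver, dict):
        raise ConfigError("solver must be a mapping")
    return dist, model, regime, solver


def parse_experiment(data: dict) -> ExperimentConfig:
    try:
        season = SeasonParams(**data.get("season", {}))
        return ExperimentConfig(
            pairs=tuple(tuple(float(R) for R in pair) for pair in data["pairs"]),
            strains=tuple(
                (float(x), float(n)) for x, n in data["strains"]
            ),
            regime=SelectionRegime.coerce(data["regime"]),
            n_transfers=int(data.get("n_transfers", 2)),
            bottleneck=float(data.get("bottleneck", 0.01)),
            season=season,
            stochastic=bool(data.get("stochastic", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation scenario: {exc}") from exc
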