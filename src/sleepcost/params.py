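"""Parameter sets for the opportunity-cost sleep model.

The generalized model is governed by thirteen parameters. Four species
presets (captive/wild elephant, captive/wild sloth) ship with the package
as JSON data files, and five sensitivity scenarios (A--E) are defined as
named override sets. Presets are data, not code constants, so users can
derive new species files from them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParams",
    "ClassicParams",
    "ScenarioSpec",
    "SCENARIOS",
    "PRESET_NAMES",
    "preset",
    "apply_scenario",
    "validate",
    "load_config",
    "save_config",
]

#: Allowed conventions for converting the AR persistence rho to a
#: per-period factor. ``per_hour`` treats rho as an hourly factor and uses
#: rho**(24/q) per period (the default: rho is quoted per hour, and only
#: this reading reproduces the calibrated species moments); ``per_day_root``
#: uses rho**(1/q).
RHO_CONVENTIONS = ("per_hour", "per_day_root")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the generalized (opportunity-cost) model.

    Attributes
    ----------
    q:
        Periods per day (integer; 144 gives 10-minute periods).
    kappa:
        Curvature of the circadian-adherence penalty (2.0 = quadratic).
    eta:
        Curvature of foraging production in the sleep stock.
    gamma:
        Curvature of foraging utility (diminishing returns when < 1).
    rho:
        AR persistence of the environmental state, quoted per hour.
    nu_W, nu_S:
        Homeostatic decay constants while awake / asleep, in hours.
    mu_W, mu_S:
        Waking and sleeping asymptotes of the homeostat (mu_S < mu_W).
    lam:
        Fixed utility cost of switching between wake and sleep.
    chi:
        Weight on the circadian penalty in total utility.
    xi:
        Opportunity-cost scale of sleep; normalized to 1 for captives.
    sigma:
        Standard deviation of the environmental innovations.
    rho_convention:
        How rho is converted to a per-period factor (see RHO_CONVENTIONS).
    """

    q: int
    kappa: float
    eta: float
    gamma: float
    rho: float
    nu_W: float
    nu_S: float
    mu_W: float
    mu_S: float
    lam: float
    chi: float
    xi: float
    sigma: float
    rho_convention: str = "per_hour"

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ClassicParams:
    """Parameters of the classic threshold-switching two-process model.

    ``Hbar_u``/``Hbar_l`` are the mean upper/lower circadian bounds, ``a``
    the bound amplitude, ``mu`` the waking asymptote of the homeostat
    (lower asymptote is zero), and ``nu_W``/``nu_S`` decay constants in
    hours with ``q`` periods per day.
    """

    Hbar_u: float = 0.8
    Hbar_l: float = 0.2
    a: float = 0.15
    mu: float = 1.0
    nu_W: float = 8.0
    nu_S: float = 8.0
    q: int = 144

    def replace(self, **changes: Any) -> "ClassicParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named sensitivity scenario: a set of parameter overrides."""

    label: str
    description: str
    overrides: Mapping[str, float]


#: The five sensitivity scenarios. A is the benchmark (empty override set,
#: kept explicit so sensitivity tables always include it).
SCENARIOS: dict[str, ScenarioSpec] = {
    "A": ScenarioSpec("A", "benchmark", {}),
    "B": ScenarioSpec("B", "lower half-lives", {"nu_W": 4.0, "nu_S": 4.0}),
    "C": ScenarioSpec("C", "higher sleep weight", {"chi": 20.0}),
    "D": ScenarioSpec("D", "lower switching cost", {"lam": 0.02}),
    "E": ScenarioSpec("E", "no diminishing utility", {"gamma": 1.0}),
}

PRESET_NAMES = (
    "elephant_captive",
    "elephant_wild",
    "sloth_captive",
    "sloth_wild",
)

_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def _from_mapping(data: Mapping[str, Any], source: str) -> ModelParams:
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(
            f"unknown parameter name(s) in {source}: {sorted(unknown)}"
        )
    missing = _FIELDS - set(data) - {"rho_convention"}
    if missing:
        raise ValueError(f"missing parameter(s) in {source}: {sorted(missing)}")
    data = dict(data)
    data["q"] = int(data["q"])
    return ModelParams(**data)


def preset(name: str) -> ModelParams:
    """Load one of the packaged species presets by name."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("sleepcost.presets").joinpath(f"{name}.json").read_text()
    return _from_mapping(json.loads(text), f"preset {name!r}")


def apply_scenario(params: ModelParams, scenario: ScenarioSpec | str) -> ModelParams:
    """Return a copy of ``params`` with the scenario's overrides applied."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    return params.replace(**dict(scenario.overrides))


def validate(params: ModelParams) -> list[str]:
    """Check every model invariant; return the violations (empty = valid).

    Reports rather than raises, so calibration can treat invariant-breaking
    candidate points as penalized instead of fatal.
    """
    v: list[str] = []
    p = params
    if not (isinstance(p.q, (int,)) and p.q >= 2):
        v.append("q must be an integer >= 2")
    if not p.mu_W > p.mu_S:
        v.append("mu_W > mu_S violated")
    if not p.nu_W > 0:
        v.append("nu_W must be > 0")
    if not p.nu_S > 0:
        v.append("nu_S must be > 0")
    if not p.kappa > 0:
        v.append("kappa must be > 0")
    if not (0 < p.gamma <= 1):
        v.append("gamma must be in (0, 1]")
    if not p.eta > 0:
        v.append("eta must be > 0")
    if not p.xi >= 0:
        v.append("xi must be >= 0")
    if not p.lam >= 0:
        v.append("lam must be >= 0")
    if not p.chi >= 0:
        v.append("chi must be >= 0")
    if not p.sigma >= 0:
        v.append("sigma must be >= 0")
    if not (0 <= p.rho < 1):
        v.append("rho must be in [0, 1)")
    if p.rho_convention not in RHO_CONVENTIONS:
        v.append(f"rho_convention must be one of {RHO_CONVENTIONS}")
    return v


def load_config(path: str | Path) -> ModelParams:
    """Read a flat key-value parameter file (JSON or YAML by extension).

    Keys must be exactly the ModelParams field names; unknown keys raise
    (catches typos in parameter names).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return _from_mapping(data, str(path))


def save_config(params: ModelParams, path: str | Path) -> None:
    """Write parameters to a flat JSON or YAML file (round-trips exactly)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
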