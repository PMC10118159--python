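"""JSON study-configuration loading and validation.

A configuration file gathers everything needed to plan a trial::

    {
      "variances": [100, 125, 150],
      "correlations": [0.3, 0.3, 0.3],          # or "covariances": [...]
      "costs": {"overhead": 500, "per_condition": [0, 423.6, 635.4]},
      "budget": 100000,
      "scenario": "1",                           # "1" | "2" | "complete"
      "criterion": {"kind": "compound", "lambda1": 0.75},   # or "DA"
      "power": {"alpha": 0.05, "sided": 1, "target_power": 0.8}
    }

Correlation/covariance order is fixed as (0-1, 0-2, 1-2).  ``criterion``
and ``power`` are optional; ``criterion`` may also be the bare string
``"DA"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .allocate import CostSpec, DesignScenario, scenario_by_name
from .criteria import CriterionSpec
from .errors import ConfigError
from .model import CovarianceSpec
from .power import PowerSpec

__all__ = ["StudyConfig", "load_config", "parse_config"]


@dataclass(frozen=True)
class StudyConfig:
    """Validated bundle of covariance, cost, scenario and criterion settings."""

    cov: CovarianceSpec
    costs: CostSpec
    scenario: DesignScenario
    criterion: CriterionSpec | None = None
    power: PowerSpec | None = None


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing {key!r} in {context}")
    return mapping[key]


def parse_config(raw: dict) -> StudyConfig:
    """Build a :class:`StudyConfig` from a decoded JSON object."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a JSON object")
    try:
        variances = tuple(_require(raw, "variances", "configuration"))
        if "correlations" in raw:
            cov = CovarianceSpec(variances, tuple(raw["correlations"]))
        elif "covariances" in raw:
            cov = CovarianceSpec.from_covariances(variances, tuple(raw["covariances"]))
        else:
            raise ConfigError(
                "configuration needs 'correlations' or 'covariances' "
                "(order: 0-1, 0-2, 1-2)"
            )

        cost_obj = _require(raw, "costs", "configuration")
        costs = CostSpec(
            overhead=_require(cost_obj, "overhead", "'costs'"),
            per_condition=tuple(_require(cost_obj, "per_condition", "'costs'")),
            budget=_require(raw, "budget", "configuration"),
        )

        scenario = scenario_by_name(raw.get("scenario", "1"))

        criterion = None
        if "criterion" in raw:
            crit_obj = raw["criterion"]
            if isinstance(crit_obj, str):
                criterion = CriterionSpec(crit_obj)
            else:
                criterion = CriterionSpec(
                    _require(crit_obj, "kind", "'criterion'"),
                    crit_obj.get("lambda1"),
                )

        pw = None
        if "power" in raw:
            pw_obj = raw["power"]
            pw = PowerSpec(
                alpha=pw_obj.get("alpha", 0.05),
                sided=pw_obj.get("sided", 1),
                power=pw_obj.get("target_power", 0.8),
            )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return StudyConfig(cov=cov, costs=costs, scenario=scenario, criterion=criterion, power=pw)


def load_config(path: str | Path) -> StudyConfig:
    """Read and validate a JSON configuration file."""
    try:
        raw = json.loads(Path(path).read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    return parse_config(raw)
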