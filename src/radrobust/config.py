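"""YAML configuration: grids, robustness thresholds, seeds.

A flat config file keeps a whole analysis reproducible from one document:

.. code-block:: yaml

    criteria:
      cv_threshold: 10.0
      rrm_threshold: 0.5
    seed: 7
    scenarios:
      - {scheme: discretisation, algorithm: FBW}
      - {scheme: interpolation, algorithm: linear}

Scenarios without an explicit ``values`` list use the default grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grids import (
    Algorithm,
    ParameterGrid,
    RobustCriteria,
    Scheme,
    build_parameter_grid,
    enumerate_default_scenarios,
)

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    criteria: RobustCriteria = field(default_factory=RobustCriteria)
    seed: int = 0
    scenarios: list[ParameterGrid] = field(
        default_factory=enumerate_default_scenarios
    )


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    criteria = RobustCriteria(**raw.get("criteria", {}))
    scenarios = []
    for sc in raw.get("scenarios", []):
        scheme = Scheme(sc["scheme"])
        algorithm = Algorithm(sc["algorithm"])
        if "values" in sc:
            scenarios.append(
                ParameterGrid(
                    scheme,
                    algorithm,
                    tuple(sc["values"]),
                    label=sc.get("label", ""),
                )
            )
        else:
            scenarios.append(build_parameter_grid(scheme, algorithm))
    return AnalysisConfig(
        criteria=criteria,
        seed=int(raw.get("seed", 0)),
        scenarios=scenarios or enumerate_default_scenarios(),
    )


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    raw = {
        "criteria": {
            "cv_threshold": config.criteria.cv_threshold,
            "rrm_threshold": config.criteria.rrm_threshold,
        },
        "seed": config.seed,
        "scenarios": [
            {
                "scheme": g.scheme.value,
                "algorithm": g.algorithm.value,
                "values": list(g.values),
                "label": g.label,
            }
            for g in config.scenarios
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
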