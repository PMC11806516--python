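"""Plan configuration files, results serialization and run manifests.

Plans are flat YAML mappings of :class:`~mepsim.experiments.ExperimentPlan`
fields; unknown keys are rejected so a typo cannot silently fall back to a
default. Results are written as RFC-4180 CSV in grid order with a fixed
column order, so identical (plan, seed) pairs produce byte-identical files.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .experiments import RESULT_COLUMNS, ExperimentPlan

__all__ = ["load_plan", "save_plan", "write_results", "read_results", "RunManifest"]

_PLAN_FIELDS = set(ExperimentPlan.__dataclass_fields__)


def load_plan(path):
    """Load and validate an :class:`ExperimentPlan` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"plan file {path} must contain a mapping")
    unknown = sorted(set(raw) - _PLAN_FIELDS)
    if unknown:
        raise ConfigError(f"unknown plan keys: {unknown}", keys=unknown)
    try:
        return ExperimentPlan(**raw)
    except Exception as exc:
        raise ConfigError(f"invalid plan: {exc}") from exc


def save_plan(plan, path):
    data = plan.to_dict()
    data["days_grid"] = list(data["days_grid"])
    data["preparations"] = list(data["preparations"])
    data["learners"] = list(data["learners"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_results(results, path):
    """Write long-form results deterministically (column and row order fixed)."""
    df = pd.DataFrame(results, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_results(path):
    return pd.read_csv(path)


@dataclass
class RunManifest:
    """Reproducibility record: plan echo, root seed and software versions."""

    plan: dict
    seed: int
    versions: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, plan):
        from . import __version__

        return cls(
            plan=plan.to_dict(),
            seed=plan.seed,
            versions={
                "mepsim": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": platform.python_version(),
            },
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
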