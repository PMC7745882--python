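"""YAML run configuration for the pipeline CLI.

A run config names exactly one cohort source (a synthetic spec, a cohort
file, or an imported risk table), at least one treatment scenario, optional
trajectory-coefficient and risk-parameter overrides or calibration targets,
seeds, and an output directory.  Validation is explicit and names the
offending field; no external schema engine is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .trajectory import TrajectoryCoefficients, TreatmentScenario

__all__ = ["RunConfig", "ConfigError", "load_config", "scenario_from_dict"]


class ConfigError(ValueError):
    """A run config is malformed; the message names the field."""


def scenario_from_dict(d: dict) -> TreatmentScenario:
    """Scenario from ``{regimen, treatment_months, recovery_months}``.

    Months are converted to years as months/12 exactly.
    """
    for key in ("regimen", "treatment_months", "recovery_months"):
        if key not in d:
            raise ConfigError(f"scenario missing field {key!r}")
    return TreatmentScenario(
        regimen=d["regimen"],
        treatment_years=float(d["treatment_months"]) / 12.0,
        recovery_years=float(d["recovery_months"]) / 12.0,
    )


@dataclass
class RunConfig:
    cohort_source: str  # "synthetic" | "file" | "risk_table"
    cohort_spec: CohortSpec | None = None
    cohort_path: str | None = None
    risk_table_path: str | None = None
    scenarios: list = field(default_factory=list)
    coefficients: TrajectoryCoefficients = field(default_factory=TrajectoryCoefficients)
    risk_params_path: str | None = None
    calibration_targets: dict | None = None
    seed: int = 0
    assignment_seed: int = 1  # mixed-dosing assignment, separate from cohort seed
    output_dir: str = "results"

    def __post_init__(self):
        sources = {
            "synthetic": self.cohort_spec is not None or self.cohort_source == "synthetic",
            "file": self.cohort_path is not None,
            "risk_table": self.risk_table_path is not None,
        }
        if self.cohort_source not in sources:
            raise ConfigError(
                f"cohort_source {self.cohort_source!r} not one of "
                "['synthetic', 'file', 'risk_table']"
            )
        given = [k for k, v in (("file", self.cohort_path), ("risk_table", self.risk_table_path)) if v]
        if self.cohort_source == "synthetic" and given:
            raise ConfigError("synthetic cohort_source must not also name a path")
        if self.cohort_source in ("file", "risk_table") and self.cohort_source not in given:
            raise ConfigError(f"cohort_source {self.cohort_source!r} requires its path field")
        if not self.scenarios:
            raise ConfigError("at least one scenario is required")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    cohort = raw.get("cohort", {})
    source = cohort.get("source", "synthetic")
    spec = None
    if source == "synthetic":
        spec_fields = {
            k: v
            for k, v in cohort.items()
            if k in CohortSpec.__dataclass_fields__
        }
        for tup in ("age_range", "age_mean_sd", "bmi_mean_sd", "tscore_mean_sd"):
            if tup in spec_fields:
                spec_fields[tup] = tuple(spec_fields[tup])
        try:
            spec = CohortSpec(**spec_fields)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"cohort spec: {e}") from e

    coeff_over = raw.get("coefficients", {})
    unknown = set(coeff_over) - set(TrajectoryCoefficients.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown coefficient fields {sorted(unknown)}")
    coeffs = TrajectoryCoefficients(**coeff_over)

    scenarios = [scenario_from_dict(s) for s in raw.get("scenarios", [])]

    risk = raw.get("risk", {})
    return RunConfig(
        cohort_source=source,
        cohort_spec=spec,
        cohort_path=cohort.get("path"),
        risk_table_path=cohort.get("risk_table"),
        scenarios=scenarios,
        coefficients=coeffs,
        risk_params_path=risk.get("params_path"),
        calibration_targets=risk.get("calibration_targets"),
        seed=int(raw.get("seed", 0)),
        assignment_seed=int(raw.get("assignment_seed", 1)),
        output_dir=str(raw.get("output_dir", "results")),
    )
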