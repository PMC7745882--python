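"""End-to-end study pipeline under the base-case conditions.

Convenience wrapper used by the analysis drivers, the acceptance script,
and the acceptance tests: generate the n=2303 synthetic cohort, calibrate
the surrogate risk engine to the published untreated stratum medians, and
run the two base-case treatment scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bridging import run_scenario, summarize_strata
from .cohort import CohortSpec, generate_cohort
from .risk import RiskModelParams, CalibrationResult, calibrate
from .trajectory import TrajectoryCoefficients, TreatmentScenario

__all__ = ["StudyRun", "run_study"]


@dataclass
class StudyRun:
    cohort: pd.DataFrame
    calibration: CalibrationResult
    paired: dict  # scenario name -> paired-risk frame
    summaries: dict  # scenario name -> stratum summary frame

    @property
    def params(self) -> RiskModelParams:
        return self.calibration.params


def run_study(
    seed: int = 0,
    n: int = 2303,
    coeffs: TrajectoryCoefficients | None = None,
    scenarios: dict | None = None,
) -> StudyRun:
    """Generate, calibrate, and bridge both base-case scenarios."""
    coeffs = coeffs or TrajectoryCoefficients()
    if scenarios is None:
        scenarios = {
            "qd150_12mo": TreatmentScenario.qd150(),
            "bid200_3mo": TreatmentScenario.bid200(),
        }
    cohort = generate_cohort(CohortSpec(n=n, seed=seed))
    calibration = calibrate(RiskModelParams(), cohort)
    paired = {
        name: run_scenario(cohort, coeffs, scen, calibration.params)
        for name, scen in scenarios.items()
    }
    summaries = {name: summarize_strata(p) for name, p in paired.items()}
    return StudyRun(cohort=cohort, calibration=calibration, paired=paired, summaries=summaries)
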