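"""Synthetic participant-level data with the structure the analysis assumes.

Each simulated experiment has three between-participants conditions, one per
time pair; every participant answers exactly one binary change question.  The
ground truth is either the two-level quantum-like model (parameter: the
per-day rotation angle theta) or a macrorealist trajectory distribution /
mixture, optionally filtered through a per-condition report-bias channel.
Exclusions are simulated as condition-specific Bernoulli flags; by default
they are independent of the response (an idealization -- real exclusions are
content-based and could correlate with responding "changed"; an optional
knob shifts exclusion probability for changed responses to probe that).
Optional reaction times are log-normal draws so exported CSVs have a
realistic schema; no statistics are computed on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .inequality_core import CONDITIONS, ValidationError
from . import macrorealist_model as mr
from . import quantum_model as qm
from .tb_inference import ConditionCounts, aggregate_participant_table

__all__ = [
    "GroundTruth",
    "ExperimentDesign",
    "generate",
    "aggregate",
    "recover_theta",
]


@dataclass(frozen=True)
class GroundTruth:
    """Response model: quantum-like (theta) or macrorealist (distribution)."""

    model: str  # "quantum" | "macrorealist"
    theta: Optional[float] = None
    distribution: Optional[Union[mr.TrajectoryDistribution, mr.PopulationMixture]] = None

    def __post_init__(self) -> None:
        if self.model == "quantum":
            if self.theta is None:
                raise ValidationError("quantum ground truth needs theta")
        elif self.model == "macrorealist":
            if self.distribution is None:
                raise ValidationError("macrorealist ground truth needs a distribution")
        else:
            raise ValidationError(f"unknown ground-truth model {self.model!r}")

    def change_probabilities(self) -> Dict[str, float]:
        if self.model == "quantum":
            return qm.protocol_change_probabilities(self.theta).as_condition_map()
        dist = self.distribution
        if isinstance(dist, mr.PopulationMixture):
            return mr.mixture_change_probabilities(dist).as_condition_map()
        return mr.change_probabilities(dist).as_condition_map()


@dataclass(frozen=True)
class ExperimentDesign:
    """Recruitment, exclusion and ground-truth configuration for one run."""

    recruited: Mapping[str, int]
    exclusion_rates: Mapping[str, float]
    ground_truth: GroundTruth
    bias: mr.ReportBias = mr.NO_BIAS
    #: Additive shift of the exclusion probability for participants who
    #: report a change (sensitivity knob; 0 keeps exclusions independent).
    exclusion_change_shift: float = 0.0
    #: Optional (mu, sigma) of log reaction time in seconds.
    rt_lognormal: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if cond not in self.recruited or int(self.recruited[cond]) < 1:
                raise ValidationError(f"recruited[{cond!r}] must be >= 1")
            rate = float(self.exclusion_rates.get(cond, 0.0))
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"exclusion_rates[{cond!r}] must be in [0, 1)")


def generate(design: ExperimentDesign) -> pd.DataFrame:
    """Draw one participant-level dataset from the design.

    Returns a DataFrame with columns participant_id, condition, change,
    excluded (and rt_change_s if an RT model is configured).  Excluded
    participants keep their response: exclusion is downstream filtering.
    Deterministic given the design's seed.
    """
    rng = np.random.default_rng(design.seed)
    true_pr = design.ground_truth.change_probabilities()
    rows = []
    pid = 0
    for cond in CONDITIONS:
        n = int(design.recruited[cond])
        p_obs = design.bias.observed(cond, true_pr[cond])
        changes = rng.random(n) < p_obs
        rate = float(design.exclusion_rates.get(cond, 0.0))
        p_excl = np.clip(rate + design.exclusion_change_shift * changes, 0.0, 1.0)
        excluded = rng.random(n) < p_excl
        if design.rt_lognormal is not None:
            mu, sigma = design.rt_lognormal
            rts = rng.lognormal(mu, sigma, size=n)
        else:
            rts = None
        for i in range(n):
            pid += 1
            row = {
                "participant_id": f"P{pid:05d}",
                "condition": cond,
                "change": int(changes[i]),
                "excluded": int(excluded[i]),
            }
            if rts is not None:
                row["rt_change_s"] = float(rts[i])
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> ConditionCounts:
    """Condition counts from participant records, dropping excluded rows."""
    return aggregate_participant_table(records)


def _theta_residual(theta: float, obs: Dict[str, float]) -> float:
    """Sum of squared deviations between observed proportions and the
    quantum-model forms (sin^2 theta, sin^2 theta, sin^2 2*theta)."""
    pred = {
        "t1t2": np.sin(theta) ** 2,
        "t2t3": np.sin(theta) ** 2,
        "t1t3": np.sin(2.0 * theta) ** 2,
    }
    return sum((obs[c] - pred[c]) ** 2 for c in CONDITIONS)


def recover_theta(
    counts_or_records: Union[ConditionCounts, pd.DataFrame],
    grid_step: float = 1e-3,
) -> Tuple[float, float]:
    """Least-squares recovery of the rotation angle from observed proportions.

    Fits theta in [0, pi/2] by a coarse grid scan followed by bounded local
    refinement, minimising the squared deviation of the per-condition change
    proportions from (sin^2 theta, sin^2 theta, sin^2 2*theta).  Returns
    (theta_hat, residual).
    """
    if isinstance(counts_or_records, pd.DataFrame):
        counts = aggregate(counts_or_records)
    else:
        counts = counts_or_records
    obs = counts.proportions().as_condition_map()
    grid = np.arange(0.0, np.pi / 2 + grid_step, grid_step)
    losses = np.array([_theta_residual(t, obs) for t in grid])
    t0 = grid[int(np.argmin(losses))]
    lo = max(0.0, t0 - grid_step)
    hi = min(np.pi / 2, t0 + grid_step)
    res = minimize_scalar(_theta_residual, bounds=(lo, hi), args=(obs,), method="bounded")
    if res.fun <= losses.min():
        return float(res.x), float(res.fun)
    return float(t0), float(losses.min())
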