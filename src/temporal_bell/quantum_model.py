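"""Two-level quantum-like juror model that violates the temporal Bell bound.

The juror's belief about guilt is a unit vector in the real plane spanned by
|Guilty> and |Innocent>.  The juror starts in the pure |Innocent> state; each
day of incriminating evidence rotates the state by an angle theta toward
|Guilty>; answering the guilt question is a projective measurement that
collapses the state onto the answer's basis vector.

With equal per-day rotation theta and the start state an eigenstate of the
first measurement, the protocol's two-time correlations are

    C_t1t2 = cos 2*theta,  C_t2t3 = cos 2*theta,  C_t1t3 = cos 4*theta,

and the change probabilities are sin^2(theta), sin^2(theta), sin^2(2*theta).
The tb statistic sin^2(2*theta) - 2 sin^2(theta) peaks at +0.25 for
theta = pi/6, violating the macrorealist bound tb <= 0.  All public protocol
quantities here are computed by explicit state propagation (rotate, collapse,
rotate, project); the closed forms above serve as independent test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .inequality_core import (
    ChangeProbabilityTriple,
    CorrelationTriple,
    TwoTimeDistribution,
    ValidationError,
    change_probability,
    expectation_value,
)

__all__ = [
    "QubitState",
    "MeasurementOutcome",
    "prepare_initial",
    "evolve",
    "measure_guilt",
    "two_time_distribution",
    "protocol_correlations",
    "protocol_change_probabilities",
    "sweep",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class QubitState:
    """Real-amplitude belief state a_g |Guilty> + a_i |Innocent>."""

    amp_g: float
    amp_i: float

    def __post_init__(self) -> None:
        norm = self.amp_g**2 + self.amp_i**2
        if abs(norm - 1.0) > 1e-9:
            raise ValidationError(f"state norm^2 = {norm!r}, not 1")


@dataclass(frozen=True)
class MeasurementOutcome:
    """One branch of a projective guilt measurement."""

    value: int  # +1 guilty, -1 innocent
    probability: float
    collapsed_state: QubitState


GUILTY_STATE = QubitState(1.0, 0.0)
INNOCENT_STATE = QubitState(0.0, 1.0)


def prepare_initial() -> QubitState:
    """The pure |Innocent> state the juror holds before any evidence."""
    return INNOCENT_STATE


def evolve(state: QubitState, theta: float) -> QubitState:
    """Rotate the belief state by theta (radians) toward |Guilty>.

    Starting from |Innocent>, evolve gives amp_g = sin(theta),
    amp_i = cos(theta).  Rotations compose additively and preserve the norm.
    """
    c, s = math.cos(theta), math.sin(theta)
    return QubitState(
        amp_g=c * state.amp_g + s * state.amp_i,
        amp_i=-s * state.amp_g + c * state.amp_i,
    )


def measure_guilt(state: QubitState) -> Tuple[MeasurementOutcome, MeasurementOutcome]:
    """Projective measurement in the guilt basis.

    Returns the (guilty, innocent) branches with Born-rule probabilities
    amp_g^2 and amp_i^2; each branch's collapsed state is the matching basis
    vector, so re-measuring a collapsed state returns it with probability 1.
    """
    return (
        MeasurementOutcome(+1, state.amp_g**2, GUILTY_STATE),
        MeasurementOutcome(-1, state.amp_i**2, INNOCENT_STATE),
    )


def two_time_distribution(theta_first: float, theta_second: float) -> TwoTimeDistribution:
    """Joint outcome distribution for measurements after two evidence rotations.

    From the initial |Innocent> state: rotate by ``theta_first``, measure
    (collapse), rotate by ``theta_second``, measure again.  P(n_i, n_j) is
    the Born probability of the first outcome times the conditional Born
    probability of the second from the collapsed state.
    """
    first = measure_guilt(evolve(prepare_initial(), theta_first))
    joint = {}
    for branch in first:
        second = measure_guilt(evolve(branch.collapsed_state, theta_second))
        for b2 in second:
            joint[(branch.value, b2.value)] = branch.probability * b2.probability
    return TwoTimeDistribution(
        p_pp=joint[(+1, +1)],
        p_pm=joint[(+1, -1)],
        p_mp=joint[(-1, +1)],
        p_mm=joint[(-1, -1)],
    )


def protocol_correlations(theta: float) -> CorrelationTriple:
    """Two-time correlations of the equal-rotation protocol.

    The t1 measurement acts on the initial eigenstate and so is
    non-disturbing.  Pair (t1,t2): measure at start, one rotation, measure.
    Pair (t2,t3): one rotation, measure (collapse), one rotation, measure.
    Pair (t1,t3): measure at start, two rotations with *no* intermediate
    measurement, measure.  Closed forms: cos 2*theta, cos 2*theta, cos 4*theta.
    """
    c12 = expectation_value(two_time_distribution(0.0, theta))
    c23 = expectation_value(two_time_distribution(theta, theta))
    c13 = expectation_value(two_time_distribution(0.0, 2.0 * theta))
    return CorrelationTriple(c_ab=c12, c_bc=c23, c_ac=c13)


def protocol_change_probabilities(theta: float) -> ChangeProbabilityTriple:
    """Change probabilities when each pair is probed without a third measurement.

    This is the model's idealization of a change judgment: each participant
    is measured only at their condition's two time points, so the (t1,t3)
    pair evolves coherently through t2.  pr12 = pr23 = sin^2(theta),
    pr13 = sin^2(2*theta); tb(theta) = sin^2(2*theta) - 2 sin^2(theta).
    """
    pr12 = change_probability(two_time_distribution(0.0, theta))
    pr23 = change_probability(two_time_distribution(theta, theta))
    pr13 = change_probability(two_time_distribution(0.0, 2.0 * theta))
    return ChangeProbabilityTriple(pr13=pr13, pr12=pr12, pr23=pr23)


def sweep(thetas: Iterable[float]) -> pd.DataFrame:
    """Tabulate correlations, change probabilities, margin and tb over theta.

    Columns: theta, c12, c23, c13, pr12, pr23, pr13, margin, tb.  The margin
    is the correlation-form excess C12 + C23 - C13 - 1 and equals 2*tb.
    """
    rows = []
    for theta in thetas:
        c = protocol_correlations(theta)
        pr = protocol_change_probabilities(theta)
        rows.append(
            {
                "theta": theta,
                "c12": c.c_ab,
                "c23": c.c_bc,
                "c13": c.c_ac,
                "pr12": pr.pr12,
                "pr23": pr.pr23,
                "pr13": pr.pr13,
                "margin": c.c_ab + c.c_bc - c.c_ac - 1.0,
                "tb": pr.pr13 - pr.pr12 - pr.pr23,
            }
        )
    return pd.DataFrame(rows)
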