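"""Temporal Bell (Leggett-Garg) inequalities for a binary question at three times.

A dichotomous question ("is the suspect guilty?") is asked at three times
t1 < t2 < t3.  Outcomes are coded q(guilty) = +1, q(innocent) = -1.  Under
macrorealism plus noninvasive measurability the two-time correlations
``C_ij = <Q_i Q_j>`` obey

    C_12 + C_23 <= C_13 + 1

and three sign variants.  Equivalently, writing ``pr_ij`` for the probability
that the answer *changed* between times i and j (``pr = (1 - C)/2``), the
change-frequency form is

    tb = pr_13 - pr_12 - pr_23 <= 0.

This module holds the containers for two-time statistics and evaluates both
forms plus the map between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = [
    "Q_GUILTY",
    "Q_INNOCENT",
    "PROB_TOL",
    "CONDITIONS",
    "TwoTimeDistribution",
    "CorrelationTriple",
    "ChangeProbabilityTriple",
    "InequalityReport",
    "expectation_value",
    "change_probability",
    "correlation_from_change",
    "evaluate_inequality",
    "evaluate_all_versions",
    "tb_from_changes",
]

#: Signed outcome values, fixed by convention.
Q_GUILTY: int = +1
Q_INNOCENT: int = -1

#: Absolute tolerance for probability normalisation (all arithmetic is closed-form).
PROB_TOL: float = 1e-12

#: Condition keys in report order: the long interval first, then the two short ones.
CONDITIONS: Tuple[str, str, str] = ("t1t3", "t1t2", "t2t3")


class ValidationError(ValueError):
    """Raised when a statistical container violates its invariants."""


@dataclass(frozen=True)
class TwoTimeDistribution:
    """Joint distribution P(n_i, n_j) of +/-1 outcomes at two time points.

    Fields are the probabilities of (n_i, n_j) = (+,+), (+,-), (-,+), (-,-).
    """

    p_pp: float
    p_pm: float
    p_mp: float
    p_mm: float

    def __post_init__(self) -> None:
        probs = (self.p_pp, self.p_pm, self.p_mp, self.p_mm)
        for p in probs:
            if not (-PROB_TOL <= p <= 1 + PROB_TOL):
                raise ValidationError(f"probability {p!r} outside [0, 1]")
        if abs(sum(probs) - 1.0) > PROB_TOL:
            raise ValidationError(f"probabilities sum to {sum(probs)!r}, not 1")


@dataclass(frozen=True)
class CorrelationTriple:
    """Two-time correlations C_12 = <Q_1 Q_2>, C_23, C_13 (dimensionless)."""

    c_ab: float
    c_bc: float
    c_ac: float

    def __post_init__(self) -> None:
        for c in (self.c_ab, self.c_bc, self.c_ac):
            if abs(c) > 1 + PROB_TOL:
                raise ValidationError(f"correlation {c!r} outside [-1, 1]")

    def to_json_dict(self) -> Dict[str, float]:
        return {"t1t2": self.c_ab, "t2t3": self.c_bc, "t1t3": self.c_ac}

    @classmethod
    def from_json_dict(cls, d: Dict[str, float]) -> "CorrelationTriple":
        return cls(c_ab=d["t1t2"], c_bc=d["t2t3"], c_ac=d["t1t3"])


@dataclass(frozen=True)
class ChangeProbabilityTriple:
    """Change probabilities pr_13, pr_12, pr_23 for the three time pairs."""

    pr13: float
    pr12: float
    pr23: float

    def __post_init__(self) -> None:
        for p in (self.pr13, self.pr12, self.pr23):
            if not (-PROB_TOL <= p <= 1 + PROB_TOL):
                raise ValidationError(f"change probability {p!r} outside [0, 1]")

    def to_json_dict(self) -> Dict[str, float]:
        return {"t1t2": self.pr12, "t2t3": self.pr23, "t1t3": self.pr13}

    @classmethod
    def from_json_dict(cls, d: Dict[str, float]) -> "ChangeProbabilityTriple":
        return cls(pr13=d["t1t3"], pr12=d["t1t2"], pr23=d["t2t3"])

    def as_condition_map(self) -> Dict[str, float]:
        return self.to_json_dict()


#: The four sign choices (s1, s2) indexing the three-time Leggett-Garg family.
VERSION_SIGNS: Tuple[Tuple[int, int], ...] = ((+1, +1), (+1, -1), (-1, +1), (-1, -1))


@dataclass(frozen=True)
class InequalityReport:
    """Margins (LHS - bound) and violation flags for the four inequality versions.

    Version (s1, s2) is s1*C_12 + s2*C_23 - s1*s2*C_13 <= 1; a positive
    margin means that version is violated.
    """

    version_margins: Dict[Tuple[int, int], float]
    violated: Dict[Tuple[int, int], bool]

    @property
    def n_violated(self) -> int:
        return sum(self.violated.values())


def expectation_value(dist: TwoTimeDistribution) -> float:
    """Correlation <Q_i Q_j> = sum over outcomes of q(n_i) q(n_j) P(n_i, n_j)."""
    return dist.p_pp + dist.p_mm - dist.p_pm - dist.p_mp


def change_probability(dist: TwoTimeDistribution) -> float:
    """Probability that the outcome differs between the two times."""
    return dist.p_pm + dist.p_mp


def correlation_from_change(pr: float) -> float:
    """Map a change probability to a correlation: C = 1 - 2*pr.

    This is the inverse of ``change_probability`` under macrorealism, where
    a change judgment reveals whether the two definite values differ.
    """
    if not (-PROB_TOL <= pr <= 1 + PROB_TOL):
        raise ValidationError(f"change probability {pr!r} outside [0, 1]")
    return 1.0 - 2.0 * pr


def evaluate_inequality(c: CorrelationTriple) -> float:
    """Signed margin of C_12 + C_23 <= C_13 + 1; positive means violation."""
    return c.c_ab + c.c_bc - c.c_ac - 1.0


def evaluate_all_versions(c: CorrelationTriple, tol: float = 0.0) -> InequalityReport:
    """Evaluate all four sign variants s1*C_12 + s2*C_23 - s1*s2*C_13 <= 1.

    The four margins always sum to -4, so at most three can be positive for
    arbitrary triples; for triples realizable by a sequential two-level
    protocol or a classical trajectory mixture at most one is.
    """
    margins = {
        (s1, s2): s1 * c.c_ab + s2 * c.c_bc - s1 * s2 * c.c_ac - 1.0
        for s1, s2 in VERSION_SIGNS
    }
    violated = {v: m > tol for v, m in margins.items()}
    return InequalityReport(version_margins=margins, violated=violated)


def tb_from_changes(pr: ChangeProbabilityTriple) -> float:
    """The tb statistic pr_13 - pr_12 - pr_23.

    Positive tb is the change-frequency form of a temporal Bell violation,
    N_-(t1,t3) > N_-(t1,t2) + N_-(t2,t3) in proportion form.  Under the
    substitution pr = (1 - C)/2 it equals (C_12 + C_23 - C_13 - 1)/2, i.e.
    half the correlation-form margin.
    """
    return pr.pr13 - pr.pr12 - pr.pr23


def correlations_to_changes(c: CorrelationTriple) -> ChangeProbabilityTriple:
    """Apply pr = (1 - C)/2 to each entry (valid under macrorealism)."""
    return ChangeProbabilityTriple(
        pr13=(1.0 - c.c_ac) / 2.0,
        pr12=(1.0 - c.c_ab) / 2.0,
        pr23=(1.0 - c.c_bc) / 2.0,
    )


def changes_to_correlations(pr: ChangeProbabilityTriple) -> CorrelationTriple:
    """Apply C = 1 - 2*pr to each entry."""
    return CorrelationTriple(
        c_ab=correlation_from_change(pr.pr12),
        c_bc=correlation_from_change(pr.pr23),
        c_ac=correlation_from_change(pr.pr13),
    )
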