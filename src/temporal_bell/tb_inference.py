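"""Inference for the tb statistic from per-condition change counts.

Given counts of "my judgment changed" responses in the three
between-participants conditions, the analysis computes

    tb = pr(t1,t3) - pr(t1,t2) - pr(t2,t3),

attaches a binomial standard error sqrt(p*q/n) to each proportion, pools
them as a root-sum-of-squares (an upper bound on the SE of tb, since the
between-participants design leaves the three proportions independent and the
covariance terms are dropped), and forms a Wald 95% CI tb +/- 1.96*SE_pooled.
A violation of the temporal Bell bound requires tb > 0, so the verdict turns
on whether the CI excludes 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple, Union

import numpy as np
import pandas as pd

from .inequality_core import CONDITIONS, ChangeProbabilityTriple, ValidationError
from . import macrorealist_model as mr
from . import quantum_model as qm

__all__ = [
    "ConditionCounts",
    "TBEstimate",
    "proportion_se",
    "pooled_se",
    "tb_estimate",
    "apply_exclusions",
    "aggregate_participant_table",
    "ci_coverage_simulation",
    "round_half_away",
]


@dataclass(frozen=True)
class ConditionCounts:
    """Per-condition (n_changed, n_total) for the three time-pair conditions."""

    counts: Mapping[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if cond not in self.counts:
                raise ValidationError(f"missing condition {cond!r}")
            changed, total = self.counts[cond]
            if total < 1:
                raise ValidationError(f"{cond}: n_total must be >= 1")
            if not 0 <= changed <= total:
                raise ValidationError(f"{cond}: need 0 <= n_changed <= n_total")

    def proportion(self, cond: str) -> float:
        changed, total = self.counts[cond]
        return changed / total

    def proportions(self) -> ChangeProbabilityTriple:
        return ChangeProbabilityTriple(
            pr13=self.proportion("t1t3"),
            pr12=self.proportion("t1t2"),
            pr23=self.proportion("t2t3"),
        )


@dataclass(frozen=True)
class TBEstimate:
    """tb point estimate with pooled-SE Wald interval and verdict.

    verdict: "violation" if the CI lies entirely above 0, "trend" if tb > 0
    but the CI straddles 0, else "none".
    """

    tb: float
    se13: float
    se12: float
    se23: float
    se_pooled: float
    z: float
    ci_lower: float
    ci_upper: float
    verdict: str

    def to_json_dict(self, counts: "ConditionCounts | None" = None) -> Dict:
        report: Dict = {
            "tb": self.tb,
            "se_pooled": self.se_pooled,
            "ci": [self.ci_lower, self.ci_upper],
            "z": self.z,
            "verdict": self.verdict,
        }
        if counts is not None:
            per = {}
            for cond, se in zip(CONDITIONS, (self.se13, self.se12, self.se23)):
                changed, total = counts.counts[cond]
                per[cond] = {"p": changed / total, "se": se, "n": total, "n_changed": changed}
            report["per_condition"] = per
        return report

    def rounded(self, ndigits: int = 2) -> Dict[str, float]:
        """tb and CI bounds at report precision (half-away-from-zero)."""
        return {
            "tb": round_half_away(self.tb, ndigits),
            "ci_lower": round_half_away(self.ci_lower, ndigits),
            "ci_upper": round_half_away(self.ci_upper, ndigits),
        }


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def proportion_se(n_changed: int, n_total: int) -> float:
    """Binomial standard error sqrt(p*q/n) with p = n_changed/n_total.

    Zero when p is 0 or 1 -- the usual Wald degeneracy, kept deliberately
    because the analysis pipeline is defined with this exact formula.
    """
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    if not 0 <= n_changed <= n_total:
        raise ValidationError("need 0 <= n_changed <= n_total")
    p = n_changed / n_total
    return math.sqrt(p * (1.0 - p) / n_total)


def pooled_se(se13: float, se12: float, se23: float) -> float:
    """Root-sum-of-squares pooling of the three proportion SEs.

    All three coefficients in tb have unit magnitude, so the delta-method SE
    reduces to sqrt(se13^2 + se12^2 + se23^2); covariances are ignored, which
    makes this an upper bound.
    """
    return math.sqrt(se13**2 + se12**2 + se23**2)


def tb_estimate(counts: ConditionCounts, z: float = 1.96) -> TBEstimate:
    """Point estimate, pooled-SE Wald CI and verdict from condition counts."""
    p = counts.proportions()
    tb = p.pr13 - p.pr12 - p.pr23
    se13 = proportion_se(*counts.counts["t1t3"])
    se12 = proportion_se(*counts.counts["t1t2"])
    se23 = proportion_se(*counts.counts["t2t3"])
    sp = pooled_se(se13, se12, se23)
    lo, hi = tb - z * sp, tb + z * sp
    if lo > 0:
        verdict = "violation"
    elif tb > 0:
        verdict = "trend"
    else:
        verdict = "none"
    return TBEstimate(
        tb=tb,
        se13=se13,
        se12=se12,
        se23=se23,
        se_pooled=sp,
        z=z,
        ci_lower=lo,
        ci_upper=hi,
        verdict=verdict,
    )


def apply_exclusions(
    recruited: Mapping[str, int], excluded: Mapping[str, int]
) -> Dict[str, int]:
    """Per-condition analyzable totals: recruited minus excluded."""
    totals = {}
    for cond in CONDITIONS:
        rem = int(recruited[cond]) - int(excluded[cond])
        if rem < 0:
            raise ValidationError(f"{cond}: more excluded than recruited")
        totals[cond] = rem
    return totals


def aggregate_participant_table(df: pd.DataFrame) -> ConditionCounts:
    """Aggregate a participant-level table to condition counts.

    Expects columns ``condition`` (t1t2 / t2t3 / t1t3), ``change`` (0/1) and
    optionally ``excluded`` (0/1); excluded rows are dropped before counting.
    """
    required = {"condition", "change"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    unknown = set(df["condition"].unique()) - set(CONDITIONS)
    if unknown:
        rows = df.index[df["condition"].isin(unknown)].tolist()[:5]
        raise ValidationError(f"unknown condition labels {sorted(unknown)} (rows {rows})")
    if "excluded" in df.columns:
        df = df[df["excluded"] == 0]
    if df.empty:
        raise ValidationError("no analyzable rows after exclusions")
    counts = {}
    for cond in CONDITIONS:
        sub = df[df["condition"] == cond]
        if sub.empty:
            raise ValidationError(f"no analyzable rows in condition {cond!r}")
        counts[cond] = (int(sub["change"].sum()), int(len(sub)))
    return ConditionCounts(counts)


TrueModel = Union[ChangeProbabilityTriple, mr.TrajectoryDistribution, mr.PopulationMixture, float]


def _true_change_probabilities(true_model: TrueModel) -> ChangeProbabilityTriple:
    """Accept a change triple, a classical model, or a quantum rotation angle."""
    if isinstance(true_model, ChangeProbabilityTriple):
        return true_model
    if isinstance(true_model, mr.TrajectoryDistribution):
        return mr.change_probabilities(true_model)
    if isinstance(true_model, mr.PopulationMixture):
        return mr.mixture_change_probabilities(true_model)
    return qm.protocol_change_probabilities(float(true_model))


def ci_coverage_simulation(
    true_model: TrueModel,
    n_per_condition: int,
    reps: int,
    seed: int,
    z: float = 1.96,
) -> Dict[str, float]:
    """Monte-Carlo coverage of the pooled-SE Wald CI and violation power.

    Draws ``reps`` independent replicate experiments with ``n_per_condition``
    participants per condition under the true model, runs the Wald analysis
    on each, and reports the fraction of CIs containing the true tb
    (coverage) and the fraction of "violation" verdicts (power).  Vectorized
    over replicates, so thousands of replicates take well under a second.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    true = _true_change_probabilities(true_model)
    true_tb = true.pr13 - true.pr12 - true.pr23
    rng = np.random.default_rng(seed)
    n = int(n_per_condition)
    ps = np.empty((reps, 3))
    for j, p_true in enumerate((true.pr13, true.pr12, true.pr23)):
        ps[:, j] = rng.binomial(n, p_true, size=reps) / n
    tb = ps[:, 0] - ps[:, 1] - ps[:, 2]
    se = np.sqrt((ps * (1.0 - ps) / n).sum(axis=1))
    lo, hi = tb - z * se, tb + z * se
    return {
        "coverage": float(np.mean((lo <= true_tb) & (true_tb <= hi))),
        "power": float(np.mean(lo > 0)),
        "true_tb": true_tb,
        "reps": reps,
        "n_per_condition": n,
    }
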