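"""Embedded change-judgment counts from two published mock-juror experiments.

Both experiments used a three-condition between-participants design: each
participant followed a two-day mock trial and answered a single binary
question about whether their guilt judgment changed over one time pair
(start vs after day 2; start vs after day 1; after day 1 vs after day 2).
Participants failing information-processing checks were excluded before
analysis.  The counts below are the recruitment, exclusion and change totals
needed to reproduce the published tb analysis without any download.
"""

from __future__ import annotations

from typing import Dict

from .tb_inference import ConditionCounts, apply_exclusions

__all__ = [
    "RECRUITED",
    "EXCLUDED",
    "CHANGED",
    "EXPECTED_ROUNDED",
    "condition_counts",
]

# Recruited participants per condition, prior to exclusions.
RECRUITED: Dict[str, Dict[str, int]] = {
    "exp1": {"t1t3": 133, "t1t2": 135, "t2t3": 133},
    "exp2": {"t1t3": 133, "t1t2": 139, "t2t3": 137},
}

# Exclusions due to information-processing failures.
EXCLUDED: Dict[str, Dict[str, int]] = {
    "exp1": {"t1t3": 42, "t1t2": 28, "t2t3": 38},
    "exp2": {"t1t3": 51, "t1t2": 31, "t2t3": 52},
}

# Participants reporting a change, among those retained.
CHANGED: Dict[str, Dict[str, int]] = {
    "exp1": {"t1t3": 7, "t1t2": 2, "t2t3": 7},
    "exp2": {"t1t3": 14, "t1t2": 4, "t2t3": 4},
}

# Published 2-dp values of tb and its 95% CI bounds, used by the
# `reproduce` command as its pass/fail reference.
EXPECTED_ROUNDED: Dict[str, Dict[str, float]] = {
    "exp1": {"tb": -0.02, "ci_lower": -0.10, "ci_upper": 0.06},
    "exp2": {"tb": 0.09, "ci_lower": -0.01, "ci_upper": 0.19},
}

EXPERIMENTS = ("exp1", "exp2")


def condition_counts(experiment: str) -> ConditionCounts:
    """Post-exclusion (n_changed, n_total) per condition for an experiment."""
    totals = apply_exclusions(RECRUITED[experiment], EXCLUDED[experiment])
    return ConditionCounts(
        {cond: (CHANGED[experiment][cond], totals[cond]) for cond in totals}
    )
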