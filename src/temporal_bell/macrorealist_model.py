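"""Classical (macrorealist) ground truth for three-time change judgments.

A macrorealist system has a definite guilt value at every time point, so a
participant's history is one of the 8 trajectories (g1, g2, g3) in {+1,-1}^3.
A macrorealist population is a probability distribution over trajectories
(or a mixture of such distributions across heterogeneous participants).  For
any such distribution the change frequencies obey the triangle-type bound
pr13 <= pr12 + pr23, i.e. tb <= 0: this module is the brute-force oracle for
the temporal Bell bound.

It also implements the two caveats that matter for interpreting an apparent
violation: population mixtures (the bound is linear, so mixing cannot break
it) and condition-specific report bias (an asymmetric binary channel between
the true change status and the reported one, which *can* produce spurious
violations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .inequality_core import (
    PROB_TOL,
    CONDITIONS,
    ChangeProbabilityTriple,
    CorrelationTriple,
    ValidationError,
)

__all__ = [
    "TRAJECTORIES",
    "TrajectoryDistribution",
    "PopulationMixture",
    "ReportBias",
    "correlations",
    "change_probabilities",
    "mixture_change_probabilities",
    "biased_observed_probabilities",
    "sample_participants",
]

#: The 8 classical trajectories (g1, g2, g3), ordered (+,+,+) first.
TRAJECTORIES: Tuple[Tuple[int, int, int], ...] = tuple(
    itertools.product((+1, -1), repeat=3)
)

_TRAJ_KEY = {t: "".join("+" if g > 0 else "-" for g in t) for t in TRAJECTORIES}
_KEY_TRAJ = {v: k for k, v in _TRAJ_KEY.items()}

# Per-trajectory indicators of a change over each time pair, in CONDITIONS
# order (t1t3, t1t2, t2t3); shape (8, 3).
_CHANGE_MATRIX = np.array(
    [[float(t[0] != t[2]), float(t[0] != t[1]), float(t[1] != t[2])] for t in TRAJECTORIES]
)
# Per-trajectory products g_i * g_j for pairs (t1,t2), (t2,t3), (t1,t3).
_PRODUCT_MATRIX = np.array(
    [[t[0] * t[1], t[1] * t[2], t[0] * t[2]] for t in TRAJECTORIES], dtype=float
)


@dataclass(frozen=True)
class TrajectoryDistribution:
    """Probability distribution over the 8 definite-value trajectories."""

    probs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != 8:
            raise ValidationError("need exactly 8 trajectory probabilities")
        arr = np.asarray(self.probs, dtype=float)
        if (arr < -PROB_TOL).any():
            raise ValidationError("negative trajectory probability")
        if abs(arr.sum() - 1.0) > PROB_TOL:
            raise ValidationError(f"trajectory probabilities sum to {arr.sum()!r}")

    # -- constructors -----------------------------------------------------
    @classmethod
    def point_mass(cls, trajectory: Tuple[int, int, int]) -> "TrajectoryDistribution":
        probs = [1.0 if t == trajectory else 0.0 for t in TRAJECTORIES]
        return cls(tuple(probs))

    @classmethod
    def uniform(cls) -> "TrajectoryDistribution":
        return cls((0.125,) * 8)

    @classmethod
    def random(cls, rng: np.random.Generator) -> "TrajectoryDistribution":
        return cls(tuple(rng.dirichlet(np.ones(8))))

    @classmethod
    def markov_chain(
        cls, p_start_guilty: float, flip12: float, flip23: float
    ) -> "TrajectoryDistribution":
        """Two-step Markov chain: start guilty w.p. p_start_guilty, flip the
        value between t1,t2 w.p. flip12 and between t2,t3 w.p. flip23.

        Convenient for dialing in target change probabilities:
        pr12 = flip12, pr23 = flip23, pr13 = flip12 + flip23 - 2*flip12*flip23.
        """
        probs = []
        for g1, g2, g3 in TRAJECTORIES:
            p = p_start_guilty if g1 > 0 else 1.0 - p_start_guilty
            p *= flip12 if g2 != g1 else 1.0 - flip12
            p *= flip23 if g3 != g2 else 1.0 - flip23
            probs.append(p)
        return cls(tuple(probs))

    # -- (de)serialisation ------------------------------------------------
    def to_json_dict(self) -> Dict[str, float]:
        return {_TRAJ_KEY[t]: p for t, p in zip(TRAJECTORIES, self.probs)}

    @classmethod
    def from_json_dict(cls, d: Mapping[str, float]) -> "TrajectoryDistribution":
        probs = [float(d.get(_TRAJ_KEY[t], 0.0)) for t in TRAJECTORIES]
        return cls(tuple(probs))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass(frozen=True)
class PopulationMixture:
    """Weighted mixture of trajectory distributions (heterogeneous population)."""

    components: Tuple[Tuple[float, TrajectoryDistribution], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("mixture needs at least one component")
        weights = np.array([w for w, _ in self.components], dtype=float)
        if (weights < -PROB_TOL).any():
            raise ValidationError("negative mixture weight")
        if abs(weights.sum() - 1.0) > PROB_TOL:
            raise ValidationError(f"mixture weights sum to {weights.sum()!r}")

    def averaged(self) -> TrajectoryDistribution:
        """The single distribution equivalent to the mixture (linearity)."""
        arr = sum(w * d.as_array() for w, d in self.components)
        return TrajectoryDistribution(tuple(arr))


@dataclass(frozen=True)
class ReportBias:
    """Asymmetric binary misreport channel, per between-participants condition.

    ``flip_yes_to_no[cond]`` is the probability a true change is reported as
    no change; ``flip_no_to_yes[cond]`` the reverse.  Zero everywhere is the
    identity channel.
    """

    flip_yes_to_no: Mapping[str, float] = field(default_factory=dict)
    flip_no_to_yes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.flip_yes_to_no, self.flip_no_to_yes):
            for cond, p in m.items():
                if cond not in CONDITIONS:
                    raise ValidationError(f"unknown condition {cond!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"flip probability {p!r} outside [0, 1]")

    def observed(self, cond: str, true_pr: float) -> float:
        """Observed change probability after the misreport channel."""
        y2n = self.flip_yes_to_no.get(cond, 0.0)
        n2y = self.flip_no_to_yes.get(cond, 0.0)
        return true_pr * (1.0 - y2n) + (1.0 - true_pr) * n2y


NO_BIAS = ReportBias()


def correlations(dist: TrajectoryDistribution) -> CorrelationTriple:
    """C_ij = sum over trajectories of p(traj) * g_i * g_j."""
    c12, c23, c13 = dist.as_array() @ _PRODUCT_MATRIX
    return CorrelationTriple(c_ab=c12, c_bc=c23, c_ac=c13)


def change_probabilities(dist: TrajectoryDistribution) -> ChangeProbabilityTriple:
    """pr_ij = probability that g_i != g_j; obeys pr13 <= pr12 + pr23."""
    pr13, pr12, pr23 = dist.as_array() @ _CHANGE_MATRIX
    return ChangeProbabilityTriple(pr13=pr13, pr12=pr12, pr23=pr23)


def batch_change_probabilities(probs: np.ndarray) -> np.ndarray:
    """Change probabilities for many distributions at once.

    ``probs`` has shape (m, 8) with rows summing to 1; returns shape (m, 3)
    in CONDITIONS order (pr13, pr12, pr23).  Used by the brute-force bound
    checks, which sweep ~1e5 random distributions.
    """
    return np.asarray(probs, dtype=float) @ _CHANGE_MATRIX


def batch_correlations(probs: np.ndarray) -> np.ndarray:
    """Correlations (C12, C23, C13) for many distributions; shape (m, 3)."""
    return np.asarray(probs, dtype=float) @ _PRODUCT_MATRIX


def mixture_change_probabilities(mix: PopulationMixture) -> ChangeProbabilityTriple:
    """Weighted average of component change probabilities.

    Because tb is linear in the distribution, this equals the change
    probabilities of the averaged distribution, and therefore still obeys
    tb <= 0: heterogeneity alone cannot fake a violation.
    """
    prs = np.array(
        [
            [w * p for p in (lambda c: (c.pr13, c.pr12, c.pr23))(change_probabilities(d))]
            for w, d in mix.components
        ]
    )
    pr13, pr12, pr23 = prs.sum(axis=0)
    return ChangeProbabilityTriple(pr13=pr13, pr12=pr12, pr23=pr23)


def biased_observed_probabilities(
    dist: TrajectoryDistribution, bias: ReportBias
) -> ChangeProbabilityTriple:
    """True change probabilities pushed through the per-condition misreport
    channel.  A condition-specific bias toward reporting changes can make the
    *observed* tb positive even though the underlying system is macrorealist.
    """
    true = change_probabilities(dist).as_condition_map()
    obs = {cond: bias.observed(cond, true[cond]) for cond in CONDITIONS}
    return ChangeProbabilityTriple(pr13=obs["t1t3"], pr12=obs["t1t2"], pr23=obs["t2t3"])


ModelInput = Union[TrajectoryDistribution, PopulationMixture]


def _as_distribution(dist_or_mix: ModelInput) -> TrajectoryDistribution:
    if isinstance(dist_or_mix, PopulationMixture):
        return dist_or_mix.averaged()
    return dist_or_mix


def sample_participants(
    dist_or_mix: ModelInput,
    bias: ReportBias,
    n_per_condition: Mapping[str, int],
    seed_or_rng: Union[int, np.random.Generator],
) -> Dict[str, Tuple[int, int]]:
    """Simulate a between-participants change-judgment experiment.

    Each simulated participant is assigned to exactly one condition (time
    pair), draws a trajectory from the population, reports whether the value
    changed over that pair through the bias channel.  Returns
    ``{condition: (n_changed, n_total)}``.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    true = change_probabilities(_as_distribution(dist_or_mix)).as_condition_map()
    counts: Dict[str, Tuple[int, int]] = {}
    for cond in CONDITIONS:
        n = int(n_per_condition[cond])
        if n < 1:
            raise ValidationError(f"need at least one participant in {cond!r}")
        p_obs = bias.observed(cond, true[cond])
        changed = int(rng.binomial(n, p_obs))
        counts[cond] = (changed, n)
    return counts
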