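# Methods

## The inequality and its two forms

For a ±1-valued question at three ordered times, macrorealism plus
noninvasive measurability implies the four Leggett–Garg inequalities

    s1·C_12 + s2·C_23 − s1·s2·C_13 ≤ 1,   s1, s2 ∈ {±1},

where C_ij = ⟨Q_i Q_j⟩.  `inequality_core.evaluate_inequality` reports the
margin of the (+1, +1) version (the one matched to the experimental design,
where small changes are expected over the short intervals and a large change
over the long one); `evaluate_all_versions` reports all four.  Two algebraic
facts are used as test invariants: the four margins always sum to −4
(so at most three can be positive for arbitrary correlation triples), and
for triples realizable by either ground-truth model at most one version can
be violated.  The change-frequency form follows from pr = (1 − C)/2:
tb = pr_13 − pr_12 − pr_23 equals half the (+1, +1) margin, identically.
Both forms are computed by separate code paths and the identity is asserted
on dense grids rather than assumed.

## Two-level quantum-like model

State: a real unit vector a_g|Guilty⟩ + a_i|Innocent⟩.  Real amplitudes
suffice because the protocol involves only one rotation axis and projective
measurements in a fixed basis; complex phases would be unobservable here.
Initial state |Innocent⟩; each day of evidence is a rotation by θ toward
|Guilty⟩ (the model's only free parameter, radians, default sweep range
[0, π/2]); answering is a Born-rule projection with collapse.

Each condition's statistics are generated by propagating the state through
*only* that condition's two measurements: since |Innocent⟩ is an eigenstate
of the first measurement, the t1 measurement is non-disturbing, and the
(t1,t3) pair evolves coherently through t2 — the model's idealization of a
change judgment that never probes the intermediate time.  Closed forms
(C_12 = C_23 = cos 2θ, C_13 = cos 4θ; pr_12 = pr_23 = sin²θ,
pr_13 = sin²2θ) are used exclusively as test oracles against the simulated
path, with agreement required to 1e−10.  The violation tb(θ) = sin²2θ −
2 sin²θ is maximal at θ = π/6 (tb = 0.25, margin 0.5), verified by dense
grid search at step 1e−4 rad.

## Macrorealist model

A population is a probability distribution over the 8 definite-value
trajectories (g1, g2, g3) ∈ {±1}³, optionally a weighted mixture of such
distributions.  Change probabilities and correlations are exact linear
functionals of the distribution (matrix products, vectorized for the 1e5
random-distribution sweeps).  Because tb is linear, mixtures reduce to their
averaged distribution — population heterogeneity alone cannot produce a
violation.  What *can* is condition-specific report bias, modeled as the
simplest channel exhibiting the caveat: an asymmetric binary misreport map
per condition, observed pr = true_pr·(1 − flip_yes_to_no) +
(1 − true_pr)·flip_no_to_yes.  Its magnitude in real data is unknown; it is
exposed as a free parameter with default 0 rather than given a "realistic"
range.  A convenience `markov_chain(p_start, flip12, flip23)` constructor
dials in target change probabilities (pr_12 = flip12, pr_23 = flip23,
pr_13 = flip12 + flip23 − 2·flip12·flip23).

## Inference

tb is estimated by plugging in per-condition sample proportions.  Each
proportion gets the binomial SE sqrt(pq/n); the pooled SE is the
root-sum-of-squares of the three (all coefficients in tb have unit
magnitude), which ignores covariances and is therefore an upper bound —
exact here, since the between-participants design makes the three
proportions independent.  The 95% CI is tb ± 1.96·SE_pooled (z
configurable).  Verdicts: "violation" if the CI lies above 0, "trend" if
tb > 0 but the CI straddles 0, else "none".

Numerical conventions: reported values are rounded half-away-from-zero to
2 decimals, with full precision retained internally; the CI is computed at
full precision and only then rounded.  Degenerate proportions (p ∈ {0, 1})
give SE = 0 — the known Wald-interval failure mode, kept deliberately
because the analysis is defined by this exact formula; no continuity
correction is applied.  Probability containers are validated to an absolute
normalization tolerance of 1e−12 (all arithmetic is closed-form).

Calibration by simulation (`ci_coverage_simulation`, vectorized over
replicates): under classical truths with change probabilities in
[0.05, 0.5] at n = 200/condition, coverage is near nominal (≈0.94–0.95; the
Wald interval is mildly anti-conservative) and the false-violation rate is
at most a few percent; under the quantum truth θ = π/6 at n =
1000/condition, power is essentially 1.  Problem sizes — 2000 replicates,
1e5 random distributions, 1e4–1e5 synthetic participants — were chosen as
the smallest that make the Monte-Carlo error negligible relative to the
asserted tolerances.

## Synthetic data generator

The generator emulates the study design the analysis assumes: three
between-participants conditions (one time pair each), every participant
answering exactly one binary change question; recruitment counts and
exclusion rates default to free parameters and in the scaled-replication
tests mirror the second experiment's recruitment (133/139/137) and
exclusion rates (51/133, 31/139, 52/137).  Exclusions are simulated as
response-independent Bernoulli flags — an idealization: real exclusions
were based on free-text quality and could correlate with responses.  An
optional `exclusion_change_shift` knob adds that correlation for
sensitivity analyses (default 0, range unknown in real data).  Optional
log-normal reaction times exist only so exported CSVs have a realistic
schema; no RT statistics are computed.  A fixed integer seed makes output
byte-identical across runs.

What passing tests do *not* show about real data: the generator draws each
response independently from the model's change probability, so it cannot
exhibit content-based exclusion artifacts, comprehension failures, or
any within-participant structure; conclusions about those require the raw
study data, which the package deliberately does not depend on.

## Parameter recovery

`recover_theta` fits θ ∈ [0, π/2] by least squares of the observed
per-condition proportions against (sin²θ, sin²θ, sin²2θ): a coarse grid
scan (step 1e−3 rad) followed by bounded scalar minimization around the
grid optimum, with the grid result kept if refinement does not improve the
loss (guards the flat-gradient case θ = 0).  At 1e4 participants per
condition the angle is recovered to well within 0.02 rad across
θ ∈ {π/12, π/6, π/4}.

## Design choices and limitations

- Conditions are keyed by literal time-pair strings `t1t2`, `t2t3`, `t1t3`
  throughout (APIs, CSV schemas, JSON reports).
- The CLI (`temporal-bell reproduce | analyze | simulate | sweep`) is a thin
  layer over the library; exit codes are 0 (success), 2 (validation/schema
  error), 3 (reproduction mismatch).
- Out of scope: more than three time points, density-matrix/weak-measurement
  extensions of the two-level model, within-participant repeated
  measurements, alternatives to the Wald interval, and reaction-time
  statistics.
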