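# Methods

## Model and assumptions

A procedure is modelled as an ordered list of activities executed
sequentially, with directed dependencies (provider → consumer) carrying
rework probabilities. The model is purely additive in time: activities
do not overlap, there are no resource constraints, and rework adds
duration without rescheduling. Rework of a loop member does not
re-trigger rework of activities outside the loop (first-order
semantics); higher-order propagation is treated analytically in the risk
module's geometric series, not in the simulation.

Durations are triangular. This is a deliberate small-data choice: a
handful of annotated video observations per activity supports no more
than a minimum, a mode estimate, and a maximum. Sampling uses the
closed-form inverse CDF (cross-checked in the tests against
`scipy.stats.triang.ppf`), with results clipped into [BCV, WCV] to guard
against one-ulp excursions of the subtraction form; degenerate estimates
(BCV = MLV = WCV) are point masses.

## Rework mechanics

For a dependency with probability p, the repeat count nr counts
consecutive uniform draws below p, truncated at a cap:
P(nr = k) = p^k (1 − p) for k below the cap, with the remaining mass on
the cap. Its mean is Σ_{k=1..cap} p^k. Each repeat of activity *a* costs
D₀(a) × RI(a) × IC_i(a), where D₀ is the duration drawn for this run
(rework is a fraction of the realized first-trial work, so it is not
re-sampled), RI the fraction of the activity that must be redone, and
IC_i the improvement multiplier for the i-th iteration (a finite list
extends by repeating its last value; the fully-trained default is a
constant 1.0).

Two conventions deserve note:

- **Trigger direction.** The default ("standard") convention reworks
  when the draw falls *below* p, preserving p's meaning as a probability
  of rework. The inverted convention (rework while the draw *exceeds*
  p), found in some legacy spreadsheet macros, is available as
  `rework_trigger="literal"` for fidelity experiments; under it a
  nominal 0.1 would trigger rework 90% of the time, which we consider a
  specification artefact rather than intended semantics.
- **Certainty cap.** p ≥ 0.999 is treated as observed certainty: exactly
  one repeat per pass (an uncapped geometric at p = 1 never terminates).
  Elsewhere the cap defaults to 25 repeats per dependency, where the
  truncated mass is negligible for realistic probabilities (1e-25 at
  p = 0.1). This rule intentionally breaks stochastic monotonicity in p
  across the 0.999 boundary; the monotonicity property is therefore
  stated and tested below that threshold.

Loops are the strongly connected components (size ≥ 2) of the dependency
graph, computed via networkx and checked in the tests against an
independent boolean-reachability oracle. A loop is simulated by walking
its internal dependencies — the cyclic consecutive pairs first, then any
chords — each contributing rework of its consumer. Every dependency
outside a loop contributes single-edge rework with the same machinery,
including ordinary feed-forward chain dependencies: a deviation in a
completed step can force its successor to be redone even without a
feedback cycle.

The execution order reported by partitioning is a deterministic
topological sort of the loop-condensed graph (Kahn's algorithm,
ties broken by declared order, loop members kept contiguous); for the
packaged structures this coincides with the declared protocol sequence.
Active sets are maximal consecutive runs executable before an activity
whose provider has not yet run; they describe where execution pauses on
feedback but do not change the additive total.

## Randomness and determinism

A single seeded `numpy` generator drives each study. Within a run,
draws are consumed in a fixed order: one duration per activity in
declared order, then a fixed-size block of `max_reworks_per_edge`
uniforms per rework edge (loops in partition order, then remaining edges
by consumer-then-provider position). Consuming a full block regardless
of the realized repeat count keeps later draws aligned when a single
probability is changed, which is what makes the paired monotonicity
comparison meaningful and same-seed results bit-identical.
`duration_source="mlv_only"` skips duration draws entirely and uses the
most-likely values.

The deterministic companion `expected_duration` computes
Σ MLV + Σ_edges MLV × RI × Σ_k IC_k p^k and agrees with the mean of the
`mlv_only` Monte Carlo mode (verified within three standard errors).

## Parameter estimation

Volatility and sensitivity are plain frequency ratios with explicit
undefined-estimate errors at zero denominators. When a dependency has
several deviation classes with distinct sensitivities, per-class rework
probabilities combine as 1 − Π(1 − p_class) (rework if at least one
class triggers). The MLV of a fitted triangular distribution is the
sample median for n ≤ 5 and a Robertson–Cryer half-sample mode for
larger samples — robust in the small-sample, high-variation regime —
clamped to [min, max]; the estimator is selectable.

## Risk propagation

Per dependency, R = P_ir × RI of the consumer; cumulative risk is the
geometric series CR = R/(1 − R), stored in a matrix indexed
[consumer, provider] so that column sums f_j give the risk an activity
transfers and row sums e_i the risk it receives. Pairs with R ≥ 1
diverge; they are reported (with a count) and excluded from the margins
rather than silently saturated, since including an unbounded term would
misstate the totals. Both the grand total ΣΣ CR and the per-activity
combined load f_j + e_j are reported, as the two are useful at different
granularities. The propagation is per-pair (a scalar power series), not
a matrix power: path-dependent multi-hop propagation is out of scope.

## Packaged structures and the synthetic generator

Two bundled structures mirror published laparoscopic-cholecystectomy
protocols used to validate this class of model: a 9-activity standard
procedure with a bleeding-driven loop between cystic-artery dissection
and cutting (loop probability 1, all other dependencies 0.1, impacts
equal to probabilities) and an 11-activity pediatric variant with no
loop (all probabilities and impacts 0.1, reflecting that no rework was
observed and 0.1 is a realistic floor). The per-activity duration
profiles are **synthetic**: the published per-activity timings are not
available as data, so fixed plausible weight profiles are scaled so the
MLVs sum exactly to a chosen total (defaults 10 and 5.5 minutes), with
BCV = 0.8 × MLV and WCV = 1.5 × MLV. Consequently the packaged
structures exercise every structural and probabilistic feature of the
real protocols — loop identification, certain rework, below-diagonal
cleaning dependencies — but their absolute simulated durations are
stand-ins: passing tests demonstrate correctness of the machinery, not
agreement with any particular operating-room timing. The random-DSM
generator produces seeded reproducible instances (edge density,
probability range) for property testing.

The validation-error statistic is |predicted − reference| / predicted ×
100; the predicted value is the denominator, the only convention
consistent with both published comparisons (10 vs 9.75 min → 2.5%;
5.7 vs 5.5 min within 4%).

## Numerical choices

- Accounting identity: totals are assembled as first-trial + rework with
  `math.fsum`, and the identity is asserted exactly (bit-level), not
  approximately.
- Risk margins use `fsum` per row/column; divergent entries are masked
  before summation.
- Zero-probability matrix cells are "no dependency" and are dropped at
  construction; probabilities are validated into [0, 1] with errors
  naming the offending entry.
- Monte Carlo problem sizes in the tests (10 000–50 000 runs) keep
  statistical checks at three standard errors while the full suite runs
  in well under a minute on one core.
- Time unit is minutes throughout; summaries are meaningful to about
  0.1 min, matching the precision achievable from annotated video.

## Known limitations

- No overlap/compression of activities, no resources, no costs.
- First-order rework only outside the analytic risk series.
- The certainty cap collapses p ∈ [0.999, 1] to one repeat per pass.
- Synthetic duration profiles (see above): absolute totals from the
  packaged structures are illustrative.
- The half-sample mode estimator is one of several defensible MLV
  choices; with n ≤ 5 observations the median is used instead.
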