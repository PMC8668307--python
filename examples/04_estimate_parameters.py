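"""Estimate model parameters from annotated observation tallies.

Rework probability is volatility (how often the provider step deviates
from protocol) times sensitivity (how often a deviation forces rework of
the consumer).  Durations observed across executions are condensed into
triangular three-point estimates.
"""

from dsmsim import (
    DurationSample,
    ObservationCounts,
    aggregate_rework_impact,
    combine_rework_probabilities,
    estimate_sensitivity,
    estimate_volatility,
    fit_triangular,
    rework_probability,
)

# ten observations of a dissection step: three deviations, one of which
# caused the downstream clipping step to be redone
counts = ObservationCounts(n_o=10, n_oc=3, n_ic=3, n_ir=1)
p_i = estimate_volatility(counts)
p_r = estimate_sensitivity(counts)
p_ir = rework_probability(p_i, p_r)
print(f"volatility P_i = {p_i:.2f}, sensitivity P_r = {p_r:.2f}")
print(f"rework probability P_ir = {p_ir:.2f}")

# a second deviation class (instrument slip) for the same dependency
slip = ObservationCounts(n_o=10, n_oc=1, n_ic=1, n_ir=1)
p_slip = rework_probability(estimate_volatility(slip), estimate_sensitivity(slip))
combined = combine_rework_probabilities([p_ir, p_slip])
print(f"combined over 2 deviation classes: {combined:.2f}")

# expert assessments of how much of the step must be redone
ri = aggregate_rework_impact([0.2, 0.3, 0.4])
print(f"aggregated rework impact RI = {ri:.2f}")

# observed execution times (minutes) -> triangular estimate
tri = fit_triangular(DurationSample("A4", (1.2, 1.4, 1.5, 1.9, 2.6)))
print(f"triangular fit: BCV {tri.bcv}, MLV {tri.mlv}, WCV {tri.wcv} min")
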