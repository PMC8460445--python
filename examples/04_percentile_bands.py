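"""Categorical percentile-band analysis against the continuous prediction.

Bands are cut at quantiles of the unilateral-case PRS distribution with the
40th-60th percentile as reference.  If the continuous per-SD model holds,
the fitted band hazard ratios should track the smooth curve implied by the
continuous estimate (the expected relative hazard within each band).
"""

import math

from cbcprs.eligibility import apply_eligibility, build_risk_intervals
from cbcprs.simulate import SimulationConfig, simulate_study
from cbcprs.survival import (
    compute_percentile_bands,
    fit_cox_categorical,
    fit_cox_continuous,
    predict_band_hrs,
)

config = SimulationConfig(n_subjects=20_000, beta_true=math.log(1.3), seed=5)
study = simulate_study(config, with_genotypes=False)
eligible, _ = apply_eligibility(study["records_complete"])
intervals = build_risk_intervals(eligible).intervals

continuous = fit_cox_continuous(intervals)
bands = compute_percentile_bands(intervals.loc[intervals["event"] == 0, "z"].to_numpy())
categorical = fit_cox_categorical(intervals, bands)
predicted = predict_band_hrs(continuous.coefficients["z"], bands)

print(f"continuous HR per SD: {continuous.hr['z']:.3f}\n")
print("band      fitted HR   predicted HR")
for label in bands.labels:
    term = f"band_{label.replace('-', '_')}"
    fitted = categorical.hr.get(term, 1.0)
    print(f"{label:8s}  {fitted:9.2f}   {predicted[label]:11.2f}")
# agreement between the two columns is the consistency check between the
# categorical and continuous PRS models
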