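"""Compute and standardize the three PRS flavours from dosages and weights.

The raw score for a subject is the weighted sum of effect-allele dosages;
it is reported in SD units of an external reference population (here the
panel is built with unit variance, so the reference SD is 1).
"""

from cbcprs.scoring import StandardizationSpec, compute_prs, standardize_prs
from cbcprs.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(n_subjects=2000, n_variants=313, seed=11))
panel, genotypes = study["panel"], study["genotypes"]

for flavor in ("overall", "er_positive", "er_negative"):
    scores = compute_prs(genotypes, panel, flavor=flavor)
    z, spec = standardize_prs(scores["raw_score"], StandardizationSpec(scale=1.0))
    print(
        f"{flavor:12s} raw mean {scores['raw_score'].mean():+.3f} "
        f"sd {scores['raw_score'].std():.3f} -> z mean {z.mean():+.3f} sd {z.std():.3f}"
    )
# z is centred on the cohort mean and scaled by the reference SD, so a value
# of +1 means one reference-population SD above the cohort average.
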