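"""Generate a small synthetic case-control cohort and inspect its ground truth.

The generator plants (i) weaker within-network correlations for the consumer
group and (ii) a structural model in which group membership lowers a latent
DMN-efficiency construct (path a) which in turn lowers two cognitive scores
(path b), so the planted indirect effect is exactly a*b.
"""

import numpy as np

from waveconn import CohortConfig, generate_cohort

config = CohortConfig(
    n_per_group=(12, 12),
    n_regions=40,
    network_sizes={"DMN": 10, "SN": 6, "FPN": 8},
    n_timepoints=256,
    seed=7,
)
cohort = generate_cohort(config)

manifest = cohort.manifest()
print(manifest.groupby("group")[["age"]].mean().round(2))
print(f"\nsubjects: {len(cohort.subjects)} "
      f"(IC {sum(s.group == 'IC' for s in cohort.subjects)}, "
      f"HC {sum(s.group == 'HC' for s in cohort.subjects)})")

ts = cohort.timeseries["sub-000"]
print(f"time series shape per subject: {ts.data.shape} (T x R), TR {ts.tr_seconds} s")

truth = cohort.ground_truth
print("\nplanted within-network correlations:")
for group, rho in truth.rho_within.items():
    print(f"  {group}: {rho}")
print("planted indirect effect for the Stroop score "
      f"(a*b): {truth.indirect_effect('score_stroop'):+.2f}")

# empirical check: within-DMN correlation of one HC subject approaches target
hc_id = next(s.subject_id for s in cohort.subjects if s.group == "HC")
r = np.corrcoef(cohort.timeseries[hc_id].data, rowvar=False)
dmn = cohort.parcels.nodes_in("DMN")
within = r[np.ix_(dmn, dmn)][np.triu_indices(len(dmn), 1)]
print(f"empirical within-DMN r for one HC subject: {within.mean():.2f} "
      f"(target {truth.rho_within['HC']['DMN']})")
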