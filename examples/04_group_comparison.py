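"""Group comparison of efficiency and cognition with FDR control.

Runs the connectivity/efficiency stages for every subject of a small cohort
with a planted within-DMN deficit in the consumer group, then compares the
groups: Student's t for the efficiency family, Kruskal-Wallis for cognitive
scores, Benjamini-Hochberg correction within each family.
"""

from waveconn import CohortConfig, PipelineConfig, generate_cohort
from waveconn.efficiency import efficiency_record, efficiency_table
from waveconn.inference import compare_cohort
from waveconn.pipeline import subject_connectivity

config = CohortConfig(
    n_per_group=(20, 20),
    n_regions=60,
    network_sizes={"DMN": 12, "SN": 10, "FPN": 10},
    n_timepoints=500,
    rho_within={"HC": 0.6, "IC": {"DMN": 0.35, "SN": 0.6, "FPN": 0.6}},
    rho_between=0.1,
    seed=21,
)
pipeline = PipelineConfig(simulate=config, seed=21)

cohort = generate_cohort(config)
records = []
for sid, ts in cohort.timeseries.items():
    _, adj = subject_connectivity(ts.data, pipeline, region_ids=cohort.parcels.region_ids)
    records.append(efficiency_record(adj, cohort.parcels, sid))

results = compare_cohort(efficiency_table(records), cohort.manifest())
print(f"{'variable':24s} {'test':15s} {'stat':>8s} {'p_fdr':>10s}")
for r in results:
    flag = " *" if r.p_adjusted < 0.05 else ""
    print(f"{r.variable:24s} {r.test:15s} {r.statistic:8.2f} {r.p_adjusted:10.2g}{flag}")
print("\nThe DMN carries the planted correlation gap: positive t, HC above IC."
      "\nBecause the edge budget is fixed, edges the weak IC DMN loses are"
      "\nreallocated elsewhere in the graph, which can *raise* the consumers'"
      "\nwhole-graph (and occasionally another network's) efficiency - a known"
      "\ncoupling of fixed-density thresholding, visible as negative t values."
      "\nCognitive scores differ through the planted direct/mediated paths.")
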