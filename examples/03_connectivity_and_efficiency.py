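"""From one subject's time series to a fixed-density graph and its efficiency.

The correlation matrix is computed on level-4 MODWT coefficients, binarized
by keeping exactly the top 5% of region pairs (the threshold adapts per
subject; the edge count never does), and summarized by global efficiency and
per-network subnetwork efficiency.
"""

from waveconn import (
    CohortConfig,
    PipelineConfig,
    make_parcel_table,
    simulate_subject_timeseries,
)
from waveconn.efficiency import efficiency_record
from waveconn.pipeline import subject_connectivity

networks = {"DMN": 10, "SN": 6, "FPN": 8}
parcels = make_parcel_table(40, networks)
config = CohortConfig(
    n_per_group=(2, 2), n_regions=40, network_sizes=networks, n_timepoints=500, seed=3
)
ts = simulate_subject_timeseries(config, parcels, "HC", subject_seed=11)

pipeline = PipelineConfig(simulate=config, density=0.05)
corr, adj = subject_connectivity(ts.data, pipeline, region_ids=parcels.region_ids)
print(f"kept {adj.edge_count} of {40 * 39 // 2} region pairs "
      f"(density {adj.density:.3f}, attained threshold r = {adj.threshold:.3f})")

record = efficiency_record(adj, parcels, ts.subject_id)
print(f"global efficiency E = {record.e_global:.3f}")
for name, value in record.e_networks.items():
    print(f"  E_s({name}) = {value:.3f}  (n_s = {record.n_s[name]})")
print("\nWithin-network correlations are planted stronger than background, so"
      "\nthe 5% strongest edges concentrate inside the named networks and the"
      "\nsubnetwork efficiencies sit far above the whole-graph value.")
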