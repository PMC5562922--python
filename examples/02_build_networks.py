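"""From time series to density-thresholded binary networks.

Shows the Pearson connectivity step, the density sweep, and the two
data-driven rules that fix the sweep endpoints (full connectedness for the
minimum; per-subject FDR on edge p-values for the maximum).
"""

from fcnet import (
    CohortSpec,
    DensitySweep,
    build_sweep_networks,
    find_max_density_fdr,
    find_min_connected_density,
    generate_cohort,
    pearson_connectivity,
)

# stronger between-module coupling so that, as in typical resting-state
# cohorts, the FDR rule admits more edges than connectedness requires
spec = CohortSpec(n_regions=30, n_per_group=10, rho_within=0.5,
                  rho_between=0.2, seed=2)
records, _ = generate_cohort(spec)
cms = [pearson_connectivity(r) for r in records]

d_min = find_min_connected_density(cms, sweep_step=0.005)
frac = find_max_density_fdr(cms, q=0.05)
print(f"smallest grid density with every subject connected: {d_min:.3f}")
print(f"largest FDR-safe edge fraction across subjects:     {frac:.3f}")
# any density between these keeps every network whole while retaining only
# edges that survive FDR correction for every subject

sweep = DensitySweep()  # default 0.245..0.300 step 0.005
nets = build_sweep_networks(cms[0], sweep)
print(f"sweep: {len(nets)} networks, edge counts "
      f"{nets[0].n_edges}..{nets[-1].n_edges} (nested)")
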