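"""Full group analysis: AUC curves, permutation tests, FDR, behavior.

Runs the entire chain on a scaled cohort with a planted 8-node effect and
prints which nodes the pipeline recovers and how the trained group's
behavior couples to them.
"""

from fcnet import CohortSpec, RunConfig, analyze_cohort, generate_cohort
from fcnet.stats import behavior_correlation

spec = CohortSpec(n_regions=30, n_per_group=72, rho_within=0.3,
                  rho_between=0.1, delta=0.30, delta_sd=0.15,
                  behavior_coupling=0.85 * 8.01, seed=4)
records, manifest = generate_cohort(spec)

cfg = RunConfig(ensemble_size=0, n_perm=5000, include_globals=False, seed=4)
result = analyze_cohort(records, cfg)

planted = set(int(i) for i in spec.planted_regions)
for metric, nodes in result.report["significant_nodes"].items():
    hits = planted & set(nodes)
    print(f"{metric}: {len(nodes)} significant nodes, "
          f"{len(hits)}/{len(planted)} planted recovered, "
          f"{len(set(nodes) - planted)} false positives")

auc = result.auc
for group in ("trained", "control"):
    sub = auc[(auc.metric == "local_efficiency")
              & (auc.node.isin(list(planted))) & (auc.group == group)]
    per_subject = sub.groupby("subject_id").auc.mean()
    scores = manifest.set_index("subject_id").score.loc[per_subject.index]
    r, p = behavior_correlation(per_subject.to_numpy(), scores.to_numpy())
    print(f"{group}: behavior vs planted local-efficiency AUC "
          f"r = {r:+.2f} (p = {p:.3f})")
# the trained group shows a positive, significant correlation because its
# scores were coupled to realized connectivity; the control group does not
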