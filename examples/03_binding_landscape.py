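"""Quantify binding scores and build the association landscape.

Simulates a dataset in which membrane-protein mRNAs (MPRs) bind the tagged
protein preferentially — more strongly under high Mg2+ — then runs the full
quantification: RPKM, detection filter, pooled binding scores, decile
quotas, and top/bottom-30% enrichment statistics per condition.
"""

from csplandscape import (
    SimulationConfig,
    binding_scores,
    landscape_report,
    simulate_annotation,
    simulate_counts,
)

config = SimulationConfig(n_genes=2000, seed=1)
annotation = simulate_annotation(config)
counts, truth = simulate_counts(annotation, config)

for condition in config.conditions:
    scores = binding_scores(counts, annotation, condition=condition)
    report = landscape_report(scores, annotation, n_bins=10, fraction=0.30)
    enr = report["enrichment"].set_index(["set", "category"])
    mpr_top = enr.loc[("top", "MPR")]
    cpr_bottom = enr.loc[("bottom", "CPR")]
    print(f"\n[{condition}] {len(scores)} detected mRNAs, "
          f"top/bottom sets of {len(report['top_set'])} genes")
    print(f"  MPR in top 30%:    {mpr_top['k']}/{mpr_top['K']}  "
          f"fold={mpr_top['fold_enrichment']:.2f}  p={mpr_top['p_hypergeometric']:.2e}")
    print(f"  CPR in bottom 30%: {cpr_bottom['k']}/{cpr_bottom['K']}  "
          f"fold={cpr_bottom['fold_enrichment']:.2f}  p={cpr_bottom['p_hypergeometric']:.2e}")
    print(f"  smoothed MPR quota by decile: "
          f"{[round(q, 2) for q in report['quota_smoothed']['MPR']]}")
# MPRs crowd the most-associated deciles and CPRs the least-associated
# ones, and the separation sharpens under the high-Mg2+ condition — the
# qualitative signature the binding-score landscape is designed to expose.
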