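"""Correlate gene-network activity with the serum protein panel and
extract HEALTH/INJURY signatures.

Axis membership (which networks are metabolic vs inflammatory) normally
comes from functional annotation; here the generator's ground truth plays
that role. Proteins with |Spearman rho| > 0.6 and p < 0.05 against an axis
enter the directional categories; HEALTH = MB up or INF down, INJURY =
MB down or INF up; the top 10 by |rho| form each signature.

A larger simulated cohort (n=200) is used so that the planted couplings
are measurable; at the study's n=15 the same machinery runs but single-
cohort estimates scatter widely.
"""

from dataclasses import replace

import graftaxis as ga

cfg = replace(ga.reference_scenario(), n_samples=200)
bundle, truth = ga.generate_cohort(cfg, seed=1)

# networks = planted modules; axes from the ground-truth annotation
labels = truth.gene_to_module[truth.gene_to_module > 0]
z = ga.zscore_genes(ga.ExpressionMatrix(bundle.expression.data.loc[labels.index]))
axes = [ga.AxisDefinition(a, [m for m, ax in truth.module_to_axis.items() if ax == a])
        for a in ("MB", "INF")]

axis_act = ga.axis_activity(z, labels, axes)
table = ga.protein_axis_table(axis_act, bundle.proteins)

for cat in ("INJURY", "HEALTH"):
    sig = ga.extract_signature(table, cat, rho_min=0.6, p_max=0.05, k=10)
    print(f"{cat} top-{len(sig.members)}: {', '.join(sig.members)}")

planted_injury = truth.proteins_for_axis("INF", 1)
sig = ga.extract_signature(table, "INJURY", k=10)
hits = len(set(planted_injury) & set(sig.members))
print(f"planted INJURY-like proteins recovered: {hits}/10")
print("P001..P010 were planted INJURY-like (MB down / INF up), "
      "P011..P020 HEALTH-like; the filter recovers them from 159 proteins.")
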