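"""Cluster TF fold-change trajectories into model profiles and test
over-representation of an annotation term among treatment-responsive genes.
"""

import pandas as pd

import vdegkit as vk

cfg = vk.SimConfig(n_genes=800, seed=3, n_tfs=40)
counts, design, lengths, truth = vk.simulate_counts(cfg)
factors = vk.size_factors(counts)
dispersions = vk.estimate_dispersion(counts, design, factors)

ts_tables = {
    spec.numerator[1]: vk.wald_test(counts, design, spec, factors, dispersions)
    for spec in vk.build_contrasts(design, "TS")
}

# trajectories of the TFs that are DE in at least one treatment-vs-baseline day
detfs = sorted(
    {g for t in ts_tables.values() for g in vk.call_degs(t).genes}
    & set(truth.tf_families)
)
traj = vk.build_trajectories(ts_tables, detfs)
models = vk.generate_model_profiles(c=1, n_transitions=4, m=26)
assignment = vk.assign_genes(traj, models)
significance = vk.profile_significance(assignment, traj, models)

print(f"{len(detfs)} differentially expressed TFs assigned to "
      f"{assignment['profile'].nunique()} of {len(models)} model profiles")
print(significance[significance["observed"] > 0]
      [["observed", "expected", "pvalue", "significant"]].round(3))
# 'expected' is the permutation-based size each profile would reach by chance;
# a significant profile holds many more trajectories than that.

annotation = vk.simulate_annotations(cfg, truth)
study = set(truth.genes_of_class("cppu_only"))
res = vk.hypergeom_enrich(study, set(truth.classes), annotation, by_namespace=False)
print("\ntop enrichment of the treatment-only gene set:")
print(res.head(3)[["term", "k", "K", "pvalue", "padj"]].to_string(index=False))
# the planted term should dominate: the simulator enriched it among exactly
# these genes
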