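"""Generate a synthetic case/control cohort with planted structure.

Builds variant tables, signed functional-score matrices, sulcal graphs
and a gene annotation with a planted enriched set, then prints the
cohort dimensions and the planted ground truth a downstream analysis
should recover.
"""

from sulcalvar.config import SimulationConfig
from sulcalvar.synthetic import simulate_study

cfg = SimulationConfig(seed=42, n_case=20, n_control=20,
                       n_annotations=80, planted_module_sizes=(20, 20),
                       effect_annotation_count=8)
study = simulate_study(cfg)

variants = study["variants"]
scores = study["scores"]
truth = study["truth"]

print(f"variants: {len(variants)} across "
      f"{variants['participant'].nunique()} participants")
print(f"score matrix: {scores.shape[0]} variants x "
      f"{scores.shape[1]} annotations")
print(f"effect annotations (case tails inflated): "
      f"{truth.effect_annotations}")
print("planted modules:",
      truth.module_membership.value_counts().to_dict())
print(f"planted enriched gene set: {len(truth.enriched_genes)} genes")
print(f"sulcal graphs: {len(study['graphs'])} participants, "
      f"{len(next(iter(study['graphs'].values())))} region(s) each")

# The effect annotations have case-cohort scores that are more extreme
# in both tails; the module annotations share a per-participant latent
# factor; participant graph perturbation is tied to that factor.
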