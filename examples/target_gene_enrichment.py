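"""Top-variant prioritization, nearest-TSS targets and enrichment.

Selects each case participant's highest-scoring variant on a target
annotation, assigns the nearest transcription start site within 20 kb
as the likely target gene, and tests gene sets for over-representation
against the background of all assigned target genes.
"""

import pandas as pd

from sulcalvar.config import SimulationConfig
from sulcalvar.prioritization import (
    assign_targets,
    hypergeometric_enrichment,
    nearest_tss_bulk,
    recurrent_targets,
    top_variant_per_participant,
)
from sulcalvar.synthetic import gen_cohort_scores, gen_gene_annotation

cfg = SimulationConfig(seed=9, n_case=40, n_control=10, n_annotations=70)
variants, scores, truth = gen_cohort_scores(cfg)
tss, gene_sets = gen_gene_annotation(cfg, variants, scores, truth)

vid = (variants["chrom"] + ":" + variants["pos"].astype(str)
       + ":" + variants["ref"] + ":" + variants["alt"])
meta = variants.copy()
meta.index = vid
case = meta[meta["cohort"] == "case"]
pmap = pd.Series(case["participant"], index=case.index)

target_annotation = truth.effect_annotations[0]
top = top_variant_per_participant(
    scores.loc[case.index, target_annotation], pmap)
print(f"top variant per participant on {target_annotation}: "
      f"{len(top)} variants")

assignments = assign_targets(top, tss)
assigned = [a for a in assignments if a.gene]
print(f"assigned a target gene within 20 kb: {len(assigned)}/{len(top)}")
print("recurrent targets (>= 2 variants):")
print(recurrent_targets(assignments, min_count=2).head().to_string(
    index=False))

study = sorted({a.gene for a in assigned})
background = set(nearest_tss_bulk(case, tss).dropna()) | set(study)
enrichment = hypergeometric_enrichment(study, sorted(background),
                                       gene_sets)
print("\nenrichment (hypergeometric, BH-adjusted):")
print(enrichment.head(4).to_string(index=False))
# The planted set should rank first with adjusted p << 0.05: the
# generator placed enriched-gene TSSs near the case cohort's
# top-scoring variants, while decoy sets are random draws.
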