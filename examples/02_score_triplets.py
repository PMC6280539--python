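"""Score every triplet for disease-specific dysregulation and test
significance with the label-permutation null.

Each triplet gets three scores: the gene's disease risk score (S_risk), the
product of the mRNA and miRNA differential-expression P values (S_P,
smaller = stronger), and the absolute disease-vs-control difference of the
miRNA-mRNA Pearson correlation (S_pcc). Equal-weight rank aggregation
combines them into a final score in (0, 1]; shuffling the disease/control
labels 500 times yields a permutation P value per triplet.
"""
import numpy as np

from mgdtnet import (SyntheticDesign, build_tripartite_network,
                     enumerate_mgdts, generate_catalog, generate_study,
                     permutation_significance, select_significant)

design = SyntheticDesign(seed=1)          # 20 planted dysregulated triplets
catalog = generate_catalog(design)
study, truth = generate_study(design, catalog)
triplets = enumerate_mgdts(build_tripartite_network(catalog))

records = permutation_significance(study, catalog, triplets,
                                   n_perm=500, seed=1)
significant, fraction = select_significant(records, alpha=0.05)
print(f"{len(significant)} of {len(records)} triplets significant "
      f"({fraction:.1%}) at permutation P < 0.05")

hits = {r.triplet for r in significant}
sens = sum(t in hits for t in truth.planted) / len(truth.planted)
print(f"recovered {sens:.0%} of the {len(truth.planted)} planted triplets")

top = max(records, key=lambda r: r.final_score)
print(f"top triplet: {top.triplet.mirna} / {top.triplet.gene} / "
      f"{top.triplet.drug}")
print(f"  S_risk={top.s_risk:.3f}  S_P={top.s_p:.2e}  "
      f"S_pcc={top.s_pcc:.2f}  final={top.final_score:.3f}  "
      f"perm P={top.perm_p:.4f}")
planted_scores = [r.final_score for r in records
                  if truth.carries_signal(r.triplet)]
print(f"median final score, planted {np.median(planted_scores):.3f} vs "
      f"all {np.median([r.final_score for r in records]):.3f} "
      "- planted triplets concentrate at the top of the ranking")
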