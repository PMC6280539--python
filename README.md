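# mgdtnet

Tripartite **miRNA–gene–drug network analysis** for disease-specific
dysregulation and drug repurposing.

Many disease genes sit between two layers of actionable biology: the miRNAs
that post-transcriptionally regulate them and the drugs that bind their
products. `mgdtnet` builds the tripartite network linking disease-associated
genes to their experimentally supported miRNA regulators and drug binders,
enumerates every **miRNA–gene–drug triplet** (a miRNA and a drug sharing a
target gene), and asks which triplets are *dysregulated* in a disease given
paired mRNA/miRNA expression profiles of disease and control samples. The
package is aimed at systems-biology and computational drug-repurposing work
where catalog-style interaction tables (DisGeNET-, miRTarBase-,
DrugBank-like exports) meet small two-group expression studies.

## The statistic

For a triplet *(m, g, d)* with disease/control expression data, three score
channels are computed:

- **S_risk** — the gene's disease-association risk score from the catalog
  (identical for all triplets sharing *g*);
- **S_P = P_mRNA · P_miRNA** — the product of the two-sample Student
  *t*-test P values of the gene's mRNA and the miRNA (smaller = stronger
  joint differential expression);
- **S_pcc = |D_pcc − C_pcc|** — the absolute difference between the
  miRNA–mRNA Pearson correlation over disease samples and over control
  samples, in [0, 2] (large = rewired co-expression).

The channels are combined by **equally weighted rank aggregation**: triplets
are ranked per channel (S_risk and S_pcc descending, S_P ascending), each
rank *r* over *N* triplets maps to *(N − r + 1)/N*, and the final score is
the mean of the three mapped values, in (0, 1] — higher = more dysregulated.
Significance comes from a **label-permutation null**: the disease/control
labels are reshuffled (group sizes preserved, identically for both
matrices), the label-dependent channels and the full ranking are recomputed,
and each triplet's permutation P value is the add-one estimator
*(1 + #{permuted final ≥ observed final}) / (1 + N_perm)*. Triplets with
P < α (default 0.05) form the disease's significant set, from which the
package derives disease-specific/common triplet networks, drug-participation
rankings, gene-centered star subnetworks, and — via upper-tail
hypergeometric enrichment of miRNA target sets against GMT pathway
collections — miRNA-mediated drug–pathway networks.

A first-class synthetic-data module generates interaction catalogs and
two-group studies with *planted* triplets (mean shifts plus a
disease-vs-control correlation flip), so the whole pipeline is testable at
desk scale without any external database.

## Worked example

```python
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
```

Running `python examples/02_score_triplets.py` (the same computation)
prints:

```
152 of 1271 triplets significant (12.0%) at permutation P < 0.05
recovered 90% of the 20 planted triplets
top triplet: miR-0027 / G0046 / DRUG0004
  S_risk=0.732  S_P=4.95e-10  S_pcc=1.63  final=0.966  perm P=0.0020
median final score, planted 0.848 vs all 0.503 - planted triplets concentrate at the top of the ranking
```

The benchmark contains 1271 triplets over 235 nodes; the permutation test
recovers 18 of the 20 planted triplets, and the top-ranked triplet combines
a high gene risk score, a tiny P-value product and a strong correlation
flip — exactly the profile the final score is designed to reward. The other
scripts in `examples/` walk through network topology, two-disease
comparison, and pathway enrichment; each prints the numbers it computes
with a line on what they mean.

A thin CLI wraps the same library:

```sh
mgdtnet simulate --seed 1 --out bench/
mgdtnet run --disease-genes bench/disease_genes.tsv \
    --mirna-targets bench/mirna_targets.tsv --drug-targets bench/drug_targets.tsv \
    --mrna bench/mrna.tsv --mirna bench/mirna.tsv --labels bench/labels.tsv \
    --gmt bench/gene_sets.gmt --n-perm 1000 --seed 1 --out results/
```

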