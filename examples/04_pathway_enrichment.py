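"""Map miRNA target sets to enriched pathways and assemble the
miRNA-mediated drug-pathway network around one drug-gene pair.

For each miRNA, its target genes form the query of an upper-tail
hypergeometric test against every pathway gene set; pathways enriched in
all (or a chosen fraction of) the miRNAs of a subnetwork connect the drug
to its putative mechanism.
"""
from mgdtnet import (SyntheticDesign, build_drug_pathway_network,
                     common_pathways, generate_catalog,
                     mirna_pathway_profiles)
from mgdtnet.datatypes import GeneSetCollection
from mgdtnet.simulate import generate_gene_sets

catalog = generate_catalog(SyntheticDesign(seed=2))
sets = GeneSetCollection(sets=generate_gene_sets(catalog, n_sets=12, seed=2))

mirnas = sorted({m for m, _ in catalog.mirna_targets})[:6]
profiles = mirna_pathway_profiles(mirnas, catalog, sets, alpha=0.25)
for m, pws in sorted(profiles.items()):
    print(f"{m}: {len(pws)} enriched pathways {sorted(pws)}")

active = {m: p for m, p in profiles.items() if p}
common = common_pathways(active, min_fraction=0.5)
print(f"pathways enriched in >= half of the {len(active)} miRNAs with any "
      f"enrichment: {sorted(common)}")

gene = next(g for _, g in sorted(catalog.mirna_targets))
drug = next(d for d, _ in sorted(catalog.drug_targets))
net = build_drug_pathway_network(drug, gene, profiles, common)
print(f"drug-pathway network around {drug}/{gene}: {net}")
print("pathway nodes reached through >= 1 miRNA link the drug's target "
      "gene to candidate mechanisms")
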