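"""Hypergeometric pathway enrichment, per-miRNA pathway profiles, common
pathways, and the miRNA-mediated drug-pathway network.

Enrichment is the classical one-sided over-representation test: for a query
of n genes drawn from a universe of M genes of which K belong to the
pathway, the P value is P(X >= k) with X hypergeometric — the statistic
underlying DAVID-style annotation tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .datatypes import GeneSetCollection, InteractionCatalog
from .network import DRUG_PATHWAY_PAIRS, TripartiteNetwork
from .scoring import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "resolve_universe",
    "mirna_pathway_profiles",
    "common_pathways",
    "build_drug_pathway_network",
]


@dataclass
class EnrichmentResult:
    pathway: str
    description: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p: float
    enriched: bool


def hypergeometric_enrichment(query: set[str], sets: GeneSetCollection,
                              universe: set[str], alpha: float = 0.05, *,
                              bh_adjust: bool = False
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a gene query against each set.

    Query and pathway sets are restricted to the universe first. Results are
    sorted by P value then pathway id; ``enriched`` flags p < alpha (on BH
    adjusted values when ``bh_adjust``).
    """
    if not universe:
        raise ValueError("empty universe")
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValueError("query empty after restriction to the universe")
    m_univ = len(universe)
    n_query = len(query)
    results = []
    for pathway, (desc, genes) in sets.sets.items():
        in_univ = genes & universe
        if not in_univ:
            continue
        k = len(query & in_univ)
        # P(X >= k), X ~ Hypergeom(M=m_univ, K=|set|, n=n_query)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(in_univ), n_query))
        p = min(p, 1.0)
        results.append(EnrichmentResult(
            pathway=pathway, description=desc, overlap=k,
            query_size=n_query, set_size=len(in_univ),
            universe_size=m_univ, p=p, enriched=False))
    results.sort(key=lambda r: (r.p, r.pathway))
    pvals = [r.p for r in results]
    if bh_adjust and results:
        pvals = benjamini_hochberg(pvals)
    for r, p in zip(results, pvals):
        r.enriched = bool(p < alpha)
    return results


def resolve_universe(policy, catalog: InteractionCatalog,
                     sets: GeneSetCollection) -> set[str]:
    """Resolve a background-universe policy to a gene set.

    Policies: ``"catalog_and_gmt"`` (default elsewhere) — genes present in
    both the GMT union and the miRNA-target catalog; ``"gmt"`` — the GMT
    union; or an explicit collection of gene ids.
    """
    if policy == "catalog_and_gmt":
        targets = {g for _, g in catalog.mirna_targets}
        return set(sets.all_genes) & targets
    if policy == "gmt":
        return set(sets.all_genes)
    if isinstance(policy, (set, frozenset, list, tuple)):
        return set(policy)
    raise ValueError(f"unknown universe policy {policy!r}")


def mirna_pathway_profiles(mirnas: list[str], catalog: InteractionCatalog,
                           sets: GeneSetCollection,
                           universe_policy="catalog_and_gmt",
                           alpha: float = 0.05, *,
                           bh_adjust: bool = False) -> dict[str, set[str]]:
    """Enriched-pathway profile per miRNA, from its target-gene set.

    Each miRNA's profile depends only on its own targets (queries are
    independent). miRNAs with no target gene inside the universe are
    skipped with a warning.
    """
    universe = resolve_universe(universe_policy, catalog, sets)
    logger.info("enrichment universe: %d genes", len(universe))
    targets_by_mirna: dict[str, set[str]] = {}
    for m, g in catalog.mirna_targets:
        targets_by_mirna.setdefault(m, set()).add(g)
    profiles: dict[str, set[str]] = {}
    for m in mirnas:
        query = targets_by_mirna.get(m, set()) & universe
        if not query:
            logger.warning("miRNA %r has no target gene in the universe; "
                           "skipped", m)
            continue
        res = hypergeometric_enrichment(query, sets, universe, alpha,
                                        bh_adjust=bh_adjust)
        profiles[m] = {r.pathway for r in res if r.enriched}
    return profiles


def common_pathways(profiles: dict[str, set[str]],
                    min_fraction: float = 1.0) -> set[str]:
    """Pathways enriched in at least ceil(min_fraction * n_profiles) profiles.

    ``min_fraction = 1.0`` is the strict intersection across all miRNAs.
    """
    if not profiles:
        raise ValueError("common_pathways needs >= 1 profile")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    import math
    threshold = math.ceil(min_fraction * len(profiles))
    counts: dict[str, int] = {}
    for pw_set in profiles.values():
        for pw in pw_set:
            counts[pw] = counts.get(pw, 0) + 1
    return {pw for pw, c in counts.items() if c >= threshold}


def build_drug_pathway_network(drug: str, gene: str,
                               profiles: dict[str, set[str]],
                               common: set[str]) -> TripartiteNetwork:
    """The miRNA-mediated drug-pathway view around one drug-gene pair.

    Nodes: the drug, the gene, every profiled miRNA, and every common
    pathway. Edges: drug-gene, each miRNA-gene, and miRNA-pathway for each
    common pathway contained in that miRNA's profile. Every pathway node
    ends up connected to >= 1 miRNA because ``common`` must be covered by
    the profiles.
    """
    if not profiles:
        raise ValueError("empty profiles")
    union: set[str] = set()
    for pw_set in profiles.values():
        union |= pw_set
    stray = set(common) - union
    if stray:
        raise ValueError(f"common pathways absent from every profile: "
                         f"{sorted(stray)[:5]}")
    net = TripartiteNetwork(allowed_pairs=DRUG_PATHWAY_PAIRS)
    net.add_node(drug, "drug")
    net.add_node(gene, "gene")
    net.add_edge(drug, gene)
    for m in sorted(profiles):
        net.add_node(m, "miRNA")
        net.add_edge(m, gene)
    for pw in sorted(common):
        net.add_node(pw, "pathway")
        for m, pw_set in sorted(profiles.items()):
            if pw in pw_set:
                net.add_edge(m, pw)
    return net
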