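"""Disease-specific and common triplet sets, drug rankings, star subnetworks,
and score-profile summaries."""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MGDT, MGDTRecord
from .network import TripartiteNetwork

__all__ = [
    "TripletSetComparison",
    "significant_network",
    "compare_triplet_sets",
    "drug_participation_ranking",
    "gene_centered_subnetwork",
    "ScoreProfileSummary",
    "score_profile_summary",
]


def significant_network(triplets: set[MGDT] | list[MGDT]) -> TripartiteNetwork:
    """Union network of a triplet set: each triplet contributes its
    (miRNA, gene) and (drug, gene) edges; shared edges collapse."""
    net = TripartiteNetwork()
    for t in sorted(set(triplets)):
        net.add_node(t.gene, "gene")
        net.add_node(t.mirna, "miRNA")
        net.add_node(t.drug, "drug")
        net.add_edge(t.mirna, t.gene)
        net.add_edge(t.drug, t.gene)
    return net


@dataclass
class TripletSetComparison:
    """Whole-triplet overlap between two diseases' significant sets.

    A triplet is "common" only when the identical (miRNA, gene, drug) triple
    is significant in both diseases; the specific sets are the respective
    complements. The three sets are pairwise disjoint.
    """

    common: set[MGDT]
    specific_a: set[MGDT]
    specific_b: set[MGDT]

    def component_overlap(self) -> dict[str, int]:
        """Descriptive extra: per-component (gene/miRNA/drug) overlap sizes."""
        a = self.common | self.specific_a
        b = self.common | self.specific_b
        return {
            "genes": len({t.gene for t in a} & {t.gene for t in b}),
            "mirnas": len({t.mirna for t in a} & {t.mirna for t in b}),
            "drugs": len({t.drug for t in a} & {t.drug for t in b}),
        }


def compare_triplet_sets(a: set[MGDT] | list[MGDT],
                         b: set[MGDT] | list[MGDT]) -> TripletSetComparison:
    """Exact intersection/differences on whole triplets."""
    a, b = set(a), set(b)
    common = a & b
    return TripletSetComparison(common=common, specific_a=a - common,
                                specific_b=b - common)


def drug_participation_ranking(triplets: set[MGDT] | list[MGDT]
                               ) -> list[tuple[str, int]]:
    """Drugs ordered by how many triplets they participate in.

    Descending by count, ties broken lexicographically by drug id. The
    counts sum to the number of triplets (one drug per triplet).
    """
    counts = Counter(t.drug for t in set(triplets))
    return sorted(counts.items(), key=lambda dc: (-dc[1], dc[0]))


def gene_centered_subnetwork(triplets: set[MGDT] | list[MGDT],
                             gene: str) -> TripartiteNetwork:
    """Star subnetwork of one gene: its miRNA and drug partners in the
    triplet set, with only edges incident to the gene."""
    relevant = [t for t in set(triplets) if t.gene == gene]
    if not relevant:
        raise ValueError(f"gene {gene!r} occurs in no triplet")
    net = TripartiteNetwork()
    net.add_node(gene, "gene")
    for t in sorted(relevant):
        net.add_node(t.mirna, "miRNA")
        net.add_node(t.drug, "drug")
        net.add_edge(t.mirna, gene)
        net.add_edge(t.drug, gene)
    return net


SCORE_TYPES = ("final_score", "s_risk", "s_p", "s_pcc")


@dataclass
class ScoreProfileSummary:
    """Tabulated activity-score profile: location/spread statistics plus a
    fixed-bin histogram per score type."""

    stats: pd.DataFrame  # index: score type; columns: mean..max
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # type -> (edges, counts)


def score_profile_summary(records: list[MGDTRecord],
                          n_bins: int = 30) -> ScoreProfileSummary:
    """Summarize the distribution of each score channel over the records.

    Histogram bin edges are deterministic: ``n_bins`` equal-width bins over
    the observed min..max of each score type; counts sum to the number of
    records.
    """
    if not records:
        raise ValueError("score_profile_summary needs >= 1 record")
    rows = []
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for st in SCORE_TYPES:
        vals = np.array([getattr(r, st) for r in records], dtype=float)
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append({
            "score_type": st, "mean": float(vals.mean()),
            "median": float(q50), "q25": float(q25), "q75": float(q75),
            "min": float(vals.min()), "max": float(vals.max()),
        })
        counts, edges = np.histogram(vals, bins=n_bins)
        histograms[st] = (edges, counts)
    stats = pd.DataFrame(rows).set_index("score_type")
    return ScoreProfileSummary(stats=stats, histograms=histograms)
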