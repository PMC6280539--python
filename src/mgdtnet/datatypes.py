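"""Core in-memory containers shared across the pipeline.

Identifiers are free-form non-empty strings; the three namespaces (gene,
miRNA, drug) are kept apart by role (which table/column an id came from),
never by string pattern.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

__all__ = [
    "InteractionCatalog",
    "ExpressionStudy",
    "GeneSetCollection",
    "MGDT",
    "MGDTRecord",
]


class MGDT(NamedTuple):
    """One miRNA-gene-drug triplet: a miRNA and a drug sharing a target gene."""

    mirna: str
    gene: str
    drug: str


@dataclass
class InteractionCatalog:
    """Disease-gene risk scores plus miRNA->gene and drug->gene target pairs.

    ``disease_genes`` maps gene id to a unitless disease-association risk
    score (DisGeNET-style, expected in [0, 1] but not clamped). The two
    target collections are sets of (regulator, gene) pairs, deduplicated.
    """

    disease_genes: dict[str, float] = field(default_factory=dict)
    mirna_targets: set[tuple[str, str]] = field(default_factory=set)
    drug_targets: set[tuple[str, str]] = field(default_factory=set)

    def validate(self) -> None:
        for gene, score in self.disease_genes.items():
            if not gene:
                raise ValueError("empty gene identifier in disease_genes")
            if not math.isfinite(score):
                raise ValueError(f"non-finite risk score for gene {gene!r}")
        for name, pairs in (("mirna_targets", self.mirna_targets),
                            ("drug_targets", self.drug_targets)):
            for a, b in pairs:
                if not a or not b:
                    raise ValueError(f"empty identifier in {name}: {(a, b)!r}")

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.mirna_targets}

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.drug_targets}


@dataclass
class ExpressionStudy:
    """Paired mRNA and miRNA expression over one shared ordered sample list.

    ``mrna``: genes x samples, ``mirna``: miRNAs x samples (same columns,
    same order), ``labels``: per-sample group, each value "disease" or
    "control". Values are continuous expression, log scale assumed.
    """

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    labels: pd.Series

    def validate(self) -> None:
        if list(self.mrna.columns) != list(self.mirna.columns):
            raise ValueError("mRNA and miRNA matrices must share an identical "
                             "ordered sample list")
        if list(self.labels.index) != list(self.mrna.columns):
            raise ValueError("labels must cover exactly the shared samples, "
                             "in matrix order")
        bad = set(self.labels.unique()) - {"disease", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for name, mat in (("mrna", self.mrna), ("mirna", self.mirna)):
            if mat.isna().any().any():
                raise ValueError(f"{name} matrix contains missing values")
        for group in ("disease", "control"):
            if (self.labels == group).sum() < 1:
                raise ValueError(f"group {group!r} has no samples")

    @property
    def disease_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "disease"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "control"])

    @property
    def n_disease(self) -> int:
        return int((self.labels == "disease").sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == "control").sum())


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (GMT-backed): id -> (description, gene set)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, pathway: str) -> frozenset[str]:
        return self.sets[pathway][1]

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class MGDTRecord:
    """One scored triplet.

    Score channels: ``s_risk`` is the gene's disease risk score (constant
    across triplets sharing a gene); ``s_p`` = p_mrna * p_mirna, the product
    of the two-group differential-expression P values (smaller = stronger);
    ``s_pcc`` = |d_pcc - c_pcc|, the absolute difference between the
    miRNA-mRNA Pearson correlation in disease and in control samples, in
    [0, 2]. ``final_score`` in (0, 1] is the equal-weight rank aggregate of
    the three channels (higher = more dysregulated); ``perm_p`` the
    label-permutation P value for the final score.
    """

    triplet: MGDT
    s_risk: float = math.nan
    p_mrna: float = math.nan
    p_mirna: float = math.nan
    s_p: float = math.nan
    d_pcc: float = math.nan
    c_pcc: float = math.nan
    s_pcc: float = math.nan
    final_score: float = math.nan
    perm_p: float = math.nan
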