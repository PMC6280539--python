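"""Synthetic interaction catalogs and two-group expression studies with
planted dysregulated triplets.

The generator emulates the pipeline's three input families at desk scale:
sparse bipartite miRNA-gene and drug-gene target tables with per-gene
disease risk scores on [0, 1] (Beta-distributed, right-skewed like curated
disease-gene catalogs), and a disease-vs-control expression study in which
background features are i.i.d. Gaussian noise in both groups while each
planted triplet's (gene, miRNA) pair carries a disease-group mean shift and
a group-dependent Pearson correlation — exactly the structure the three
dysregulation scores are designed to detect.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MGDT, ExpressionStudy, InteractionCatalog
from .network import build_tripartite_network, enumerate_mgdts

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "generate_catalog",
    "generate_study",
    "generate_gene_sets",
    "make_benchmark",
    "read_ground_truth",
]


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic benchmark.

    Defaults give a minutes-scale benchmark: ~1000 triplets, 10 vs 10
    samples, 20 planted triplets with a 2-SD mean shift and a correlation
    flip from +0.8 (disease) to -0.5 (control).
    """

    n_genes: int = 50
    n_mirnas: int = 80
    n_drugs: int = 120
    edge_density_mg: float = 0.06
    edge_density_dg: float = 0.04
    n_disease: int = 10
    n_control: int = 10
    n_planted: int = 20
    delta: float = 2.0                 # mean shift, units of noise_sd
    rho_disease: float = 0.8
    rho_control: float = -0.5
    noise_sd: float = 1.0
    risk_alpha: float = 2.0            # Beta shape of the risk-score law
    risk_beta: float = 5.0
    planted_high_risk: bool = True     # redraw planted genes' risk from the
                                       # top quartile of the Beta law
    seed: int = 0

    def validate(self) -> None:
        for name in ("edge_density_mg", "edge_density_dg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("rho_disease", "rho_control"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be in (-1, 1), got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_genes, self.n_mirnas, self.n_drugs) < 1:
            raise ValueError("need >= 1 node per class")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        if min(self.n_disease, self.n_control) < 3:
            raise ValueError("sample counts must be >= 3 by default")


@dataclass
class GroundTruth:
    """What was planted: the triplets plus the per-triplet parameters used.

    The planted signal is a property of the (miRNA, gene) expression pair,
    so every triplet sharing a planted pair (same pair, different drug) is
    genuinely dysregulated and score-identical to the named planted triplet;
    :meth:`carries_signal` tests that pair-level membership.
    """

    planted: set[MGDT] = field(default_factory=set)
    params: dict[MGDT, tuple[float, float, float]] = field(default_factory=dict)
    # params: triplet -> (delta, rho_disease, rho_control)

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(t.mirna, t.gene) for t in self.planted}

    def carries_signal(self, triplet: MGDT) -> bool:
        return (triplet.mirna, triplet.gene) in self.planted_pairs


def _rng_for(design: SyntheticDesign, stream: int) -> np.random.Generator:
    # independent child streams per pipeline stage, all rooted at design.seed
    return np.random.default_rng(np.random.SeedSequence(design.seed).spawn(8)[stream])


def generate_catalog(design: SyntheticDesign) -> InteractionCatalog:
    """Random sparse catalog: each miRNA-gene / drug-gene pair independently
    present with its density; risk scores Beta(risk_alpha, risk_beta)."""
    design.validate()
    rng = _rng_for(design, 0)
    genes = [f"G{i:04d}" for i in range(design.n_genes)]
    mirnas = [f"miR-{i:04d}" for i in range(design.n_mirnas)]
    drugs = [f"DRUG{i:04d}" for i in range(design.n_drugs)]
    risk = rng.beta(design.risk_alpha, design.risk_beta, size=design.n_genes)
    mg = rng.random((design.n_mirnas, design.n_genes)) < design.edge_density_mg
    dg = rng.random((design.n_drugs, design.n_genes)) < design.edge_density_dg
    return InteractionCatalog(
        disease_genes={g: float(r) for g, r in zip(genes, risk)},
        mirna_targets={(mirnas[i], genes[j]) for i, j in zip(*np.nonzero(mg))},
        drug_targets={(drugs[i], genes[j]) for i, j in zip(*np.nonzero(dg))},
    )


def _select_planted(design: SyntheticDesign, catalog: InteractionCatalog,
                    rng: np.random.Generator) -> list[MGDT]:
    """Pick n_planted valid triplets to carry signal.

    The dysregulation signal lives on the (gene, miRNA) expression pair —
    the drug never enters the generative model — so planted pairs are drawn
    uniformly from the eligible miRNA-target pairs (gene must be a disease
    gene with >= 1 drug partner), with pairwise-distinct genes and miRNAs so
    each pair carries exactly its own signal; a representative drug partner
    is then drawn uniformly to name the planted triplet.
    """
    if design.n_planted == 0:
        return []
    drugs_by_gene: dict[str, list[str]] = {}
    for d, g in sorted(catalog.drug_targets):
        if g in catalog.disease_genes:
            drugs_by_gene.setdefault(g, []).append(d)
    pairs = sorted((m, g) for m, g in catalog.mirna_targets
                   if g in catalog.disease_genes and g in drugs_by_gene)
    if not pairs:
        raise ValueError("catalog contains no valid triplet to plant in")
    order = rng.permutation(len(pairs))
    chosen: list[MGDT] = []
    used_genes: set[str] = set()
    used_mirnas: set[str] = set()
    for i in order:
        m, g = pairs[i]
        if g in used_genes or m in used_mirnas:
            continue
        drugs = drugs_by_gene[g]
        chosen.append(MGDT(m, g, drugs[int(rng.integers(len(drugs)))]))
        used_genes.add(g)
        used_mirnas.add(m)
        if len(chosen) == design.n_planted:
            break
    if len(chosen) < design.n_planted:
        raise ValueError(
            f"cannot plant {design.n_planted} triplets with distinct genes "
            f"and miRNAs; only {len(chosen)} available")
    return chosen


def generate_study(design: SyntheticDesign, catalog: InteractionCatalog
                   ) -> tuple[ExpressionStudy, GroundTruth]:
    """Two-group expression study with planted dysregulated triplets.

    Background features are i.i.d. Normal(0, noise_sd) in both groups. For
    each planted triplet the (gene, miRNA) expression pair is bivariate
    normal with correlation ``rho_disease`` in disease samples and
    ``rho_control`` in control samples, and both means are shifted by
    ``delta * noise_sd`` in the disease group.

    When ``design.planted_high_risk``, the risk scores of the planted genes
    are redrawn in place on ``catalog`` from the top quartile of the
    Beta(risk_alpha, risk_beta) law, so all three score channels carry
    signal.
    """
    design.validate()
    from scipy import stats as sps
    rng = _rng_for(design, 1)
    planted = _select_planted(design, catalog, rng)

    genes = sorted(catalog.disease_genes)
    mirnas = sorted(catalog.mirnas)
    n_d, n_c = design.n_disease, design.n_control
    n_s = n_d + n_c
    samples = [f"S{i:02d}" for i in range(n_s)]
    sd = design.noise_sd

    mrna = rng.normal(0.0, sd, size=(len(genes), n_s))
    mirna = rng.normal(0.0, sd, size=(len(mirnas), n_s))
    gene_row = {g: i for i, g in enumerate(genes)}
    mirna_row = {m: i for i, m in enumerate(mirnas)}

    truth = GroundTruth()
    for t in planted:
        gi, mi = gene_row[t.gene], mirna_row[t.mirna]
        for rho, cols, shift in (
                (design.rho_disease, slice(0, n_d), design.delta * sd),
                (design.rho_control, slice(n_d, n_s), 0.0)):
            n = cols.stop - cols.start
            z1 = rng.normal(size=n)
            z2 = rng.normal(size=n)
            # Cholesky construction of the target correlation
            mrna[gi, cols] = shift + sd * z1
            mirna[mi, cols] = shift + sd * (rho * z1
                                            + math.sqrt(1 - rho ** 2) * z2)
        truth.planted.add(t)
        truth.params[t] = (design.delta, design.rho_disease,
                           design.rho_control)

    if design.planted_high_risk and planted:
        q75 = sps.beta.ppf(0.75, design.risk_alpha, design.risk_beta)
        for t in sorted(truth.planted):
            u = rng.uniform(0.75, 1.0)
            catalog.disease_genes[t.gene] = float(
                sps.beta.ppf(u, design.risk_alpha, design.risk_beta))
        logger.info("redrew %d planted-gene risk scores above the Beta "
                    "quartile %.3f", len(planted), q75)

    labels = pd.Series(["disease"] * n_d + ["control"] * n_c,
                       index=samples, name="group")
    study = ExpressionStudy(
        mrna=pd.DataFrame(mrna, index=genes, columns=samples),
        mirna=pd.DataFrame(mirna, index=mirnas, columns=samples),
        labels=labels)
    study.validate()
    return study, truth


def generate_gene_sets(catalog: InteractionCatalog, n_sets: int = 15,
                       set_size_range: tuple[int, int] = (5, 25),
                       seed: int = 0) -> dict[str, tuple[str, frozenset[str]]]:
    """Random pathway gene sets drawn from the catalog's disease genes."""
    rng = np.random.default_rng(seed)
    genes = sorted(catalog.disease_genes)
    lo, hi = set_size_range
    hi = min(hi, len(genes))
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"PW{i:03d}"] = (f"synthetic pathway {i}",
                              frozenset(str(g) for g in members))
    return sets


# ---------------------------------------------------------------------------
# file benchmark

def make_benchmark(design: SyntheticDesign, out_dir) -> dict[str, Path]:
    """Generate a catalog + study + gene sets and write them in the
    pipeline's input formats; ground truth and the design are serialized
    alongside. Returns the path of every file written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(design)
    study, truth = generate_study(design, catalog)
    gene_sets = generate_gene_sets(catalog, seed=design.seed)

    paths: dict[str, Path] = {}

    def write(name: str, lines: list[str]) -> None:
        p = out_dir / name
        p.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
        paths[name] = p

    write("disease_genes.tsv", ["gene\trisk_score"] + [
        f"{g}\t{catalog.disease_genes[g]:.10g}"
        for g in sorted(catalog.disease_genes)])
    write("mirna_targets.tsv", ["mirna\tgene"] + [
        f"{m}\t{g}" for m, g in sorted(catalog.mirna_targets)])
    write("drug_targets.tsv", ["drug\tgene"] + [
        f"{d}\t{g}" for d, g in sorted(catalog.drug_targets)])

    for name, mat in (("mrna.tsv", study.mrna), ("mirna.tsv", study.mirna)):
        p = out_dir / name
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            mat.to_csv(fh, sep="\t", index_label="feature",
                       float_format="%.10g", lineterminator="\n")
        paths[name] = p
    write("labels.tsv", ["sample\tgroup"] + [
        f"{s}\t{g}" for s, g in study.labels.items()])

    gmt_lines = [f"{pw}\t{desc}\t" + "\t".join(sorted(genes))
                 for pw, (desc, genes) in sorted(gene_sets.items())]
    write("gene_sets.gmt", gmt_lines)

    write("ground_truth.tsv", ["mirna\tgene\tdrug\tdelta\trho_disease"
                               "\trho_control"] + [
        f"{t.mirna}\t{t.gene}\t{t.drug}\t{d:g}\t{rd:g}\t{rc:g}"
        for t, (d, rd, rc) in sorted(truth.params.items())])
    write("design.txt", [f"{k} = {v}" for k, v in
                         sorted(asdict(design).items())])
    logger.info("benchmark written to %s (%d files)", out_dir, len(paths))
    return paths


def read_ground_truth(path) -> GroundTruth:
    """Read the planted-triplet table written by :func:`make_benchmark`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    truth = GroundTruth()
    for row in df.itertuples(index=False):
        t = MGDT(str(row.mirna), str(row.gene), str(row.drug))
        truth.planted.add(t)
        truth.params[t] = (float(row.delta), float(row.rho_disease),
                           float(row.rho_control))
    return truth
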