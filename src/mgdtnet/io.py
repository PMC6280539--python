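"""Readers and writers for the pipeline's file formats.

Dialect: tab-separated with one header line; lines starting with '#' are
comments and are ignored. All writers emit UTF-8 and end the file with a
trailing newline; line order is deterministic (lexicographic).
"""
from __future__ import annotations

import logging
import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import (MGDT, ExpressionStudy, GeneSetCollection,
                        InteractionCatalog, MGDTRecord)
from .network import TripartiteNetwork, TRIPARTITE_PAIRS

logger = logging.getLogger(__name__)

__all__ = [
    "InputFormatError",
    "read_interaction_catalog",
    "read_expression_study",
    "read_gene_sets",
    "write_network",
    "read_network",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]


class InputFormatError(ValueError):
    """A malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# interaction catalog

def _data_lines(path: Path):
    """Yield (line_number, fields) for non-comment, non-blank lines past the
    header. Line numbers are 1-based over the physical file."""
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first data-bearing line is the header
                continue
            yield lineno, line.split("\t")


def read_interaction_catalog(disease_gene_path, mirna_target_path,
                             drug_target_path) -> InteractionCatalog:
    """Load disease-gene risk scores and the two target tables.

    Each file is tab-separated with one header line. Columns by position:
    disease genes (gene, risk_score), miRNA targets (mirna, gene), drug
    targets (drug, gene). Duplicate rows are stored once; counts of rows
    read and dropped are logged.
    """
    disease_gene_path = Path(disease_gene_path)
    mirna_target_path = Path(mirna_target_path)
    drug_target_path = Path(drug_target_path)

    disease_genes: dict[str, float] = {}
    n_dup = 0
    for lineno, fields in _data_lines(disease_gene_path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{disease_gene_path}:{lineno}: expected >= 2 tab-separated "
                f"fields (gene, risk_score), got {len(fields)}")
        gene, raw_score = fields[0].strip(), fields[1].strip()
        if not gene:
            raise InputFormatError(
                f"{disease_gene_path}:{lineno}: empty gene identifier")
        try:
            score = float(raw_score)
        except ValueError:
            raise InputFormatError(
                f"{disease_gene_path}:{lineno}: non-numeric risk score "
                f"{raw_score!r}") from None
        if not math.isfinite(score):
            raise InputFormatError(
                f"{disease_gene_path}:{lineno}: non-finite risk score")
        if not 0.0 <= score <= 1.0:
            logger.warning("%s:%d: risk score %g outside [0, 1] accepted "
                           "as-is", disease_gene_path, lineno, score)
        if gene in disease_genes:
            n_dup += 1
        else:
            disease_genes[gene] = score
    logger.info("read %d disease genes from %s (%d duplicate rows dropped)",
                len(disease_genes), disease_gene_path, n_dup)

    def read_pairs(path: Path, what: str) -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        dup = 0
        for lineno, fields in _data_lines(path):
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected >= 2 tab-separated fields, "
                    f"got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise InputFormatError(f"{path}:{lineno}: empty identifier")
            if (a, b) in pairs:
                dup += 1
            else:
                pairs.add((a, b))
        logger.info("read %d %s pairs from %s (%d duplicate rows dropped)",
                    len(pairs), what, path, dup)
        return pairs

    catalog = InteractionCatalog(
        disease_genes=disease_genes,
        mirna_targets=read_pairs(mirna_target_path, "miRNA-gene"),
        drug_targets=read_pairs(drug_target_path, "drug-gene"),
    )
    catalog.validate()
    return catalog


# ---------------------------------------------------------------------------
# expression study

def _read_matrix(path: Path) -> pd.DataFrame:
    """Read a feature x sample matrix; first column is the feature id.

    Non-numeric cells raise with row/column coordinates; rows containing
    missing values are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    was_na = df.isna()
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & ~was_na
    if bad.any().any():
        feat = bad.index[bad.any(axis=1)][0]
        samp = bad.columns[bad.loc[feat]][0]
        raise InputFormatError(
            f"{path}: non-numeric expression value at feature {feat!r}, "
            f"sample {samp!r}: {df.loc[feat, samp]!r}")
    complete = ~numeric.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing values",
                       path, n_dropped)
    out = numeric.loc[complete].astype(float)
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise InputFormatError(f"{path}: duplicate feature ids: {dups[:5]}")
    return out


def read_expression_study(mrna_path, mirna_path, labels_path) -> ExpressionStudy:
    """Load the paired mRNA/miRNA matrices plus the disease/control labels.

    The miRNA matrix is reindexed to the mRNA sample order. The label file
    (sample TAB group) must cover exactly the shared samples.
    """
    mrna = _read_matrix(Path(mrna_path))
    mirna = _read_matrix(Path(mirna_path))
    s_mrna, s_mirna = set(mrna.columns), set(mirna.columns)
    if s_mrna != s_mirna:
        only_m = sorted(s_mrna - s_mirna)
        only_mi = sorted(s_mirna - s_mrna)
        raise InputFormatError(
            f"sample sets differ between {mrna_path} and {mirna_path}: "
            f"mRNA-only={only_m}, miRNA-only={only_mi}")
    mirna = mirna[mrna.columns]

    labels: dict[str, str] = {}
    labels_path = Path(labels_path)
    for lineno, fields in _data_lines(labels_path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{labels_path}:{lineno}: expected (sample, group)")
        sample, group = fields[0].strip(), fields[1].strip()
        if sample not in s_mrna:
            raise InputFormatError(
                f"{labels_path}:{lineno}: sample {sample!r} absent from the "
                f"expression matrices")
        if group not in ("disease", "control"):
            raise InputFormatError(
                f"{labels_path}:{lineno}: group must be 'disease' or "
                f"'control', got {group!r}")
        labels[sample] = group
    missing = sorted(s_mrna - set(labels))
    if missing:
        raise InputFormatError(
            f"{labels_path}: no group label for samples {missing}")
    study = ExpressionStudy(
        mrna=mrna, mirna=mirna,
        labels=pd.Series([labels[s] for s in mrna.columns],
                         index=mrna.columns, name="group"),
    )
    study.validate()
    return study


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Read pathway gene sets from a GMT file.

    Standard GMT: name TAB description TAB gene TAB gene ... Genes are
    deduplicated per set; sets left empty are dropped with a warning;
    duplicate pathway ids are an error.
    """
    gmt_path = Path(gmt_path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{gmt_path}:{lineno}: GMT line needs >= 3 fields "
                    f"(name, description, gene...), got {len(fields)}")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise InputFormatError(
                    f"{gmt_path}:{lineno}: duplicate pathway id {name!r}")
            genes = frozenset(g for g in (f.strip() for f in fields[2:]) if g)
            if not genes:
                logger.warning("%s:%d: pathway %r has no genes, dropped",
                               gmt_path, lineno, name)
                continue
            sets[name] = (desc, genes)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# networks

#: SIF relation label per (source class, target class)
_RELATIONS = {
    ("miRNA", "gene"): "targets",
    ("drug", "gene"): "binds",
    ("miRNA", "pathway"): "enriched_in",
}
_REL_TO_CLASSES = {rel: classes for classes, rel in _RELATIONS.items()}

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def _oriented_edges(net: TripartiteNetwork):
    """Yield (source, relation, target) with the regulator first, sorted."""
    rows = []
    for u, v in net.edges:
        cu, cv = net.node_class(u), net.node_class(v)
        if (cu, cv) in _RELATIONS:
            rows.append((u, _RELATIONS[(cu, cv)], v))
        elif (cv, cu) in _RELATIONS:
            rows.append((v, _RELATIONS[(cv, cu)], u))
        else:
            raise ValueError(f"no relation label for classes {cu!r}-{cv!r}")
    rows.sort()
    return rows


def write_network(net: TripartiteNetwork, path, format: str = "sif") -> Path:
    """Write a network as SIF, GraphML, or an edge TSV.

    SIF lines read ``source TAB relation TAB target`` with relations
    "targets" (miRNA->gene), "binds" (drug->gene) and "enriched_in"
    (miRNA->pathway). GraphML carries a ``node_class`` attribute and
    preserves isolated nodes; the text formats list edges only.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unsupported format {format!r}; "
                         f"choose from {NETWORK_FORMATS}")
    if fmt == "sif":
        lines = [f"{s}\t{rel}\t{t}" for s, rel, t in _oriented_edges(net)]
        path.write_text("".join(line + "\n" for line in lines),
                        encoding="utf-8")
    elif fmt == "tsv":
        lines = ["source\tsource_class\trelation\ttarget\ttarget_class"]
        for s, rel, t in _oriented_edges(net):
            lines.append(f"{s}\t{net.node_class(s)}\t{rel}\t{t}"
                         f"\t{net.node_class(t)}")
        path.write_text("".join(line + "\n" for line in lines),
                        encoding="utf-8")
    else:  # graphml, via a deterministically ordered copy
        g = nx.Graph()
        for n, c in sorted(net.nodes.items()):
            g.add_node(n, node_class=c)
        for u, v in sorted(net.edges):
            g.add_edge(u, v)
        text = "\n".join(nx.generate_graphml(g)) + "\n"
        path.write_text(text, encoding="utf-8")
    return path


def read_network(path, format: str | None = None,
                 allowed_pairs: frozenset = TRIPARTITE_PAIRS) -> TripartiteNetwork:
    """Read a network written by :func:`write_network`.

    ``format`` defaults to the file extension. SIF infers node classes from
    the relation labels; GraphML restores them from the ``node_class``
    attribute (including isolated nodes).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    net = TripartiteNetwork(allowed_pairs=allowed_pairs)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            net.add_node(str(n), d["node_class"])
        for u, v in g.edges():
            net.add_edge(str(u), str(v))
        return net
    if fmt not in ("sif", "tsv"):
        raise ValueError(f"unsupported format {fmt!r}")
    with open(path, encoding="utf-8") as fh:
        first = fmt == "tsv"
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if first:  # TSV header
                first = False
                continue
            fields = line.split("\t")
            if fmt == "sif":
                if len(fields) != 3:
                    raise InputFormatError(
                        f"{path}:{lineno}: SIF line needs 3 fields")
                s, rel, t = fields
                if rel not in _REL_TO_CLASSES:
                    raise InputFormatError(
                        f"{path}:{lineno}: unknown relation {rel!r}")
                cs, ct = _REL_TO_CLASSES[rel]
            else:
                if len(fields) != 5:
                    raise InputFormatError(
                        f"{path}:{lineno}: edge TSV line needs 5 fields")
                s, cs, rel, t, ct = fields
            net.add_node(s, cs)
            net.add_node(t, ct)
            net.add_edge(s, t)
    return net


# ---------------------------------------------------------------------------
# score tables

RECORD_COLUMNS = ["mirna", "gene", "drug", "s_risk", "p_mrna", "p_mirna",
                  "s_p", "d_pcc", "c_pcc", "s_pcc", "final_score", "perm_p",
                  "significant"]


def records_to_frame(records: list[MGDTRecord],
                     alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "mirna": r.triplet.mirna, "gene": r.triplet.gene,
            "drug": r.triplet.drug, "s_risk": r.s_risk,
            "p_mrna": r.p_mrna, "p_mirna": r.p_mirna, "s_p": r.s_p,
            "d_pcc": r.d_pcc, "c_pcc": r.c_pcc, "s_pcc": r.s_pcc,
            "final_score": r.final_score, "perm_p": r.perm_p,
            "significant": bool(r.perm_p < alpha) if math.isfinite(r.perm_p)
                           else False,
        })
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df.sort_values(["mirna", "gene", "drug"]).reset_index(drop=True)


def write_records(records: list[MGDTRecord], path, alpha: float = 0.05,
                  header_comments: list[str] | None = None) -> Path:
    """Write scored triplets as a TSV with a fixed column order."""
    path = Path(path)
    df = records_to_frame(records, alpha=alpha)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")
    return path


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
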