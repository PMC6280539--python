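"""Shared fixtures: tiny hand-written input files and in-memory objects."""
import numpy as np
import pandas as pd
import pytest

from mgdtnet import ExpressionStudy, InteractionCatalog


@pytest.fixture
def toy_catalog() -> InteractionCatalog:
    """Three disease genes; g1 has 2 miRNAs + 1 drug, g2 has 1 + 1."""
    return InteractionCatalog(
        disease_genes={"g1": 0.9, "g2": 0.5, "g3": 0.1},
        mirna_targets={("m1", "g1"), ("m2", "g1"), ("m1", "g2")},
        drug_targets={("d1", "g1"), ("d2", "g2")},
    )


@pytest.fixture
def toy_catalog_files(tmp_path, toy_catalog):
    """The toy catalog written in the pipeline's TSV dialect, with one
    duplicate miRNA row to exercise deduplication."""
    dg = tmp_path / "disease_genes.tsv"
    dg.write_text("gene\trisk_score\n" + "".join(
        f"{g}\t{s}\n" for g, s in sorted(toy_catalog.disease_genes.items())))
    mt = tmp_path / "mirna_targets.tsv"
    rows = sorted(toy_catalog.mirna_targets) + [("m1", "g1")]  # duplicate
    mt.write_text("mirna\tgene\n" + "".join(f"{m}\t{g}\n" for m, g in rows))
    dt = tmp_path / "drug_targets.tsv"
    dt.write_text("drug\tgene\n" + "".join(
        f"{d}\t{g}\n" for d, g in sorted(toy_catalog.drug_targets)))
    return dg, mt, dt


def make_study(mrna: dict, mirna: dict, n_disease: int,
               n_control: int) -> ExpressionStudy:
    """Build an ExpressionStudy from feature -> value-list dicts."""
    n = n_disease + n_control
    samples = [f"s{i}" for i in range(n)]
    return ExpressionStudy(
        mrna=pd.DataFrame(mrna, index=samples).T,
        mirna=pd.DataFrame(mirna, index=samples).T,
        labels=pd.Series(["disease"] * n_disease + ["control"] * n_control,
                         index=samples),
    )


@pytest.fixture
def toy_study() -> ExpressionStudy:
    """Deterministic 3-vs-3 study over the toy catalog's features."""
    rng = np.random.default_rng(42)
    feats_g = {g: list(rng.normal(size=6)) for g in ("g1", "g2", "g3")}
    feats_m = {m: list(rng.normal(size=6)) for m in ("m1", "m2")}
    return make_study(feats_g, feats_m, 3, 3)
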