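"""Triplet dysregulation scores, rank aggregation, and the permutation null.

For each miRNA-gene-drug triplet three channels measure disease-specific
dysregulation:

* ``s_risk`` — the gene's disease-association risk score (catalog property,
  identical for triplets sharing a gene);
* ``s_p = p_mrna * p_mirna`` — the product of the two-group Student t-test
  P values of the triplet's mRNA and miRNA (smaller = stronger differential
  expression);
* ``s_pcc = |d_pcc - c_pcc|`` — the absolute difference between the
  miRNA-mRNA Pearson correlation computed over disease samples and over
  control samples (range [0, 2]; large = rewired co-expression).

The three channels live on incomparable scales, so triplets are ranked per
channel (risk and correlation-difference descending, P-product ascending),
each rank r over N triplets is mapped to (N - r + 1) / N, and the final
score is the equal-weight mean of the three, in (0, 1]; higher = more
dysregulated. Significance comes from re-deriving the final score under
random reassignments of the disease/control labels.
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MGDT, ExpressionStudy, InteractionCatalog, MGDTRecord

logger = logging.getLogger(__name__)

__all__ = [
    "student_t_test",
    "pearson_correlation",
    "compute_triplet_scores",
    "aggregate_ranks",
    "permutation_significance",
    "select_significant",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# elementary statistics

def _t_pvalues(mat: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
               welch: bool = False) -> np.ndarray:
    """Two-sided two-sample t-test P value per row of ``mat``.

    Pooled-variance Student t by default (df = n_a + n_b - 2); Welch with
    Satterthwaite df when ``welch``. Zero-variance conventions: equal means
    -> p = 1; unequal means with zero variance -> p = 0.
    """
    a, b = mat[:, idx_a], mat[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            va = ssa / max(na - 1, 1) / na
            vb = ssb / max(nb - 1, 1) / nb
            se = np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va ** 2 / max(na - 1, 1)
                                   + vb ** 2 / max(nb - 1, 1))
        else:
            sp2 = (ssa + ssb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full(mat.shape[0], na + nb - 2, dtype=float)
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = ~np.isfinite(se) | (se == 0.0)
    if degenerate.any():
        p = np.where(degenerate & (diff == 0.0), 1.0, p)
        p = np.where(degenerate & (diff != 0.0), 0.0, p)
    return p


def student_t_test(group_a, group_b, *, welch: bool = False,
                   min_group_size: int = 2,
                   feature: str = "") -> tuple[float, float]:
    """Two-sample t-test; returns (t statistic, two-sided P value).

    Pooled-variance Student t with df = n_a + n_b - 2 unless ``welch``.
    Degenerate zero-variance inputs follow the conventions of
    :func:`_t_pvalues` (t reported as 0 or signed infinity accordingly).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < min_group_size or len(b) < min_group_size:
        who = f" for feature {feature!r}" if feature else ""
        raise ValueError(
            f"t-test needs >= {min_group_size} samples per group{who}: "
            f"got {len(a)} vs {len(b)}")
    mat = np.vstack([np.concatenate([a, b])])
    idx_a = np.arange(len(a))
    idx_b = np.arange(len(a), len(a) + len(b))
    p = float(_t_pvalues(mat, idx_a, idx_b, welch=welch)[0])
    diff = a.mean() - b.mean()
    if welch:
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    else:
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
            / (len(a) + len(b) - 2)
        se = math.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    return t, p


def _row_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between paired rows of x and y; 0 where a row is constant."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Needs >= 3 paired observations. A constant vector makes r undefined;
    it is reported as 0 with a logged warning (degenerate convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"Pearson correlation needs >= 3 samples, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector in Pearson correlation; "
                       "reporting r = 0 (degenerate)")
        return 0.0
    return float(_row_correlations(x[None, :], y[None, :])[0])


# ---------------------------------------------------------------------------
# score assembly

class _ScoreEngine:
    """Precomputed index arrays for fast repeated scoring of one triplet set.

    Maps the triplet list onto row indices of the expression matrices once,
    then evaluates (s_p, s_pcc) per triplet for any disease/control column
    split — the observed labels or a permutation.
    """

    def __init__(self, study: ExpressionStudy, catalog: InteractionCatalog,
                 triplets: list[MGDT], *, welch: bool = False,
                 allow_degenerate_groups: bool = False) -> None:
        if not triplets:
            raise ValueError("no triplets to score")
        study.validate()
        self.welch = welch
        self.allow_degenerate = allow_degenerate_groups

        genes = sorted({t.gene for t in triplets})
        mirnas = sorted({t.mirna for t in triplets})
        missing_g = [g for g in genes if g not in study.mrna.index]
        missing_m = [m for m in mirnas if m not in study.mirna.index]
        missing_risk = [g for g in genes if g not in catalog.disease_genes]
        offenders = []
        if missing_g:
            offenders.append(f"genes absent from mRNA matrix: {missing_g[:10]}")
        if missing_m:
            offenders.append(f"miRNAs absent from miRNA matrix: {missing_m[:10]}")
        if missing_risk:
            offenders.append(f"genes without a risk score: {missing_risk[:10]}")
        if offenders:
            raise ValueError("; ".join(offenders))

        self.gene_index = {g: i for i, g in enumerate(genes)}
        self.mirna_index = {m: i for i, m in enumerate(mirnas)}
        self.gmat = study.mrna.loc[genes].to_numpy(dtype=float)
        self.mmat = study.mirna.loc[mirnas].to_numpy(dtype=float)

        pairs = sorted({(t.gene, t.mirna) for t in triplets})
        self.pair_index = {p: i for i, p in enumerate(pairs)}
        self.pair_g = np.array([self.gene_index[g] for g, _ in pairs])
        self.pair_m = np.array([self.mirna_index[m] for _, m in pairs])

        self.trip_g = np.array([self.gene_index[t.gene] for t in triplets])
        self.trip_m = np.array([self.mirna_index[t.mirna] for t in triplets])
        self.trip_pair = np.array([self.pair_index[(t.gene, t.mirna)]
                                   for t in triplets])
        self.s_risk = np.array([catalog.disease_genes[t.gene]
                                for t in triplets])
        self.triplets = triplets

        labels = study.labels.to_numpy()
        self.idx_disease = np.flatnonzero(labels == "disease")
        self.idx_control = np.flatnonzero(labels == "control")
        self._check_group(len(self.idx_disease), "disease")
        self._check_group(len(self.idx_control), "control")

    def _check_group(self, n: int, name: str) -> None:
        min_t, min_r = 2, 3
        if self.allow_degenerate:
            if n < 1:
                raise ValueError(f"group {name!r} is empty")
            if n < min_r:
                logger.warning(
                    "group %r has %d sample(s); its Pearson correlation is "
                    "undefined and will be reported as 0", name, n)
            return
        if n < max(min_t, min_r):
            raise ValueError(
                f"group {name!r} has {n} samples; scoring needs >= {min_r} "
                f"per group (pass allow_degenerate_groups=True to proceed "
                f"with the undefined correlation set to 0)")

    def _group_corr(self, idx: np.ndarray) -> np.ndarray:
        if len(idx) < 3:
            return np.zeros(len(self.pair_g))
        return _row_correlations(self.gmat[self.pair_g][:, idx],
                                 self.mmat[self.pair_m][:, idx])

    def score(self, idx_d: np.ndarray, idx_c: np.ndarray):
        """Return (p_gene, p_mirna, d_pcc, c_pcc) aligned to the triplets."""
        pg = _t_pvalues(self.gmat, idx_d, idx_c, welch=self.welch)
        pm = _t_pvalues(self.mmat, idx_d, idx_c, welch=self.welch)
        d_pcc = self._group_corr(idx_d)
        c_pcc = self._group_corr(idx_c)
        return (pg[self.trip_g], pm[self.trip_m],
                d_pcc[self.trip_pair], c_pcc[self.trip_pair])


def compute_triplet_scores(study: ExpressionStudy,
                           catalog: InteractionCatalog,
                           triplets: list[MGDT], *,
                           welch: bool = False,
                           allow_degenerate_groups: bool = False
                           ) -> list[MGDTRecord]:
    """Compute s_risk, s_p and s_pcc for every triplet (ranks left unset)."""
    eng = _ScoreEngine(study, catalog, triplets, welch=welch,
                       allow_degenerate_groups=allow_degenerate_groups)
    pg, pm, d_pcc, c_pcc = eng.score(eng.idx_disease, eng.idx_control)
    records = []
    for i, t in enumerate(triplets):
        records.append(MGDTRecord(
            triplet=t, s_risk=float(eng.s_risk[i]),
            p_mrna=float(pg[i]), p_mirna=float(pm[i]),
            s_p=float(pg[i] * pm[i]),
            d_pcc=float(d_pcc[i]), c_pcc=float(c_pcc[i]),
            s_pcc=float(abs(d_pcc[i] - c_pcc[i])),
        ))
    return records


def _final_scores(s_risk: np.ndarray, s_p: np.ndarray,
                  s_pcc: np.ndarray) -> np.ndarray:
    """Equal-weight rank aggregate of the three score channels.

    Ranks: s_risk descending, s_p ascending (small P = strong), s_pcc
    descending; average rank on ties; rank r over N maps to (N - r + 1) / N;
    final score = mean of the three mapped values, in (0, 1].
    """
    n = len(s_risk)
    def conv(ranks: np.ndarray) -> np.ndarray:
        return (n - ranks + 1.0) / n
    r_risk = stats.rankdata(-s_risk, method="average")
    r_p = stats.rankdata(s_p, method="average")
    r_pcc = stats.rankdata(-s_pcc, method="average")
    return (conv(r_risk) + conv(r_p) + conv(r_pcc)) / 3.0


def aggregate_ranks(records: list[MGDTRecord]) -> list[MGDTRecord]:
    """Set ``final_score`` on every record by equal-weight rank aggregation."""
    if not records:
        raise ValueError("aggregate_ranks needs >= 1 record")
    final = _final_scores(np.array([r.s_risk for r in records]),
                          np.array([r.s_p for r in records]),
                          np.array([r.s_pcc for r in records]))
    for rec, f in zip(records, final):
        rec.final_score = float(f)
    return records


# ---------------------------------------------------------------------------
# permutation null

def permutation_significance(study: ExpressionStudy,
                             catalog: InteractionCatalog,
                             triplets: list[MGDT],
                             n_perm: int = 1000,
                             seed: int = 0, *,
                             welch: bool = False,
                             allow_degenerate_groups: bool = False,
                             pooled: bool = False) -> list[MGDTRecord]:
    """Score the triplets and attach label-permutation P values.

    Each of the ``n_perm`` permutations reassigns the disease/control labels
    uniformly at random (group sizes preserved, identical reassignment for
    the mRNA and miRNA matrices — drawn with replacement across
    permutations), recomputes s_p and s_pcc (s_risk is label-invariant),
    re-runs the rank aggregation over all triplets, and records each
    triplet's permuted final score. The add-one estimator gives

        perm_p = (1 + #{permuted final >= observed final}) / (1 + n_perm)

    per triplet; with ``pooled=True`` the observed score is instead compared
    against the pooled permuted scores of all triplets. Reproducible for a
    given ``seed``: one ``numpy.random.default_rng(seed)`` stream, consumed
    as one full label permutation per iteration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = _ScoreEngine(study, catalog, triplets, welch=welch,
                       allow_degenerate_groups=allow_degenerate_groups)
    records = compute_triplet_scores(
        study, catalog, triplets, welch=welch,
        allow_degenerate_groups=allow_degenerate_groups)
    aggregate_ranks(records)
    observed = np.array([r.final_score for r in records])

    n_samples = len(study.labels)
    n_d = len(eng.idx_disease)
    n_distinct = math.comb(n_samples, n_d)
    if n_distinct < n_perm:
        logger.warning(
            "only %d distinct label assignments exist but %d permutations "
            "requested; sampling with replacement", n_distinct, n_perm)

    rng = np.random.default_rng(seed)
    n_trip = len(triplets)
    ge_counts = np.zeros(n_trip, dtype=np.int64)
    pooled_counts = np.zeros(n_trip, dtype=np.int64)
    for _ in range(n_perm):
        order = rng.permutation(n_samples)
        idx_d, idx_c = order[:n_d], order[n_d:]
        pg, pm, d_pcc, c_pcc = eng.score(idx_d, idx_c)
        perm_final = _final_scores(eng.s_risk, pg * pm,
                                   np.abs(d_pcc - c_pcc))
        if pooled:
            srt = np.sort(perm_final)
            pooled_counts += n_trip - np.searchsorted(srt, observed,
                                                      side="left")
        else:
            ge_counts += perm_final >= observed
    if pooled:
        perm_p = (1.0 + pooled_counts) / (1.0 + n_perm * n_trip)
    else:
        perm_p = (1.0 + ge_counts) / (1.0 + n_perm)
    for rec, p in zip(records, perm_p):
        rec.perm_p = float(p)
    return records


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (FDR control)."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def select_significant(records: list[MGDTRecord], alpha: float = 0.05, *,
                       bh_adjust: bool = False
                       ) -> tuple[list[MGDTRecord], float]:
    """Records with perm_p < alpha (strict), plus the selected fraction.

    ``bh_adjust=True`` applies the selection to Benjamini-Hochberg adjusted
    permutation P values instead of the raw ones.
    """
    if not records:
        return [], 0.0
    pvals = np.array([r.perm_p for r in records])
    if np.isnan(pvals).any():
        raise ValueError("perm_p unset on some records; run "
                         "permutation_significance first")
    if bh_adjust:
        pvals = benjamini_hochberg(pvals)
    keep = [r for r, p in zip(records, pvals) if p < alpha]
    return keep, len(keep) / len(records)
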