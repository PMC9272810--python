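"""miRNA-gene association by correlation, regularized regression and voting.

Because miRNAs repress their targets, a genuine miRNA-target relationship
shows up as a *negative* association between the miRNA's and the gene's
expression across samples. This module quantifies that association with

* linear (Pearson), rank-based (Spearman, Kendall) and nonlinear (distance)
  correlation,
* regularized regression (Lasso, Ridge, Elastic Net) of each gene on a set
  of candidate miRNAs, with the penalty chosen by internal cross-validation,
* a Borda voting rank integrating the per-method orderings (most negative
  association first), and
* an empirical null model: the distribution of a miRNA's correlation with
  genes carrying *zero* evidence from all 40 target-prediction tools, used
  to calibrate observed correlations against chance.

It also correlates miRNAs with arbitrary per-sample scores (e.g. the
immunophenoscore or immune-cell infiltration estimates) and computes a
per-patient gene-set targeting score weighted by prediction-tool support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import (
    ElasticNet, ElasticNetCV, Lasso, LassoCV, Ridge, RidgeCV,
)
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError, ValidationError
from .io_core import GeneSet, PairedDataset
from .target_evidence import N_TOOLS, TargetEvidenceMatrix

logger = logging.getLogger(__name__)

CORRELATION_METHODS = ("pearson", "spearman", "kendall", "distance")
REGRESSION_MODELS = ("lasso", "ridge", "enet")

#: attribute of AssociationResult holding each method's statistic
_METHOD_ATTR = {
    "pearson": "r_pearson",
    "spearman": "r_spearman",
    "kendall": "r_kendall",
    "distance": "r_distance",
    "lasso": "coef_lasso",
    "ridge": "coef_ridge",
    "enet": "coef_enet",
}


@dataclass
class AssociationResult:
    """Association evidence for a single (miRNA, gene) pair."""

    mirna: str
    gene: str
    r_pearson: float | None = None
    r_spearman: float | None = None
    r_kendall: float | None = None
    r_distance: float | None = None
    p_pearson: float | None = None
    p_spearman: float | None = None
    p_kendall: float | None = None
    p_distance: float | None = None
    q_pearson: float | None = None
    q_spearman: float | None = None
    q_kendall: float | None = None
    q_distance: float | None = None
    coef_lasso: float | None = None
    coef_ridge: float | None = None
    coef_enet: float | None = None
    support: int = 0
    empirical_p: float | None = None
    vote_score: float | None = None
    vote_rank: int | None = None


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabulate results, one row per pair, all fields as columns."""
    cols = [f.name for f in dc_fields(AssociationResult)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])


# ---------------------------------------------------------------------------
# Correlation


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation in [0, 1].

    Double-centers the pairwise absolute-distance matrices of x and y and
    normalizes their inner product; zero iff (population-level) independence,
    sensitive to nonlinear dependence that Pearson misses.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom == 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def correlate_pair(
    x, y, method: str = "pearson", n_permutations: int = 200,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Correlation between two sample vectors with a two-sided p-value.

    ``method`` is one of pearson / spearman / kendall / distance. Missing
    values are dropped pairwise; at least 4 complete observations are
    required and constant input is rejected. The distance-correlation p is a
    seeded permutation p (add-one estimator).
    """
    x, y = _pairwise_complete(x, y)
    if x.size < 4:
        raise AnalysisError(f"need >=4 pairwise-complete observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "kendall":
        r, p = stats.kendalltau(x, y)
    elif method == "distance":
        r = distance_correlation(x, y)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            if distance_correlation(x, rng.permutation(y)) >= r:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def correlate_all(
    ds: PairedDataset,
    mirnas: Sequence[str],
    genes: Sequence[str],
    ev: TargetEvidenceMatrix | None = None,
    methods: Sequence[str] = ("pearson", "spearman"),
    seed: int | None = 0,
) -> list[AssociationResult]:
    """Correlate every requested miRNA with every requested gene.

    One :class:`AssociationResult` per (miRNA, gene) pair; BH q-values are
    computed per method across all pairs of this call; the support count is
    filled from the evidence matrix when one is given.
    """
    if not mirnas or not genes:
        raise AnalysisError("empty miRNA or gene list")
    missing_m = [m for m in mirnas if m not in ds.mirnas.data.index]
    missing_g = [g for g in genes if g not in ds.genes.data.index]
    if missing_m or missing_g:
        raise AnalysisError(f"ids absent from dataset: {(missing_m + missing_g)[:5]}")
    for method in methods:
        if method not in CORRELATION_METHODS:
            raise ValidationError(f"unknown correlation method {method!r}")

    results = []
    for m in mirnas:
        xm = ds.mirnas.data.loc[m].to_numpy()
        for g in genes:
            yg = ds.genes.data.loc[g].to_numpy()
            res = AssociationResult(mirna=m, gene=g)
            for method in methods:
                r, p = correlate_pair(xm, yg, method, seed=seed)
                setattr(res, _METHOD_ATTR[method], r)
                setattr(res, "p_" + method, p)
            if ev is not None:
                res.support = ev.support(m, g)
            results.append(res)

    for method in methods:
        pvals = np.array([getattr(r, "p_" + method) for r in results])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            setattr(r, "q_" + method, float(q))
    return results


# ---------------------------------------------------------------------------
# Regularized regression


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        raise AnalysisError("cannot standardize a constant vector")
    return (a - a.mean()) / sd


def regularized_fit(
    ds: PairedDataset,
    gene: str,
    candidate_mirnas: Sequence[str],
    model: str = "lasso",
    alpha: float | None = None,
    l1_ratio: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Regress a gene's expression on candidate miRNAs with a penalized model.

    The response (gene) and every predictor (miRNA) are standardized, so the
    returned coefficients are directly comparable across miRNAs; a negative
    coefficient supports repression. ``model`` is lasso / ridge / enet; when
    ``alpha`` is None the penalty weight is chosen by seeded 5-fold CV.
    """
    if not candidate_mirnas:
        raise AnalysisError("candidate miRNA set is empty")
    if ds.n_samples < 10:
        raise AnalysisError(f"need >=10 samples, got {ds.n_samples}")
    if model not in REGRESSION_MODELS:
        raise ValidationError(f"unknown regression model {model!r}")
    y = _zscore(ds.genes.data.loc[gene].to_numpy())
    X = np.column_stack([
        _zscore(ds.mirnas.data.loc[m].to_numpy()) for m in candidate_mirnas
    ])
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    alphas = np.logspace(-3, 2, 30)
    if model == "lasso":
        est = (Lasso(alpha=alpha) if alpha is not None
               else LassoCV(cv=cv, alphas=alphas, random_state=seed))
    elif model == "ridge":
        est = (Ridge(alpha=alpha) if alpha is not None
               else RidgeCV(cv=cv, alphas=np.logspace(-3, 4, 40)))
    else:
        est = (ElasticNet(alpha=alpha, l1_ratio=l1_ratio) if alpha is not None
               else ElasticNetCV(cv=cv, alphas=alphas, l1_ratio=l1_ratio,
                                 random_state=seed))
    est.fit(X, y)
    return {m: float(c) for m, c in zip(candidate_mirnas, est.coef_)}


def add_regression(
    results: Sequence[AssociationResult],
    ds: PairedDataset,
    models: Sequence[str] = ("lasso",),
    seed: int = 0,
) -> Sequence[AssociationResult]:
    """Fill regression coefficients into correlation results, per gene.

    For each gene appearing in ``results``, its candidate miRNAs are all
    miRNAs paired with it in ``results``; one fit per (gene, model).
    """
    by_gene: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, rs in by_gene.items():
        cands = [r.mirna for r in rs]
        for model in models:
            coefs = regularized_fit(ds, gene, cands, model=model, seed=seed)
            for r in rs:
                setattr(r, "coef_" + model, coefs[r.mirna])
    return results


# ---------------------------------------------------------------------------
# Voting


def vote_rank(
    results: Sequence[AssociationResult],
    methods_used: Sequence[str],
) -> Sequence[AssociationResult]:
    """Borda-integrate per-method orderings into a single candidate rank.

    For signed statistics (correlations, regression coefficients) the most
    *negative* value gets rank 1 — repression is the biological expectation.
    The signless distance correlation ranks descending (strongest dependence
    first). Ties receive average ranks within a method; ``vote_score`` is the
    mean rank over methods, and ``vote_rank`` orders pairs by vote_score
    ascending with lexicographic (mirna, gene) tie-break.
    """
    if not results:
        raise AnalysisError("no results to rank")
    rank_matrix = []
    for method in methods_used:
        attr = _METHOD_ATTR.get(method)
        if attr is None:
            raise ValidationError(f"unknown method {method!r}")
        vals = []
        for r in results:
            v = getattr(r, attr)
            if v is None:
                raise AnalysisError(
                    f"pair ({r.mirna}, {r.gene}) has no value for method {method!r}"
                )
            vals.append(v)
        vals = np.asarray(vals, dtype=float)
        if method == "distance":
            vals = -vals  # strongest dependence first
        rank_matrix.append(stats.rankdata(vals, method="average"))
    scores = np.mean(rank_matrix, axis=0)
    order = sorted(range(len(results)),
                   key=lambda i: (scores[i], results[i].mirna, results[i].gene))
    for rank0, i in enumerate(order):
        results[i].vote_score = float(scores[i])
        results[i].vote_rank = rank0 + 1
    return results


# ---------------------------------------------------------------------------
# Empirical null model


@dataclass
class NullModel:
    """Null correlation distribution for one miRNA.

    Correlations of the miRNA with genes that carry *no* evidence from any of
    the 40 target-prediction tools — the best available "random gene"
    population for calibrating observed correlations.
    """

    mirna: str
    method: str
    sampled_genes: list[str]
    null_correlations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.null_correlations) < 100:
            raise ValidationError("null model needs >=100 correlations")


#: default number of zero-evidence genes drawn for the null model
DEFAULT_N_NULL = 1000


def build_null(
    ds: PairedDataset,
    mirna: str,
    ev: TargetEvidenceMatrix,
    n_null: int = DEFAULT_N_NULL,
    method: str = "pearson",
    seed: int = 0,
) -> NullModel:
    """Correlate a miRNA with ``n_null`` randomly drawn zero-evidence genes.

    Genes with support 0 across all 40 tools for this miRNA form the sampling
    pool; sampling is seeded and without replacement. If the pool is smaller
    than ``n_null`` all available genes are used with a warning; fewer than
    100 zero-evidence genes make the null unreliable and raise an error.
    """
    with_evidence = ev.genes_with_evidence(mirna)
    pool = [g for g in ds.genes.feature_ids if g not in with_evidence]
    if len(pool) < 100:
        raise AnalysisError(
            f"only {len(pool)} zero-evidence genes for {mirna}; null unreliable"
        )
    rng = np.random.default_rng(seed)
    if len(pool) < n_null:
        logger.warning("only %d zero-evidence genes available (requested %d)",
                       len(pool), n_null)
        sampled = list(pool)
    else:
        sampled = list(rng.choice(pool, size=n_null, replace=False))
    x = ds.mirnas.data.loc[mirna].to_numpy()
    nulls = np.array([
        correlate_pair(x, ds.genes.data.loc[g].to_numpy(), method, seed=seed)[0]
        for g in sampled
    ])
    return NullModel(mirna=mirna, method=method, sampled_genes=sampled,
                     null_correlations=nulls)


def empirical_p(null: "NullModel | np.ndarray", observed_r: float,
                tail: str = "negative") -> float:
    """Add-one empirical p-value of an observed correlation against the null.

    negative tail: p = (1 + #{null_i <= observed}) / (n_null + 1); mirrored
    for the positive tail; two-sided compares absolute values. The add-one
    estimator keeps p >= 1/(n_null + 1), never exactly zero. ``null`` is a
    :class:`NullModel` or a raw array of null statistics.
    """
    nulls = (null.null_correlations if isinstance(null, NullModel)
             else np.asarray(null, dtype=float))
    if nulls.size == 0:
        raise AnalysisError("empty null distribution")
    n = len(nulls)
    if tail == "negative":
        hits = int(np.sum(nulls <= observed_r))
    elif tail == "positive":
        hits = int(np.sum(nulls >= observed_r))
    elif tail == "two_sided":
        hits = int(np.sum(np.abs(nulls) >= abs(observed_r)))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (1 + hits) / (n + 1)


def add_empirical_p(
    results: Sequence[AssociationResult],
    ds: PairedDataset,
    ev: TargetEvidenceMatrix,
    n_null: int = DEFAULT_N_NULL,
    method: str = "pearson",
    tail: str = "negative",
    seed: int = 0,
) -> Sequence[AssociationResult]:
    """Calibrate each result's correlation against its miRNA's null model."""
    attr = _METHOD_ATTR[method]
    nulls: dict[str, NullModel] = {}
    for r in results:
        if r.mirna not in nulls:
            nulls[r.mirna] = build_null(ds, r.mirna, ev, n_null, method, seed)
        obs = getattr(r, attr)
        if obs is None:
            raise AnalysisError(f"({r.mirna}, {r.gene}) lacks {method} correlation")
        r.empirical_p = empirical_p(nulls[r.mirna], obs, tail)
    return results


# ---------------------------------------------------------------------------
# Score association and per-patient gene-set targeting score


def score_association(
    ds: PairedDataset,
    mirnas: Sequence[str],
    score_name: str,
    method: str = "pearson",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Correlate miRNAs with a per-sample continuous score (e.g. IPS).

    Returns a DataFrame (mirna, r, p, q) with BH correction across the tested
    miRNAs.
    """
    if score_name not in ds.scores:
        raise AnalysisError(
            f"unknown score {score_name!r}; available: {sorted(ds.scores)}"
        )
    if not mirnas:
        raise AnalysisError("empty miRNA list")
    score = ds.scores[score_name].to_numpy()
    rows = []
    for m in mirnas:
        r, p = correlate_pair(ds.mirnas.data.loc[m].to_numpy(), score, method,
                              seed=seed)
        rows.append({"mirna": m, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def geneset_target_score(
    ds: PairedDataset,
    mirna: str,
    gene_set: GeneSet,
    ev: TargetEvidenceMatrix,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-patient targeting score of a miRNA over a gene set.

    For sample s: score(s) = sum over genes g in the set (present in the
    data) of w_g * z_g(s), where w_g = support(mirna, g) / 40 and z_g is the
    gene's expression standardized across samples. Genes without tool support
    contribute nothing. Returns the score vector and the weight table used,
    for transparency.
    """
    present = sorted(gene_set.members & set(ds.genes.feature_ids))
    if not present:
        raise AnalysisError(f"gene set {gene_set.name!r} shares no genes with data")
    weights = pd.DataFrame({
        "gene": present,
        "support": [ev.support(mirna, g) for g in present],
    })
    weights["weight"] = weights["support"] / N_TOOLS
    sub = ds.genes.data.loc[present]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    z = z.fillna(0.0)  # constant genes carry no signal
    score = z.mul(weights.set_index("gene")["weight"], axis=0).sum(axis=0)
    score.name = f"{mirna}:{gene_set.name}"
    return score, weights
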