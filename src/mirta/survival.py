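"""Prognostic biomarker selection and survival analysis.

Candidate prognostic features are miRNAs, genes, or miRNA/gene *ratios* (the
difference of the two log2 values — a quotient on the original scale), for
instance restricted to an immune signature. Feature selection ranks
candidates by *presence*: the fraction of (cross-validation fold x model)
combinations in which a feature lands among the top-n by absolute weight or
importance, using ridge-penalized Cox regression, gradient-boosted survival
trees and a linear survival SVM.

Kaplan-Meier analysis dichotomizes patients into high/low expression at a
chosen percentile (median by default) or at the *optimal* cutpoint — the one
minimizing the log-rank p over the 10th-90th percentile range. Minimum-p
scanning is anti-conservative, so the optimal mode also reports a
permutation-adjusted p (survival labels permuted against the feature).

A miRNA-gene survival network annotates each node with its univariate Cox
hazard direction and flags edges where a miRNA and its target act in
*opposing* directions on survival (one risk, one protective), the pattern
expected of a repressive interaction with prognostic relevance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sksurv.ensemble import GradientBoostingSurvivalAnalysis
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from .exceptions import AnalysisError, ValidationError
from .io_core import ClinicalTable, PairedDataset
from .association import AssociationResult

logger = logging.getLogger(__name__)

SURVIVAL_MODELS = ("penalized_cox", "gradient_boosting", "survival_svm")


@dataclass
class SurvivalFeature:
    """A per-sample feature entering survival analysis.

    ``feature_id`` is a miRNA id, a gene id, or a ratio id
    ``"<mirna>/<gene>"`` whose values are miRNA log2 minus gene log2.
    """

    feature_id: str
    values: pd.Series  # indexed by sample id


def expression_feature(ds: PairedDataset, feature_id: str) -> SurvivalFeature:
    """Look up a miRNA or gene as a survival feature."""
    if feature_id in ds.mirnas.data.index:
        vals = ds.mirnas.data.loc[feature_id]
    elif feature_id in ds.genes.data.index:
        vals = ds.genes.data.loc[feature_id]
    else:
        raise AnalysisError(f"feature {feature_id!r} not in dataset")
    return SurvivalFeature(feature_id, vals.copy())


def make_ratio_features(
    ds: PairedDataset,
    pairs: Iterable[tuple[str, str]],
) -> list[SurvivalFeature]:
    """miRNA/gene ratio features: log2(miRNA) - log2(gene) per sample.

    Pairs whose miRNA or gene is absent from the dataset are skipped with a
    warning.
    """
    out = []
    for mirna, gene in pairs:
        if mirna not in ds.mirnas.data.index or gene not in ds.genes.data.index:
            logger.warning("skipping ratio %s/%s: parent feature missing", mirna, gene)
            continue
        vals = ds.mirnas.data.loc[mirna] - ds.genes.data.loc[gene]
        out.append(SurvivalFeature(f"{mirna}/{gene}", vals))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier with median / optimal dichotomization


@dataclass
class KMResult:
    """Dichotomized Kaplan-Meier comparison of high vs low expression."""

    feature_id: str
    cutpoint: float
    percentile: float  # fraction of samples in the low group
    n_low: int
    n_high: int
    logrank_statistic: float
    p_value: float
    adjusted_p: float | None  # permutation-adjusted (optimal mode only)
    hazard_ratio: float
    hr_ci: tuple[float, float]
    curves: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)


def _km_curves(time, event, high) -> dict[str, pd.DataFrame]:
    curves = {}
    for name, mask in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=name)
        curves[name] = kmf.survival_function_
    return curves


def _logrank(time, event, high) -> tuple[float, float]:
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return float(res.test_statistic), float(res.p_value)


def _logrank_fast(time, event, high) -> tuple[float, float]:
    """Observed-minus-expected log-rank chi-square via vectorized lifetables.

    Same statistic as :func:`_logrank`; used inside the optimal-cutpoint scan
    where lifelines' per-call overhead dominates.
    """
    from scipy import stats as _st
    et_all, d_all = np.unique(time[event == 1], return_counts=True)
    if et_all.size == 0:
        return 0.0, 1.0
    et1, d1c = np.unique(time[(event == 1) & high], return_counts=True)
    d1 = np.zeros_like(d_all, dtype=float)
    if et1.size:
        d1[np.searchsorted(et_all, et1)] = d1c
    sorted_all = np.sort(time)
    sorted_hi = np.sort(time[high])
    n_at = time.size - np.searchsorted(sorted_all, et_all, side="left")
    n1_at = sorted_hi.size - np.searchsorted(sorted_hi, et_all, side="left")
    frac = n1_at / n_at
    exp1 = d_all * frac
    var = d_all * frac * (1 - frac) * (n_at - d_all) / np.maximum(n_at - 1, 1)
    v = var.sum()
    if v == 0:
        return 0.0, 1.0
    chi2 = float((d1.sum() - exp1.sum()) ** 2 / v)
    return chi2, float(_st.chi2.sf(chi2, 1))


def _binary_cox(time, event, high) -> tuple[float, tuple[float, float]]:
    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(float)})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = cph.confidence_intervals_.loc["high"]
        return hr, (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
    except (ConvergenceError, ValueError):
        return float("nan"), (float("nan"), float("nan"))


def _aligned_survival(feature: SurvivalFeature, clinical: ClinicalTable,
                      min_samples: int = 10,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    common = [s for s in feature.values.index if s in clinical.data.index]
    cl = clinical.data.loc[common, ["time", "event"]].dropna()
    vals = feature.values.loc[cl.index]
    keep = vals.notna()
    vals, cl = vals[keep], cl.loc[keep]
    if len(vals) < min_samples:
        raise AnalysisError(f"only {len(vals)} samples with survival data")
    return (vals.to_numpy(), cl["time"].to_numpy(), cl["event"].to_numpy().astype(int))


def km_analysis(
    feature: SurvivalFeature,
    clinical: ClinicalTable,
    percentile: float | str = 0.5,
    min_group_frac: float = 0.1,
    n_permutations: int = 200,
    seed: int = 0,
    min_samples: int = 10,
) -> KMResult:
    """Kaplan-Meier high-vs-low comparison of one feature.

    ``percentile`` is the low-group fraction (0.5 = median split) or
    ``"optimal"``: scan every candidate cutpoint between the 10th and 90th
    percentile (splits leaving a group below ``min_group_frac`` of samples
    are rejected) and take the minimum log-rank p; a permutation-adjusted p
    (add-one, ``n_permutations`` label permutations of the same scan) is then
    reported alongside the nominal one.
    """
    values, time, event = _aligned_survival(feature, clinical, min_samples)
    if np.ptp(values) == 0:
        raise AnalysisError(f"feature {feature.feature_id!r} is constant")
    n = len(values)
    min_group = max(2, int(np.ceil(min_group_frac * n)))

    def scan_best(t, e):
        lo, hi = np.quantile(values, [0.10, 0.90])
        candidates = np.unique(values[(values >= lo) & (values <= hi)])
        best = None
        for c in candidates:
            high = values > c
            if high.sum() < min_group or (~high).sum() < min_group:
                continue
            stat, p = _logrank_fast(t, e, high)
            if best is None or p < best[1]:
                best = (c, p, stat)
        if best is None:
            raise AnalysisError("no admissible cutpoint in the 10-90 percentile range")
        return best

    if percentile == "optimal":
        cut, p, stat = scan_best(time, event)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            _, p_perm, _ = scan_best(time[perm], event[perm])
            if p_perm <= p:
                hits += 1
        adjusted = (1 + hits) / (n_permutations + 1)
    else:
        if not 0 < float(percentile) < 1:
            raise ValidationError("percentile must be in (0, 1) or 'optimal'")
        cut = float(np.quantile(values, float(percentile)))
        high = values > cut
        if high.sum() < min_group or (~high).sum() < min_group:
            raise AnalysisError("percentile split leaves a group too small")
        stat, p = _logrank(time, event, high)
        adjusted = None

    high = values > cut
    hr, ci = _binary_cox(time, event, high)
    return KMResult(
        feature_id=feature.feature_id,
        cutpoint=float(cut),
        percentile=float(np.mean(values <= cut)),
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        logrank_statistic=stat,
        p_value=p,
        adjusted_p=adjusted,
        hazard_ratio=hr,
        hr_ci=ci,
        curves=_km_curves(time, event, high),
    )


# ---------------------------------------------------------------------------
# Univariate Cox


@dataclass
class CoxResult:
    feature_id: str
    hazard_ratio: float  # per 1 sd of the feature
    ci: tuple[float, float]
    p_value: float
    converged: bool

    @property
    def direction(self) -> str:
        return "risk" if self.hazard_ratio > 1 else "protective"


def cox_univariate(feature: SurvivalFeature, clinical: ClinicalTable) -> CoxResult:
    """Univariate proportional-hazards fit on the standardized feature.

    The hazard ratio is per 1 sd. Non-convergence yields a flagged result
    (``converged=False``, NaN estimates) rather than an exception.
    """
    values, time, event = _aligned_survival(feature, clinical)
    if np.ptp(values) == 0:
        raise AnalysisError(f"feature {feature.feature_id!r} is constant")
    z = (values - values.mean()) / values.std()
    df = pd.DataFrame({"time": time, "event": event, "z": z})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError):
        return CoxResult(feature.feature_id, float("nan"),
                         (float("nan"), float("nan")), float("nan"), False)
    ci = cph.confidence_intervals_.loc["z"]
    return CoxResult(
        feature_id=feature.feature_id,
        hazard_ratio=float(np.exp(cph.params_["z"])),
        ci=(float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))),
        p_value=float(cph.summary.loc["z", "p"]),
        converged=True,
    )


# ---------------------------------------------------------------------------
# Cross-validated presence ranking


@dataclass
class FeatureRanking:
    """Feature -> presence across CV (fold x model) combinations.

    ``table`` columns: feature_id, presence (0..1 in steps of
    1/(k x n_models)), mean_importance (max-normalized within each fold/model
    before averaging), plus per-model presence columns; sorted by presence
    then mean_importance, both descending.
    """

    table: pd.DataFrame
    k: int
    models: tuple[str, ...]
    top_n: int

    def top(self, n: int = 10) -> list[str]:
        return list(self.table["feature_id"].head(n))


def _feature_matrix(features: Sequence[SurvivalFeature]) -> pd.DataFrame:
    X = pd.DataFrame({f.feature_id: f.values for f in features})
    if X.isna().any().any():
        X = X.dropna()
    return X


def _fit_survival_model(model: str, X: np.ndarray, y, seed: int) -> np.ndarray:
    """Fit one selector model and return a nonnegative importance per feature."""
    if model == "penalized_cox":
        est = CoxPHSurvivalAnalysis(alpha=0.1)
        est.fit(X, y)
        return np.abs(est.coef_)
    if model == "gradient_boosting":
        est = GradientBoostingSurvivalAnalysis(
            n_estimators=100, max_depth=2, random_state=seed)
        est.fit(X, y)
        return est.feature_importances_
    if model == "survival_svm":
        est = FastSurvivalSVM(max_iter=100, random_state=seed, tol=1e-5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        return np.abs(est.coef_)
    raise ValidationError(f"unknown survival model {model!r}")


def select_prognostic(
    features: Sequence[SurvivalFeature],
    clinical: ClinicalTable,
    models: Sequence[str] = SURVIVAL_MODELS,
    k: int = 5,
    top_n: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by presence in the CV top candidates.

    Per fold and model: fit on the training split (features standardized with
    training statistics), take the ``top_n`` features by absolute coefficient
    or importance. Presence = fraction of (fold, model) combinations
    containing the feature. Deterministic given ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    for m in models:
        if m not in SURVIVAL_MODELS:
            raise ValidationError(f"unknown survival model {m!r}")
    if len(features) < top_n:
        raise AnalysisError(f"need >= top_n={top_n} features, got {len(features)}")
    X_df = _feature_matrix(features)
    cl = clinical.data.loc[X_df.index, ["time", "event"]].dropna()
    X_df = X_df.loc[cl.index]
    n = len(X_df)
    if n < 5 * k:
        raise AnalysisError(f"need >= {5 * k} samples for {k}-fold CV, got {n}")
    y_all = Surv.from_arrays(cl["event"].astype(bool).to_numpy(),
                             cl["time"].to_numpy())
    feat_ids = list(X_df.columns)
    X_all = X_df.to_numpy()

    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)

    counts = {m: pd.Series(0.0, index=feat_ids) for m in models}
    importance_sum = pd.Series(0.0, index=feat_ids)
    n_combos = 0
    for fold_i, test_idx in enumerate(folds):
        train = np.setdiff1d(idx, test_idx)
        if cl["event"].to_numpy()[train].sum() == 0:
            logger.warning("fold %d: all-censored training split skipped", fold_i)
            continue
        Xtr = X_all[train]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        ytr = y_all[train]
        for model in models:
            imp = _fit_survival_model(model, Xtr, ytr, seed + fold_i)
            top_idx = np.argsort(-imp, kind="stable")[:top_n]
            for j in top_idx:
                counts[model].iloc[j] += 1
            if imp.max() > 0:
                importance_sum += imp / imp.max()
            n_combos += 1

    if n_combos == 0:
        raise AnalysisError("every CV fold was skipped (all-censored splits)")
    presence = sum(counts.values()) / n_combos
    table = pd.DataFrame({
        "feature_id": feat_ids,
        "presence": presence.to_numpy(),
        "mean_importance": (importance_sum / n_combos).to_numpy(),
    })
    for m in models:
        table[f"presence_{m}"] = (counts[m] / max(1, n_combos / len(models))).to_numpy()
    table = table.sort_values(["presence", "mean_importance", "feature_id"],
                              ascending=[False, False, True]).reset_index(drop=True)
    return FeatureRanking(table=table, k=k, models=tuple(models), top_n=top_n)


# ---------------------------------------------------------------------------
# Survival network


def build_survival_network(
    results: Sequence[AssociationResult],
    ds: PairedDataset,
    min_tools: int = 5,
    max_corr: float = -0.4,
    alpha: float = 0.05,
) -> nx.Graph:
    """miRNA-gene network of consensus-supported negative correlations.

    Edges: pairs with support >= ``min_tools`` and Pearson r <= ``max_corr``.
    Nodes carry their univariate Cox hazard ratio and direction; an edge is
    flagged ``opposing_effect`` when the miRNA and the gene have significant
    (p < ``alpha``) hazard ratios on opposite sides of 1.
    """
    if ds.clinical is None:
        raise AnalysisError("survival network requires clinical data")
    g = nx.Graph()
    edges = [r for r in results
             if r.support >= min_tools
             and r.r_pearson is not None and r.r_pearson <= max_corr]
    cox_cache: dict[str, CoxResult] = {}

    def node_cox(fid: str) -> CoxResult:
        if fid not in cox_cache:
            cox_cache[fid] = cox_univariate(expression_feature(ds, fid), ds.clinical)
        return cox_cache[fid]

    for r in edges:
        cm, cg = node_cox(r.mirna), node_cox(r.gene)
        for fid, c, kind in ((r.mirna, cm, "mirna"), (r.gene, cg, "gene")):
            g.add_node(fid, kind=kind, hazard_ratio=c.hazard_ratio,
                       direction=c.direction, cox_p=c.p_value)
        opposing = (
            cm.converged and cg.converged
            and cm.p_value < alpha and cg.p_value < alpha
            and (cm.hazard_ratio > 1) != (cg.hazard_ratio > 1)
        )
        g.add_edge(r.mirna, r.gene, support=r.support, r=r.r_pearson,
                   opposing_effect=bool(opposing))
    return g


def write_network(g: nx.Graph, graphml_path, edgelist_path) -> None:
    """Export a survival network as GraphML plus an edge-list TSV."""
    nx.write_graphml(g, graphml_path)
    rows = [
        {"mirna": u if g.nodes[u]["kind"] == "mirna" else v,
         "gene": v if g.nodes[u]["kind"] == "mirna" else u,
         **data}
        for u, v, data in g.edges(data=True)
    ]
    pd.DataFrame(rows).sort_values(["mirna", "gene"]).to_csv(
        edgelist_path, sep="\t", index=False)
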