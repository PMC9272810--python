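"""Data model and readers/writers for expression cohorts.

The analyses in this package operate on a *paired* bulk-expression cohort: a
gene expression matrix and a microRNA expression matrix measured on the same
patients (log2-transformed, normalized upstream, e.g. with voom for RNA-seq or
rma for microarrays), an optional clinical table with survival and categorical
covariates, and optional precomputed per-sample scores such as the
immunophenoscore or estimated immune-cell infiltrations.

All tabular inputs are plain TSV; gene/miRNA signatures use the GMT format.
Feature-by-sample orientation is used throughout (features in rows, samples in
columns, first column the feature identifier, header row the sample ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError, FormatError, SampleOverlapError, ValidationError

logger = logging.getLogger(__name__)

#: Minimum number of shared samples required to form a paired dataset.
MIN_COMMON_SAMPLES = 10

#: Features missing in more than this fraction of samples are dropped.
MAX_MISSING_FRACTION = 0.2

_MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "NULL", "null"}

_SCALES = ("log2", "counts")


@dataclass
class ExpressionMatrix:
    """A feature-by-sample real matrix with unique row and column ids.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
        Values are floats; NaN marks missing observations.
    scale
        ``"log2"`` for log2-normalized intensities (the default expected by
        every downstream analysis) or ``"counts"`` for raw counts.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        self.data = self.data.astype(float)
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy()).any():
                raise ValidationError("expression values must be finite or missing")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``samples`` in the given order."""
        return ExpressionMatrix(self.data.loc[:, list(samples)].copy(), self.scale)

    def drop_sparse_features(
        self, max_missing: float = MAX_MISSING_FRACTION
    ) -> "ExpressionMatrix":
        """Drop features missing in more than ``max_missing`` of samples."""
        frac = self.data.isna().mean(axis=1)
        dropped = frac.index[frac > max_missing]
        if len(dropped):
            logger.warning(
                "dropping %d features with >%.0f%% missing values: %s%s",
                len(dropped), 100 * max_missing, list(dropped[:5]),
                "..." if len(dropped) > 5 else "",
            )
        return ExpressionMatrix(self.data.drop(index=dropped), self.scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata keyed by sample id.

    ``time`` (nonnegative survival time, any consistent unit) and ``event``
    (1 = event occurred, 0 = censored) are recognized by the survival module;
    any additional columns are categorical/continuous covariates (e.g. a
    response or subtype label used by the classification module).
    """

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        if "time" in self.data.columns:
            t = pd.to_numeric(self.data["time"], errors="coerce")
            if (t.dropna() < 0).any():
                raise ValidationError("survival times must be nonnegative")
            self.data["time"] = t
        if "event" in self.data.columns:
            e = pd.to_numeric(self.data["event"], errors="coerce")
            bad = ~e.dropna().isin([0, 1])
            if bad.any():
                raise ValidationError("event indicator must be 0 or 1")
            self.data["event"] = e

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass(frozen=True)
class GeneSet:
    """A named signature: a non-empty set of gene or miRNA identifiers."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class PairedDataset:
    """Sample-matched gene + miRNA matrices with optional clinical/score data.

    The substrate of every analysis: both matrices (and the clinical table and
    score vectors, when present) share the same samples in the same canonical
    order.
    """

    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    clinical: ClinicalTable | None = None
    scores: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes.sample_ids != self.mirnas.sample_ids:
            raise ValidationError("gene and miRNA matrices have different samples")
        if self.clinical is not None and self.clinical.sample_ids != self.genes.sample_ids:
            raise ValidationError("clinical table samples differ from expression samples")
        for name, vec in self.scores.items():
            if list(vec.index) != self.genes.sample_ids:
                raise ValidationError(f"score {name!r} is not aligned to samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.genes.sample_ids

    @property
    def n_samples(self) -> int:
        return self.genes.n_samples


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read a feature-by-sample TSV expression matrix.

    The first column holds feature ids, the header row sample ids. Cells equal
    to ``NA`` (and common variants) are treated as missing. Duplicate feature
    ids are collapsed by keeping the row with the highest mean expression (the
    standard probe-collapse heuristic; deterministic, first occurrence wins
    ties). Non-numeric cells raise :class:`FormatError` naming the offending
    row and column.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: expression file has no data rows/columns")

    stripped = raw.apply(lambda c: c.str.strip())
    missing = stripped.isin(_MISSING_TOKENS)
    numeric = stripped.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {stripped.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    # re-parse with numpy for correctly-rounded (round-trip exact) floats
    exact = stripped.mask(missing, "nan").to_numpy().astype(np.float64)
    numeric = pd.DataFrame(exact, index=raw.index, columns=raw.columns)

    if numeric.index.duplicated().any():
        means = numeric.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for i, fid in enumerate(numeric.index):
            j = best.get(fid)
            if j is None or means[i] > means[j]:
                best[fid] = i
        keep = sorted(best.values())
        n_dropped = len(numeric) - len(keep)
        logger.warning("%s: collapsed %d duplicate feature rows (kept highest mean)",
                       path, n_dropped)
        numeric = numeric.iloc[keep]

    return ExpressionMatrix(numeric, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that :func:`read_expression_matrix` reads back identically."""
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV: ``sample_id`` column plus ``time``/``event``/covariates."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty clinical file") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: clinical table needs a sample_id column plus data")
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_scores(path: str | Path) -> dict[str, pd.Series]:
    """Read per-sample continuous score vectors (sample_id + one column per score)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {name: df[name].astype(float) for name in df.columns}


def write_scores(scores: Mapping[str, pd.Series], path: str | Path) -> None:
    pd.DataFrame(dict(scores)).to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT signature collection: ``name TAB description TAB member...``.

    Duplicate set names and lines with fewer than three columns are format
    errors; empty member lists are rejected.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 columns")
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m.strip())
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            seen.add(name)
            sets.append(GeneSet(name, description, members))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Sample matching


def match_samples(
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    clinical: ClinicalTable | None = None,
    scores: Mapping[str, pd.Series] | None = None,
    min_samples: int = MIN_COMMON_SAMPLES,
) -> PairedDataset:
    """Restrict all inputs to their common samples, in sorted canonical order.

    Patient ids must match across the expression files and the clinical table;
    the paired dataset is built on the intersection. Fewer than ``min_samples``
    shared samples raises :class:`SampleOverlapError` reporting the counts.
    """
    common = set(genes.sample_ids) & set(mirnas.sample_ids)
    if clinical is not None:
        common &= set(clinical.sample_ids)
    if scores:
        for vec in scores.values():
            common &= set(vec.index)
    order = sorted(common)
    if len(order) < min_samples:
        raise SampleOverlapError(
            f"only {len(order)} samples shared (genes={genes.n_samples}, "
            f"mirnas={mirnas.n_samples}"
            + (f", clinical={len(clinical.sample_ids)}" if clinical is not None else "")
            + f"); need >= {min_samples}"
        )
    return PairedDataset(
        genes=genes.subset_samples(order),
        mirnas=mirnas.subset_samples(order),
        clinical=clinical.subset_samples(order) if clinical is not None else None,
        scores={k: v.loc[order].copy() for k, v in (scores or {}).items()},
    )


# ---------------------------------------------------------------------------
# Differential-expression filter


def de_table(
    matrix: ExpressionMatrix,
    groups: Mapping[str, int] | pd.Series,
    ) -> pd.DataFrame:
    """Per-feature two-group statistics: log2 fold change, Welch t, raw p, BH q.

    ``groups`` maps sample id -> 0/1. Missing values are handled
    pairwise-complete (per-feature omission). Both groups need >= 2 samples.
    """
    groups = pd.Series(groups)
    groups = groups.loc[[s for s in matrix.sample_ids if s in groups.index]]
    g0 = [s for s in groups.index if groups[s] == 0]
    g1 = [s for s in groups.index if groups[s] == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise AnalysisError(
            f"need >=2 samples per group, got {len(g0)} and {len(g1)}"
        )
    x0 = matrix.data[g0].to_numpy()
    x1 = matrix.data[g1].to_numpy()
    mean0 = np.nanmean(x0, axis=1)
    mean1 = np.nanmean(x1, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False, nan_policy="omit")
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2_fc": mean1 - mean0, "t": t, "p": p, "q": q},
        index=matrix.data.index,
    )


def de_filter(
    matrix: ExpressionMatrix,
    groups: Mapping[str, int] | pd.Series,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[str]:
    """Differentially expressed features between two groups.

    Returns features with ``|log2 fold change| >= fc_threshold`` and Welch
    t-test BH-adjusted ``q <= p_threshold`` (BH applied across all tested
    features). The matrix must be on the log2 scale.
    """
    if matrix.scale != "log2":
        raise AnalysisError("de_filter requires a log2-scale matrix")
    table = de_table(matrix, groups)
    hits = table[(table.log2_fc.abs() >= fc_threshold) & (table.q <= p_threshold)]
    return list(hits.index)
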