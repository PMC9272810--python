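"""Seeded generator of paired-cohort inputs with planted effects.

Emulates, on the log2-normalized scale the analyses consume, everything a
real immuno-oncology cohort would provide: a gene and a miRNA expression
matrix over the same patients, survival outcomes, a binary clinical label,
per-sample immune scores, a 40-tool target-evidence matrix and a
synthetic-lethal pair list — with known planted structure so that every
analysis module can be tested for recovery:

* planted regulations: a target gene tracks its miRNA linearly with a
  negative effect, so the pair's expected Pearson correlation is
  ``effect / sqrt(effect^2 + noise_sd^2)`` (miRNA variance is 1);
* survival: exponential event times with log-hazard equal to a linear
  combination of standardized planted features, independent uniform
  administrative censoring calibrated to a target censoring fraction;
* class labels: balanced binary groups with mean shifts on designated
  features;
* evidence: planted pairs receive a configurable support count (default 7 of
  40, always including an experimental source); decoy pairs draw support
  from {1..4}; all other pairs are absent (support 0).

The defaults encode the standard test-bench conditions used throughout the
package's recovery tests (n = 200 samples, regulation effect -0.8, noise sd
0.5, prognostic log-HR 1.0, class shift 3 log2 units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_core import (
    ClinicalTable, ExpressionMatrix, GeneSet, PairedDataset,
    write_clinical_table, write_expression_matrix, write_gene_sets, write_scores,
)
from .target_evidence import (
    N_EXPERIMENTAL, N_TOOLS, SLPairList, TargetEvidenceMatrix,
    write_evidence_matrix, write_sl_pairs,
)

TOOL_NAMES = tuple(f"pred_{i:02d}" for i in range(1, N_TOOLS - N_EXPERIMENTAL + 1)) \
    + tuple(f"exp_{i:02d}" for i in range(1, N_EXPERIMENTAL + 1))
EXPERIMENTAL_NAMES = TOOL_NAMES[-N_EXPERIMENTAL:]


@dataclass(frozen=True)
class PlantedRegulation:
    mirna: str
    gene: str
    effect: float  # negative: repression strength on the log2 scale

    def __post_init__(self) -> None:
        if self.effect >= 0:
            raise ValidationError("planted regulation effects must be negative")


@dataclass
class SurvivalConfig:
    baseline_hazard: float = 0.05
    #: feature id ("miRNA", "gene" or "mirna/gene" ratio) -> log hazard ratio per sd
    log_hrs: dict[str, float] = field(default_factory=dict)
    censoring: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.censoring < 1:
            raise ValidationError("censoring fraction must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_samples: int = 200
    n_genes: int = 400
    n_mirnas: int = 20
    noise_sd: float = 0.5
    planted_regulations: tuple[PlantedRegulation, ...] | None = None
    n_planted: int = 3  # used when planted_regulations is None
    planted_effect: float = -0.8
    planted_support: int = 7
    n_decoy_targets_per_mirna: int = 10
    survival: SurvivalConfig | None = None
    class_effects: dict[str, float] | None = None
    score_mirna: str | None = None  # miRNA whose negative transform becomes a score
    n_sl_pairs: int = 30
    n_essential: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.planted_support < 5:
            raise ValidationError("planted pairs must reach the consensus threshold")


def gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def mirna_name(i: int) -> str:
    return f"hsa-miR-sim{i + 1}-5p"


@dataclass
class SimulatedCohort:
    """Generator output: the paired dataset plus evidence and ground truth."""

    dataset: PairedDataset
    evidence: TargetEvidenceMatrix
    sl_pairs: SLPairList
    essential_genes: set[str]
    labels: pd.Series
    gene_sets: list[GeneSet]
    truth: dict


def _default_config_fill(cfg: SimulationConfig) -> SimulationConfig:
    if cfg.planted_regulations is None:
        regs = tuple(
            PlantedRegulation(mirna_name(i), gene_name(i), cfg.planted_effect)
            for i in range(cfg.n_planted)
        )
        cfg.planted_regulations = regs
    if cfg.survival is None:
        if cfg.planted_regulations:
            # default prognostic structure: first planted miRNA is a risk
            # factor, its target gene protective (the opposing-effect pattern)
            first = cfg.planted_regulations[0]
            cfg.survival = SurvivalConfig(log_hrs={first.mirna: 1.0,
                                                   first.gene: -0.7})
        else:
            cfg.survival = SurvivalConfig()
    if cfg.class_effects is None:
        # a non-planted miRNA separates the two classes by 3 log2 units (3 sd);
        # shifting a planted miRNA would dilute its planted correlation
        idx = min(cfg.n_planted, cfg.n_mirnas - 1)
        cfg.class_effects = {mirna_name(idx): 3.0}
    if cfg.score_mirna is None:
        idx = min(cfg.n_planted + 1, cfg.n_mirnas - 1)
        cfg.score_mirna = mirna_name(idx)
    return cfg


def _feature_vector(ds_genes: pd.DataFrame, ds_mirnas: pd.DataFrame,
                    feature_id: str) -> np.ndarray:
    if "/" in feature_id:
        m, g = feature_id.split("/", 1)
        return ds_mirnas.loc[m].to_numpy() - ds_genes.loc[g].to_numpy()
    if feature_id in ds_mirnas.index:
        return ds_mirnas.loc[feature_id].to_numpy()
    return ds_genes.loc[feature_id].to_numpy()


def _calibrate_censoring(times: np.ndarray, target: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0, u) administrative censoring with u chosen by bisection so the
    realized censoring fraction approximates ``target``."""
    if target == 0:
        return times.copy(), np.ones(times.size, dtype=int)
    u_draws = rng.uniform(0, 1, size=times.size)
    lo, hi = 1e-9, float(times.max()) * 10
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = np.mean(u_draws * mid < times)  # censored fraction at scale mid
        if frac > target:
            lo = mid
        else:
            hi = mid
    censor_times = u_draws * 0.5 * (lo + hi)
    event = (times <= censor_times).astype(int)
    observed = np.minimum(times, censor_times)
    return observed, event


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort from a seeded configuration."""
    cfg = _default_config_fill(config)
    rng = np.random.default_rng(cfg.seed)

    mirna_ids = [mirna_name(i) for i in range(cfg.n_mirnas)]
    gene_ids = [gene_name(i) for i in range(cfg.n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    for reg in cfg.planted_regulations:
        if reg.mirna not in mirna_ids or reg.gene not in gene_ids:
            raise ValidationError(f"planted pair {reg} out of simulated id range")

    # miRNA expression ~ N(8, 1) on the log2 scale
    M = rng.normal(8.0, 1.0, size=(cfg.n_mirnas, cfg.n_samples))
    mirnas_df = pd.DataFrame(M, index=mirna_ids, columns=samples)

    # genes: independent baselines; planted targets track their miRNA
    baselines = rng.uniform(4.0, 10.0, size=cfg.n_genes)
    G = baselines[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    planted_by_gene = {r.gene: r for r in cfg.planted_regulations}
    for gi, gid in enumerate(gene_ids):
        reg = planted_by_gene.get(gid)
        if reg is not None:
            mi = mirna_ids.index(reg.mirna)
            G[gi] = (baselines[gi]
                     + reg.effect * (M[mi] - 8.0)
                     + rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples))
    genes_df = pd.DataFrame(G, index=gene_ids, columns=samples)

    # balanced binary labels, then class shifts on designated features
    labels = pd.Series(0, index=samples, name="group")
    ones = rng.choice(cfg.n_samples, size=cfg.n_samples // 2, replace=False)
    labels.iloc[ones] = 1
    for fid, shift in cfg.class_effects.items():
        target = mirnas_df if fid in mirnas_df.index else genes_df
        target.loc[fid, labels == 1] += shift

    # survival from the final expression values
    risk = np.zeros(cfg.n_samples)
    for fid, beta in cfg.survival.log_hrs.items():
        v = _feature_vector(genes_df, mirnas_df, fid)
        risk += beta * (v - v.mean()) / v.std()
    rate = cfg.survival.baseline_hazard * np.exp(risk)
    latent_times = rng.exponential(1.0 / rate)
    time, event = _calibrate_censoring(latent_times, cfg.survival.censoring, rng)
    clinical = ClinicalTable(pd.DataFrame(
        {"time": time, "event": event, "group": labels.to_numpy()},
        index=pd.Index(samples, name="sample_id"),
    ))

    # immune-like score: noisy negative transform of a designated miRNA
    zm = mirnas_df.loc[cfg.score_mirna]
    zm = (zm - zm.mean()) / zm.std()
    score = -zm + rng.normal(0, 0.5, size=cfg.n_samples)
    scores = {"ips_like": pd.Series(score.to_numpy(), index=samples, name="ips_like")}

    # evidence matrix: planted pairs at planted_support (incl. one
    # experimental source), decoys at 1..4 tools
    rows: dict[tuple[str, str], np.ndarray] = {}
    tool_arr = np.array(TOOL_NAMES)
    pred_idx = np.arange(N_TOOLS - N_EXPERIMENTAL)
    exp_idx = np.arange(N_TOOLS - N_EXPERIMENTAL, N_TOOLS)
    for reg in cfg.planted_regulations:
        row = np.zeros(N_TOOLS, dtype=bool)
        chosen = rng.choice(pred_idx, size=cfg.planted_support - 1, replace=False)
        row[chosen] = True
        row[rng.choice(exp_idx)] = True
        rows[(reg.mirna, reg.gene)] = row
    planted_genes = set(planted_by_gene)
    for m in mirna_ids:
        decoy_pool = [g for g in gene_ids if g not in planted_genes]
        decoys = rng.choice(decoy_pool,
                            size=min(cfg.n_decoy_targets_per_mirna, len(decoy_pool)),
                            replace=False)
        for g in decoys:
            if (m, g) in rows:
                continue
            row = np.zeros(N_TOOLS, dtype=bool)
            support = int(rng.integers(1, 5))
            row[rng.choice(N_TOOLS, size=support, replace=False)] = True
            rows[(m, g)] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(tool_arr))
    table.index = pd.MultiIndex.from_tuples(table.index, names=["mirna", "gene"])
    evidence = TargetEvidenceMatrix(table.sort_index(), EXPERIMENTAL_NAMES)

    # synthetic-lethal pairs: essential partners wired to planted targets,
    # plus random filler pairs
    essential = set(rng.choice(
        [g for g in gene_ids if g not in planted_genes],
        size=cfg.n_essential, replace=False))
    sl: set[tuple[str, str]] = set()
    ess_list = sorted(essential)
    for i, reg in enumerate(cfg.planted_regulations):
        e = ess_list[i % len(ess_list)]
        sl.add((min(e, reg.gene), max(e, reg.gene)))
    while len(sl) < cfg.n_sl_pairs:
        a, b = rng.choice(cfg.n_genes, size=2, replace=False)
        sl.add((min(gene_ids[a], gene_ids[b]), max(gene_ids[a], gene_ids[b])))
    sl_pairs = SLPairList.from_iterable(sl)

    gene_sets = [
        GeneSet("RANDOM_SET", "random control genes",
                frozenset(rng.choice([g for g in gene_ids if g not in planted_genes],
                                     size=min(15, cfg.n_genes - len(planted_genes)),
                                     replace=False))),
    ]
    if planted_genes:
        gene_sets.insert(0, GeneSet("PLANTED_TARGETS", "planted direct targets",
                                    frozenset(planted_genes)))

    dataset = PairedDataset(
        genes=ExpressionMatrix(genes_df),
        mirnas=ExpressionMatrix(mirnas_df),
        clinical=clinical,
        scores=scores,
    )
    truth = {
        "planted_pairs": [(r.mirna, r.gene) for r in cfg.planted_regulations],
        "planted_effects": {(r.mirna, r.gene): r.effect
                            for r in cfg.planted_regulations},
        "prognostic_features": dict(cfg.survival.log_hrs),
        "predictive_features": dict(cfg.class_effects),
        "score_mirna": cfg.score_mirna,
        "config": cfg,
    }
    return SimulatedCohort(dataset=dataset, evidence=evidence, sl_pairs=sl_pairs,
                           essential_genes=essential, labels=labels,
                           gene_sets=gene_sets, truth=truth)


def write_fixtures(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the TSV/GMT files the readers and CLI accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "mirnas": out / "mirnas.tsv",
        "clinical": out / "clinical.tsv",
        "scores": out / "scores.tsv",
        "evidence": out / "evidence.tsv",
        "sl_pairs": out / "sl_pairs.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "essential": out / "essential_genes.txt",
    }
    write_expression_matrix(cohort.dataset.genes, paths["genes"])
    write_expression_matrix(cohort.dataset.mirnas, paths["mirnas"])
    write_clinical_table(cohort.dataset.clinical, paths["clinical"])
    write_scores(cohort.dataset.scores, paths["scores"])
    write_evidence_matrix(cohort.evidence, paths["evidence"])
    write_sl_pairs(cohort.sl_pairs, paths["sl_pairs"])
    write_gene_sets(cohort.gene_sets, paths["gene_sets"])
    with open(paths["essential"], "w") as fh:
        for g in sorted(cohort.essential_genes):
            fh.write(g + "\n")
    return paths
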