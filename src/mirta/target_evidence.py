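"""Consensus target-prediction evidence layer.

miRNA-target calls from 40 prediction tools (5 of which are
experimental-evidence databases) are consumed as a boolean evidence matrix:
one row per (miRNA, gene) pair, one 0/1 column per tool. The *support count*
of a pair is the number of tools predicting it; a consensus filter (e.g. at
least 5 of 40 tools) separates likely direct interactions from noise. The
layer also provides gene-set over-representation of a miRNA's targets and a
synthetic-lethal lookup: miRNAs targeting the partner gene of a synthetic
lethal pair whose other member is (therapy-)essential point at therapeutic
vulnerabilities.

Tool identities are schema metadata loaded with the matrix file; only the
counts (exactly 40 tools, exactly 5 experimental) are validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, FormatError, ValidationError
from .io_core import GeneSet

logger = logging.getLogger(__name__)

#: Number of target-prediction tools in the evidence compendium.
N_TOOLS = 40
#: Number of experimental-evidence sources among the tools.
N_EXPERIMENTAL = 5


@dataclass
class TargetEvidenceMatrix:
    """Boolean (miRNA, gene) x 40-tool evidence matrix.

    ``table`` is indexed by a unique (mirna, gene) MultiIndex with exactly 40
    boolean tool columns; ``experimental`` names the 5 experimental-evidence
    columns. Pairs absent from the table have support 0.
    """

    table: pd.DataFrame
    experimental: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.table.shape[1] != N_TOOLS:
            raise ValidationError(
                f"evidence matrix must have exactly {N_TOOLS} tool columns, "
                f"got {self.table.shape[1]}"
            )
        self.experimental = tuple(self.experimental)
        if len(set(self.experimental)) != N_EXPERIMENTAL:
            raise ValidationError(
                f"exactly {N_EXPERIMENTAL} distinct experimental columns required, "
                f"got {len(set(self.experimental))}"
            )
        missing = set(self.experimental) - set(self.table.columns)
        if missing:
            raise ValidationError(f"experimental columns not in matrix: {sorted(missing)}")
        if self.table.index.nlevels != 2:
            raise ValidationError("evidence index must be (mirna, gene) pairs")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate (mirna, gene) pairs in evidence matrix")
        self.table = self.table.astype(bool)
        self.table.index = self.table.index.set_names(["mirna", "gene"])

    @property
    def tools(self) -> list[str]:
        return list(self.table.columns)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.table.index)

    def support_series(self) -> pd.Series:
        """Support count for every pair in the matrix."""
        return self.table.sum(axis=1).astype(int)

    def support(self, mirna: str, gene: str) -> int:
        """Number of tools predicting (mirna, gene); 0 when the pair is absent."""
        try:
            return int(self.table.loc[(mirna, gene)].sum())
        except KeyError:
            return 0

    def has_experimental(self, mirna: str, gene: str) -> bool:
        try:
            return bool(self.table.loc[(mirna, gene), list(self.experimental)].any())
        except KeyError:
            return False

    def genes_with_evidence(self, mirna: str) -> set[str]:
        """Genes with at least one supporting tool for ``mirna``."""
        if mirna not in self.table.index.get_level_values("mirna"):
            return set()
        sub = self.table.xs(mirna, level="mirna")
        return set(sub.index[sub.any(axis=1)])


def support_count(ev: TargetEvidenceMatrix, mirna: str, gene: str) -> int:
    """Support count of a pair (0 when absent). Thin alias of ``ev.support``."""
    return ev.support(mirna, gene)


def consensus_filter(
    ev: TargetEvidenceMatrix,
    min_tools: int,
    require_experimental: bool = False,
) -> set[tuple[str, str]]:
    """Pairs supported by at least ``min_tools`` of the 40 tools.

    With ``require_experimental``, at least one of the 5 experimental-evidence
    columns must additionally be TRUE.
    """
    if not 0 <= min_tools <= N_TOOLS:
        raise ValidationError(f"min_tools must be in [0, {N_TOOLS}], got {min_tools}")
    keep = ev.support_series() >= min_tools
    if require_experimental:
        keep &= ev.table[list(ev.experimental)].any(axis=1)
    return set(ev.table.index[keep])


def query_targets(ev: TargetEvidenceMatrix, mirna: str, min_tools: int,
                  require_experimental: bool = False) -> list[str]:
    """Sorted genes targeted by ``mirna`` at the consensus threshold."""
    pairs = consensus_filter(ev, min_tools, require_experimental)
    return sorted(g for m, g in pairs if m == mirna)


def query_mirnas(ev: TargetEvidenceMatrix, gene: str, min_tools: int,
                 require_experimental: bool = False) -> list[str]:
    """Sorted miRNAs targeting ``gene`` at the consensus threshold."""
    pairs = consensus_filter(ev, min_tools, require_experimental)
    return sorted(m for m, g in pairs if g == gene)


class OverRepresentation(NamedTuple):
    overlap: int
    p_value: float
    odds_ratio: float


def over_representation(
    target_genes: Iterable[str],
    gene_set: GeneSet,
    universe: Iterable[str],
) -> OverRepresentation:
    """One-sided hypergeometric over-representation of a gene set in targets.

    P(X >= overlap) with population = |universe|, successes = members of the
    set inside the universe, draws = target genes inside the universe. Members
    outside the universe are dropped with a warning. The odds ratio comes from
    the 2x2 table with a Haldane +0.5 correction when any cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise AnalysisError("over-representation universe is empty")
    members = gene_set.members & universe
    outside = len(gene_set.members) - len(members)
    if outside:
        logger.warning("gene set %r: %d members outside the universe dropped",
                       gene_set.name, outside)
    targets = set(target_genes) & universe
    overlap = len(targets & members)

    M, K, n = len(universe), len(members), len(targets)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, n))

    a = overlap
    b = n - overlap
    c = K - overlap
    d = M - K - n + overlap
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return OverRepresentation(overlap=overlap, p_value=min(p, 1.0), odds_ratio=float(odds))


@dataclass(frozen=True)
class SLPairList:
    """Unordered synthetic-lethal gene pairs (no self-pairs, unique)."""

    pairs: frozenset[tuple[str, str]]  # each stored sorted

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-pair {a!r} in synthetic-lethal list")
            if a > b:
                raise ValidationError("SL pairs must be stored in sorted order")

    @classmethod
    def from_iterable(cls, pairs: Iterable[tuple[str, str]]) -> "SLPairList":
        clean: set[tuple[str, str]] = set()
        n_self = 0
        for a, b in pairs:
            if a == b:
                n_self += 1
                continue
            clean.add((min(a, b), max(a, b)))
        if n_self:
            logger.warning("dropped %d self-pairs from synthetic-lethal list", n_self)
        return cls(frozenset(clean))

    def partners(self, gene: str) -> set[str]:
        return {b if a == gene else a for a, b in self.pairs if gene in (a, b)}


def read_sl_pairs(path: str | Path) -> SLPairList:
    """Read a two-column TSV of synthetic-lethal gene pairs (header optional)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated genes")
            if lineno == 1 and fields[:2] in (["gene_a", "gene_b"], ["gene1", "gene2"]):
                continue
            pairs.append((fields[0], fields[1]))
    return SLPairList.from_iterable(pairs)


def write_sl_pairs(sl: SLPairList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(sl.pairs):
            fh.write(f"{a}\t{b}\n")


class SLTarget(NamedTuple):
    mirna: str
    sl_gene: str
    essential_partner: str
    support: int


def synthetic_lethal_targets(
    ev: TargetEvidenceMatrix,
    sl: SLPairList,
    essential_genes: Iterable[str],
    min_tools: int,
) -> list[SLTarget]:
    """miRNAs targeting the synthetic-lethal partner of an essential gene.

    For every SL pair (a, b) with a essential, every miRNA targeting b at
    support >= ``min_tools`` yields a record (and symmetrically for b
    essential). Records are deduplicated and sorted by support descending,
    then by (mirna, sl_gene, essential_partner).
    """
    essential = set(essential_genes)
    consensus = consensus_filter(ev, min_tools)
    by_gene: dict[str, list[str]] = {}
    for m, g in consensus:
        by_gene.setdefault(g, []).append(m)
    records: set[SLTarget] = set()
    for a, b in sl.pairs:
        for ess, target in ((a, b), (b, a)):
            if ess not in essential:
                continue
            for m in by_gene.get(target, ()):
                records.add(SLTarget(m, target, ess, ev.support(m, target)))
    return sorted(records, key=lambda r: (-r.support, r.mirna, r.sl_gene,
                                          r.essential_partner))


# ---------------------------------------------------------------------------
# TSV round trip

_EXP_HEADER = "#experimental:"


def read_evidence_matrix(path: str | Path) -> TargetEvidenceMatrix:
    """Read an evidence TSV: ``#experimental:`` comment line naming the 5
    experimental columns, then a header ``mirna TAB gene TAB <40 tools>`` and
    0/1 rows."""
    path = Path(path)
    experimental: tuple[str, ...] | None = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith(_EXP_HEADER):
                experimental = tuple(t.strip() for t in
                                     line[len(_EXP_HEADER):].strip().split(","))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if experimental is None:
        raise FormatError(f"{path}: missing '{_EXP_HEADER}' metadata line")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["mirna", "gene"]:
        raise FormatError(f"{path}: evidence header must start 'mirna\\tgene'")
    table = df.set_index(["mirna", "gene"]).astype(bool)
    return TargetEvidenceMatrix(table, experimental)


def write_evidence_matrix(ev: TargetEvidenceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_EXP_HEADER + " " + ",".join(ev.experimental) + "\n")
        ev.table.astype(int).sort_index().to_csv(fh, sep="\t")
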