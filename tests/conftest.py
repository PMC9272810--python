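"""Shared fixtures: small seeded cohorts and evidence-matrix builders."""

import numpy as np
import pandas as pd
import pytest

from mirta import synthetic_data as sd
from mirta.io_core import ExpressionMatrix
from mirta.target_evidence import N_TOOLS, TargetEvidenceMatrix

TOOLS = list(sd.TOOL_NAMES)
EXPERIMENTAL = list(sd.EXPERIMENTAL_NAMES)


def make_evidence(supports: dict[tuple[str, str], int],
                  experimental_true: set[tuple[str, str]] | None = None,
                  seed: int = 0) -> TargetEvidenceMatrix:
    """Evidence matrix with the requested support count per pair.

    Tool columns are chosen deterministically (first ``s`` prediction tools);
    pairs in ``experimental_true`` get their last supporting column swapped to
    an experimental source.
    """
    experimental_true = experimental_true or set()
    rows = {}
    for pair, s in supports.items():
        row = np.zeros(N_TOOLS, dtype=bool)
        row[:s] = True
        if pair in experimental_true and s > 0:
            row[s - 1] = False
            row[N_TOOLS - 1] = True
        rows[pair] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=TOOLS)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["mirna", "gene"])
    return TargetEvidenceMatrix(table, tuple(EXPERIMENTAL))


def expr(values, features=None, samples=None, scale="log2") -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples),
                            scale)


@pytest.fixture(scope="session")
def cohort() -> sd.SimulatedCohort:
    """Default synthetic cohort: 200 samples, 3 planted regulations at -0.8."""
    return sd.simulate(sd.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> sd.SimulatedCohort:
    """Small cohort for fast end-to-end tests."""
    return sd.simulate(sd.SimulationConfig(seed=5, n_samples=60, n_genes=80,
                                           n_mirnas=8, n_planted=2))
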