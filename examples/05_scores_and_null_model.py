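"""Immune-score association, per-patient gene-set targeting, empirical null.

The synthetic cohort carries an immunophenoscore-like vector built as a noisy
negative transform of one miRNA. This script (1) associates every miRNA with
that score, (2) computes a per-patient gene-set targeting score weighted by
prediction-tool support, and (3) calibrates an observed correlation against
the empirical null of 1000 zero-evidence genes.
"""

from mirta import simulate
from mirta.association import (
    build_null, correlate_pair, empirical_p, geneset_target_score,
    score_association,
)
from mirta.synthetic_data import SimulationConfig

cohort = simulate(SimulationConfig(seed=23, n_samples=150, n_genes=1200,
                                   n_mirnas=15))
ds = cohort.dataset

out = score_association(ds, ds.mirnas.feature_ids, "ips_like")
print("strongest miRNA ~ immune-score associations:")
print(out.reindex(out["r"].abs().sort_values(ascending=False).index)
      .head(3).round(3).to_string(index=False))
print(f"(score was built from {cohort.truth['score_mirna']})")

mirna, gene = cohort.truth["planted_pairs"][0]
planted_set = next(s for s in cohort.gene_sets if s.name == "PLANTED_TARGETS")
score, weights = geneset_target_score(ds, mirna, planted_set, cohort.evidence)
r, _ = correlate_pair(ds.mirnas.data.loc[mirna], score)
print(f"\nper-patient targeting score of {mirna} over {planted_set.name}: "
      f"correlation with the miRNA itself r = {r:.2f}")
print(weights.to_string(index=False))

null = build_null(ds, mirna, cohort.evidence, n_null=1000, seed=5)
obs, _ = correlate_pair(ds.mirnas.data.loc[mirna], ds.genes.data.loc[gene])
p_emp = empirical_p(null, obs, tail="negative")
print(f"\nobserved r({mirna}, {gene}) = {obs:.3f}; empirical p against "
      f"{len(null.sampled_genes)} zero-evidence genes = {p_emp:.4g}")
print("A tiny empirical p says the observed anti-correlation is far below"
      "\nanything this miRNA shows against random unpredicted genes.")
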