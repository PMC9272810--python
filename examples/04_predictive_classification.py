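"""Predictive biomarkers between two clinical groups + classification.

The synthetic cohort shifts one miRNA by 3 log2 units in one of two balanced
patient groups. Feature selection (AdaBoost, random forest, L1 logistic
across stratified 5-fold CV) should find it; a random-forest classifier on
the selected features is then evaluated by cross-validated ROC and PCA.
"""

from mirta import simulate
from mirta.classify import select_predictive, train_and_cv
from mirta.synthetic_data import SimulationConfig

cohort = simulate(SimulationConfig(seed=19, n_samples=160, n_mirnas=30))
planted = next(iter(cohort.truth["predictive_features"]))
X = cohort.dataset.mirnas.data.T  # samples x miRNAs
y = cohort.labels

ranking = select_predictive(X, y, k=5, top_n=10, seed=4)
print("top predictive candidates:")
print(ranking.table.head(5)[["feature_id", "presence"]].to_string(index=False))
print(f"(planted group marker: {planted})")

report = train_and_cv(X, y, ranking.top(10), model="random_forest", k=5, seed=4)
print(f"\nrandom forest, 5-fold CV: mean AUC = {report.mean_auc:.3f} "
      f"+/- {report.sd_auc:.3f} (pooled AUC = {report.pooled_auc:.3f})")
print(f"confusion matrix at p=0.5:\n{report.confusion}")
print(f"PCA explained variance: PC1 {report.pca_explained_variance[0]:.2f}, "
      f"PC2 {report.pca_explained_variance[1]:.2f}")
print("\nAUC near 1 means the selected miRNAs separate the two clinical"
      "\ngroups almost perfectly in held-out folds.")
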