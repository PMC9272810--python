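"""Correlation, regression, voting, empirical null and gene-set scores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirta import synthetic_data as sd
from mirta.association import (
    NullModel, add_regression, association_frame, build_null, correlate_all,
    correlate_pair, distance_correlation, empirical_p, geneset_target_score,
    regularized_fit, score_association, vote_rank,
)
from mirta.exceptions import AnalysisError, ValidationError
from mirta.io_core import GeneSet

from conftest import make_evidence


# ---------------------------------------------------------------------------
# definitional oracles


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def rank_oracle(v):
    out = []
    for a in v:
        less = sum(1 for b in v if b < a)
        equal = sum(1 for b in v if b == a)
        out.append(less + (equal + 1) / 2)
    return out


def kendall_oracle(x, y):
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    return (conc - disc) / math.sqrt((conc + disc + tx) * (conc + disc + ty))


def dcor_oracle(x, y):
    """Distance correlation by explicit double loops (no vectorization)."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        rows = [sum(r) / n for r in m]
        cols = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        tot = sum(rows) / n
        return [[m[i][j] - rows[i] - cols[j] + tot for j in range(n)]
                for i in range(n)]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    vx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    vy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(vx * vy))


class TestCorrelatePair:
    def test_identity_and_affine(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        assert correlate_pair(x, x, "pearson")[0] == pytest.approx(1.0)
        assert correlate_pair(x, x, "spearman")[0] == pytest.approx(1.0)
        assert correlate_pair(x, -2 * x + 3, "pearson")[0] == pytest.approx(-1.0)

    def test_kendall_matches_pair_counting(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        r, _ = correlate_pair(x, y, "kendall")
        assert r == pytest.approx(kendall_oracle(x, y))

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall", "distance"])
    def test_definitional_oracles_length_six(self, method):
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = list(rng.normal(size=6))
            y = list(rng.normal(size=6))
            r, _ = correlate_pair(x, y, method)
            if method == "pearson":
                expected = pearson_oracle(x, y)
            elif method == "spearman":
                expected = pearson_oracle(rank_oracle(x), rank_oracle(y))
            elif method == "kendall":
                expected = kendall_oracle(x, y)
            else:
                expected = dcor_oracle(x, y)
            assert r == pytest.approx(expected, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalysisError, match="zero-variance"):
            correlate_pair([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(AnalysisError, match=">=4"):
            correlate_pair([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValidationError):
            correlate_pair([1, 2, 3, 4], [4, 3, 2, 1], "mystery")

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1, 2, 3, 4, np.nan, 6.0])
        y = np.array([2, 4, 6, 8, 10, np.nan])
        r, _ = correlate_pair(x, y, "pearson")
        assert r == pytest.approx(1.0)

    def test_distance_permutation_p_seeded(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        p1 = correlate_pair(x, y, "distance", seed=3)[1]
        p2 = correlate_pair(x, y, "distance", seed=3)[1]
        assert p1 == p2


class TestCorrelateAll:
    def test_single_pair_q_equals_p(self, small_cohort):
        ds = small_cohort.dataset
        res = correlate_all(ds, ds.mirnas.feature_ids[:1], ds.genes.feature_ids[:1])
        assert len(res) == 1
        assert res[0].q_pearson == pytest.approx(res[0].p_pearson)

    def test_planted_pair_most_negative(self, cohort):
        ds = cohort.dataset
        m, g = cohort.truth["planted_pairs"][0]
        genes = [g] + [x for x in ds.genes.feature_ids if x not in
                       {p[1] for p in cohort.truth["planted_pairs"]}][:50]
        res = correlate_all(ds, [m], genes, cohort.evidence)
        best = min(res, key=lambda r: r.r_pearson)
        assert (best.mirna, best.gene) == (m, g)
        assert best.support == 7

    def test_pair_count_complete(self, small_cohort):
        ds = small_cohort.dataset
        res = correlate_all(ds, ds.mirnas.feature_ids[:3], ds.genes.feature_ids[:7])
        assert len(res) == 21

    def test_empty_lists_rejected(self, small_cohort):
        with pytest.raises(AnalysisError):
            correlate_all(small_cohort.dataset, [], ["GENE0001"])


class TestRegularizedFit:
    @staticmethod
    def _planted_ds(n=200, seed=0):
        cfg = sd.SimulationConfig(seed=seed, n_samples=n, n_genes=20, n_mirnas=10,
                                  planted_regulations=(
                                      sd.PlantedRegulation(sd.mirna_name(0),
                                                           sd.gene_name(0), -0.9),),
                                  noise_sd=0.1)
        return sd.simulate(cfg).dataset

    def test_lasso_recovers_planted_regulator(self):
        ds = self._planted_ds()
        mirnas = [sd.mirna_name(i) for i in range(10)]
        coefs = regularized_fit(ds, sd.gene_name(0), mirnas, model="lasso", seed=1)
        planted = coefs[sd.mirna_name(0)]
        assert planted < 0
        assert all(abs(planted) > abs(c) for m, c in coefs.items()
                   if m != sd.mirna_name(0))

    def test_ridge_infinite_penalty_shrinks_to_zero(self):
        ds = self._planted_ds()
        coefs = regularized_fit(ds, sd.gene_name(0),
                                [sd.mirna_name(i) for i in range(5)],
                                model="ridge", alpha=1e9)
        assert all(abs(c) < 1e-4 for c in coefs.values())

    def test_ridge_symmetry_for_duplicate_predictors(self):
        ds = self._planted_ds()
        # duplicate the planted miRNA under a second name
        dup = ds.mirnas.data.loc[sd.mirna_name(0)].copy()
        ds.mirnas.data.loc["dup-miR"] = dup
        coefs = regularized_fit(ds, sd.gene_name(0), [sd.mirna_name(0), "dup-miR"],
                                model="ridge", alpha=1.0)
        assert coefs[sd.mirna_name(0)] == pytest.approx(coefs["dup-miR"], abs=1e-8)

    def test_constant_response_rejected(self):
        ds = self._planted_ds()
        ds.genes.data.loc[sd.gene_name(1)] = 3.0
        with pytest.raises(AnalysisError):
            regularized_fit(ds, sd.gene_name(1), [sd.mirna_name(0)])

    def test_enet_fills_results(self, small_cohort):
        ds = small_cohort.dataset
        res = correlate_all(ds, ds.mirnas.feature_ids[:3], ds.genes.feature_ids[:4])
        add_regression(res, ds, models=("enet",), seed=0)
        assert all(r.coef_enet is not None for r in res)


def borda_oracle(values_by_method, keys):
    """Brute-force Borda: per-method average ranks (ascending), mean, then
    order by (score, key)."""
    n = len(keys)
    scores = [0.0] * n
    for vals in values_by_method:
        ranks = []
        for i in range(n):
            less = sum(1 for v in vals if v < vals[i])
            equal = sum(1 for v in vals if v == vals[i])
            ranks.append(less + (equal + 1) / 2)
        scores = [s + r / len(values_by_method) for s, r in zip(scores, ranks)]
    order = sorted(range(n), key=lambda i: (scores[i], keys[i]))
    ranks_out = [0] * n
    for pos, i in enumerate(order):
        ranks_out[i] = pos + 1
    return scores, ranks_out


def _results_from(values_by_method, methods):
    from mirta.association import AssociationResult, _METHOD_ATTR
    n = len(values_by_method[0])
    results = [AssociationResult(mirna=f"m{i}", gene=f"g{i}") for i in range(n)]
    for method, vals in zip(methods, values_by_method):
        for r, v in zip(results, vals):
            setattr(r, _METHOD_ATTR[method], v)
    return results


class TestVoteRank:
    def test_single_method_equals_method_rank(self):
        res = _results_from([[-0.9, -0.1, -0.5]], ["pearson"])
        vote_rank(res, ["pearson"])
        assert [r.vote_rank for r in res] == [1, 3, 2]

    def test_hand_borda_two_methods(self):
        # per-method ranks {(1,2),(2,1),(3,3)} -> scores {1.5,1.5,3}
        res = _results_from([[-0.9, -0.5, -0.1], [-0.5, -0.9, -0.1]],
                            ["pearson", "spearman"])
        vote_rank(res, ["pearson", "spearman"])
        assert [r.vote_score for r in res] == [1.5, 1.5, 3.0]
        assert [r.vote_rank for r in res] == [1, 2, 3]  # id tie-break

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        res = _results_from([list(rng.normal(size=8)), list(rng.normal(size=8))],
                            ["pearson", "lasso"])
        vote_rank(res, ["pearson", "lasso"])
        by_pair = {(r.mirna, r.gene): r.vote_rank for r in res}
        shuffled = list(rng.permutation(res))
        for r in shuffled:
            r.vote_score = r.vote_rank = None
        vote_rank(shuffled, ["pearson", "lasso"])
        assert {(r.mirna, r.gene): r.vote_rank for r in shuffled} == by_pair

    def test_matches_borda_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            vals = [list(rng.choice([-0.8, -0.5, -0.2, 0.1], size=10)),
                    list(rng.normal(size=10))]
            res = _results_from(vals, ["pearson", "spearman"])
            vote_rank(res, ["pearson", "spearman"])
            scores, ranks = borda_oracle(
                vals, [(r.mirna, r.gene) for r in res])
            assert [r.vote_score for r in res] == pytest.approx(scores)
            assert [r.vote_rank for r in res] == ranks

    def test_missing_method_value_reported(self):
        res = _results_from([[-0.5, -0.1]], ["pearson"])
        with pytest.raises(AnalysisError, match="spearman"):
            vote_rank(res, ["pearson", "spearman"])


class TestNullModel:
    def test_no_zero_evidence_pool_rejected(self, small_cohort):
        ds = small_cohort.dataset
        m = ds.mirnas.feature_ids[0]
        supports = {(m, g): 3 for g in ds.genes.feature_ids}
        ev = make_evidence(supports)
        with pytest.raises(AnalysisError, match="zero-evidence"):
            build_null(ds, m, ev, n_null=100)

    def test_seed_reproducibility(self, cohort):
        ds, ev = cohort.dataset, cohort.evidence
        m = ds.mirnas.feature_ids[0]
        a = build_null(ds, m, ev, n_null=100, seed=5)
        b = build_null(ds, m, ev, n_null=100, seed=5)
        assert a.sampled_genes == b.sampled_genes
        np.testing.assert_array_equal(a.null_correlations, b.null_correlations)

    def test_sampled_genes_have_no_evidence(self, cohort):
        ds, ev = cohort.dataset, cohort.evidence
        m = ds.mirnas.feature_ids[0]
        null = build_null(ds, m, ev, n_null=100, seed=1)
        assert all(ev.support(m, g) == 0 for g in null.sampled_genes)

    def test_independent_mirna_null_centered(self, cohort):
        ds, ev = cohort.dataset, cohort.evidence
        m = ds.mirnas.feature_ids[-1]  # no planted regulation
        null = build_null(ds, m, ev, n_null=300, seed=2)
        assert abs(null.null_correlations.mean()) < 3 / np.sqrt(300)


class TestEmpiricalP:
    def test_add_one_floor(self):
        nulls = np.linspace(-0.5, 0.5, 1000)
        assert empirical_p(nulls, -0.99) == pytest.approx(1 / 1001)

    def test_upper_bound_one(self):
        nulls = np.linspace(-0.9, 0.9, 200)
        assert empirical_p(nulls, 1.0) == pytest.approx(1.0)

    def test_hand_count(self):
        assert empirical_p(np.array([-0.5, -0.1, 0.2, 0.4]), -0.2) \
            == pytest.approx(2 / 5)

    def test_positive_tail_mirrors(self):
        nulls = np.array([-0.5, -0.1, 0.2, 0.4])
        assert empirical_p(nulls, 0.3, tail="positive") == pytest.approx(2 / 5)


class TestScoreAssociation:
    def test_score_equal_to_mirna_expression(self, small_cohort):
        ds = small_cohort.dataset
        m = ds.mirnas.feature_ids[0]
        ds.scores["self"] = ds.mirnas.data.loc[m].copy()
        out = score_association(ds, ds.mirnas.feature_ids, "self")
        assert out.set_index("mirna").loc[m, "r"] == pytest.approx(1.0)

    def test_planted_score_mirna_ranks_first(self, cohort):
        ds = cohort.dataset
        out = score_association(ds, ds.mirnas.feature_ids, "ips_like")
        top = out.loc[out["r"].abs().idxmax(), "mirna"]
        assert top == cohort.truth["score_mirna"]
        assert out.set_index("mirna").loc[top, "r"] < 0

    def test_q_monotone_in_p(self, cohort):
        out = score_association(cohort.dataset, cohort.dataset.mirnas.feature_ids,
                                "ips_like").sort_values("p")
        assert (np.diff(out["q"].to_numpy()) >= -1e-12).all()

    def test_unknown_score_rejected(self, small_cohort):
        with pytest.raises(AnalysisError, match="unknown score"):
            score_association(small_cohort.dataset, ["hsa-miR-sim1-5p"], "nope")


class TestGenesetTargetScore:
    @staticmethod
    def _tiny_ds():
        from conftest import expr
        from mirta.io_core import PairedDataset
        genes = expr([[1.0, 2, 3, 4], [4, 3, 2, 1]], features=["G1", "G2"],
                     samples=list("ABCD"))
        mirnas = expr([[5.0, 5, 6, 6]], features=["miR-1"], samples=list("ABCD"))
        return PairedDataset(genes=genes, mirnas=mirnas)

    def test_zero_support_gives_zero_scores(self):
        ds = self._tiny_ds()
        ev = make_evidence({("miR-1", "OTHER"): 6})
        gs = GeneSet("S", "", frozenset({"G1", "G2"}))
        score, _ = geneset_target_score(ds, "miR-1", gs, ev)
        assert np.allclose(score.to_numpy(), 0.0)

    def test_full_support_single_gene_equals_zscore(self):
        ds = self._tiny_ds()
        ev = make_evidence({("miR-1", "G1"): 40})
        gs = GeneSet("S", "", frozenset({"G1"}))
        score, _ = geneset_target_score(ds, "miR-1", gs, ev)
        g = ds.genes.data.loc["G1"]
        z = (g - g.mean()) / g.std(ddof=0)
        np.testing.assert_allclose(score.to_numpy(), z.to_numpy())

    def test_two_gene_hand_arithmetic(self):
        ds = self._tiny_ds()
        ev = make_evidence({("miR-1", "G1"): 20, ("miR-1", "G2"): 40})
        gs = GeneSet("S", "", frozenset({"G1", "G2"}))
        score, weights = geneset_target_score(ds, "miR-1", gs, ev)
        z = ds.genes.data.sub(ds.genes.data.mean(axis=1), axis=0) \
            .div(ds.genes.data.std(axis=1, ddof=0), axis=0)
        expected = 0.5 * z.loc["G1"] + 1.0 * z.loc["G2"]
        np.testing.assert_allclose(score.to_numpy(), expected.to_numpy())
        assert set(weights["weight"]) == {0.5, 1.0}

    def test_linear_in_weights(self):
        ds = self._tiny_ds()
        gs = GeneSet("S", "", frozenset({"G1", "G2"}))
        half, _ = geneset_target_score(ds, "miR-1", gs,
                                       make_evidence({("miR-1", "G1"): 10,
                                                      ("miR-1", "G2"): 20}))
        full, _ = geneset_target_score(ds, "miR-1", gs,
                                       make_evidence({("miR-1", "G1"): 20,
                                                      ("miR-1", "G2"): 40}))
        np.testing.assert_allclose(2 * half.to_numpy(), full.to_numpy())

    def test_empty_intersection_rejected(self):
        ds = self._tiny_ds()
        ev = make_evidence({("miR-1", "G1"): 5})
        with pytest.raises(AnalysisError):
            geneset_target_score(ds, "miR-1", GeneSet("S", "", frozenset({"X"})), ev)
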