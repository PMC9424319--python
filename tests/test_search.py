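import numpy as np
import pytest

import sigforge as sf
from sigforge.exceptions import ValidationError

from oracles import brute_tsp_delta


def _alt(calls, genes=None, samples=None):
    calls = np.asarray(calls)
    genes = genes or [f"g{i}" for i in range(calls.shape[0])]
    samples = samples or [f"s{i}" for i in range(calls.shape[1])]
    return sf.AlterationMatrix(genes, samples, calls)


class TestSingleGeneSignificance:
    def test_planted_gene_is_prognostic(self):
        cfg = sf.CohortConfig(seed=21, n_tumor=200)
        expr, clin, truth = sf.simulate_cohort(cfg)
        a = sf.call_alterations(sf.zscore_vs_reference(expr))
        table = sf.single_gene_significance(a, clin).set_index("gene")
        planted = table.loc[truth.prognostic_genes[0]]
        assert planted["testable"]
        assert planted["hr"] > 1
        assert planted["logrank_p"] < 0.05

    def test_all_altered_gene_flagged_untestable(self, simple_clinical):
        a = _alt([[1] * 8, [1, 0, 0, 1, 0, 1, 0, 1]], samples=simple_clinical.sample_ids)
        table = sf.single_gene_significance(a, simple_clinical).set_index("gene")
        assert not table.loc["g0", "testable"]
        assert table.loc["g1", "testable"]

    def test_null_pvalues_roughly_uniform(self):
        """Permuted alteration labels give a flat p-value distribution."""
        from scipy import stats

        ps = []
        for r in range(300):
            rng = np.random.default_rng(r)
            n = 120
            status = np.zeros(n, dtype=int)
            status[: n // 4] = 1
            rng.shuffle(status)
            te = rng.exponential(80, n)
            tc = np.minimum(rng.exponential(200, n), 240)
            t, e = np.minimum(te, tc), (te <= tc).astype(int)
            clin = sf.ClinicalTable([f"s{i}" for i in range(n)], t, e)
            a = _alt(status[None, :], genes=["g"], samples=clin.sample_ids)
            table = sf.single_gene_significance(a, clin)
            ps.append(table["logrank_p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSGR:
    def test_single_step_to_target(self, simple_clinical):
        rng = np.random.default_rng(0)
        a = _alt(rng.integers(0, 2, (2, 8)), samples=simple_clinical.sample_ids)
        trace = sf.sgr_refine(a, simple_clinical, sf.GeneSignature("s", ["g0", "g1"]), 1)
        assert len(trace.steps) == 1
        assert len(trace.final_signature) == 1

    def test_trace_is_deterministic(self, demo_cohort):
        expr, clin, _ = demo_cohort
        a = sf.call_alterations(sf.zscore_vs_reference(expr))
        sig = sf.GeneSignature("all", list(a.gene_ids))
        t1 = sf.sgr_refine(a, clin, sig, 3)
        t2 = sf.sgr_refine(a, clin, sig, 3)
        assert t1.as_dict() == t2.as_dict()

    def test_constant_candidate_scores_p_one(self, simple_clinical):
        # removing g1 leaves g0 which is altered everywhere -> p = 1 candidate
        a = _alt([[1] * 8, [1, 0, 1, 0, 1, 0, 1, 0]], samples=simple_clinical.sample_ids)
        trace = sf.sgr_refine(a, simple_clinical, sf.GeneSignature("s", ["g0", "g1"]), 1)
        assert trace.steps[0].logrank_p <= 1.0

    def test_all_censored_cohort_rejected(self):
        clin = sf.ClinicalTable(["s0", "s1", "s2", "s3"], [1.0, 2, 3, 4], [0, 0, 0, 0])
        a = _alt([[1, 0, 1, 0], [0, 1, 0, 1]], samples=clin.sample_ids)
        with pytest.raises(ValidationError):
            sf.sgr_refine(a, clin, sf.GeneSignature("s", ["g0", "g1"]), 1)

    def test_no_improvement_rule_stops_early(self, demo_cohort):
        expr, clin, _ = demo_cohort
        a = sf.call_alterations(sf.zscore_vs_reference(expr))
        sig = sf.GeneSignature("all", list(a.gene_ids))
        trace = sf.sgr_refine(a, clin, sig, stop_rule="no-improvement")
        ps = [trace.start_p] + [s.logrank_p for s in trace.steps]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_invalid_target_rejected(self, simple_clinical):
        a = _alt(np.zeros((2, 8), int), samples=simple_clinical.sample_ids)
        with pytest.raises(ValidationError):
            sf.sgr_refine(a, simple_clinical, sf.GeneSignature("s", ["g0", "g1"]), 5)

    def test_null_shows_no_systematic_gene_preference(self):
        """With no planted effect every gene should reach the final set at
        roughly the same frequency (3 of 10 survive)."""
        counts = {f"G{i + 1:03d}": 0 for i in range(10)}
        reps = 40
        for seed in range(reps):
            cfg = sf.CohortConfig(seed=seed, effect_beta={}, prognostic_genes=[])
            expr, clin, _ = sf.simulate_cohort(cfg)
            a = sf.call_alterations(sf.zscore_vs_reference(expr))
            tr = sf.sgr_refine(a, clin, sf.GeneSignature("all", list(a.gene_ids)), 3)
            for g in tr.final_signature.genes:
                counts[g] += 1
        freqs = np.array(list(counts.values())) / reps
        # expected 0.3 each; allow generous binomial slack
        assert (np.abs(freqs - 0.3) < 4 * np.sqrt(0.3 * 0.7 / reps)).all()


class TestKTSP:
    def test_perfect_flip_scores_delta_one(self):
        X = np.array([[0.0, 0, 1, 1], [1.0, 1, 0, 0]])
        z = sf.ExpressionMatrix(["a", "b"], list("wxyz"), X)
        labels = np.array([1, 1, 0, 0])
        (pair,) = sf.ktsp_score_pairs(z, labels)
        assert pair.delta == 1.0
        assert pair.less_predicts_class1  # a < b in class 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n, G = int(rng.integers(4, 21)), int(rng.integers(2, 7))
            X = rng.integers(0, 5, (G, n)).astype(float)  # many within-sample ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            z = sf.ExpressionMatrix(
                [f"g{i}" for i in range(G)], [f"s{i}" for i in range(n)], X
            )
            got = {(p.gene_i, p.gene_j): p.delta for p in sf.ktsp_score_pairs(z, labels)}
            for i in range(G):
                for j in range(i + 1, G):
                    want, _, _ = brute_tsp_delta(X, labels, i, j)
                    assert got[(f"g{i}", f"g{j}")] == pytest.approx(want)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((4, 12))
        labels = np.array([1, 0] * 6)
        z1 = sf.ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{i}" for i in range(12)], X)
        X2 = X.copy()
        X2[:, 3] = np.exp(X2[:, 3])  # strictly increasing transform of one sample
        z2 = sf.ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{i}" for i in range(12)], X2)
        d1 = [p.delta for p in sf.ktsp_score_pairs(z1, labels)]
        d2 = [p.delta for p in sf.ktsp_score_pairs(z2, labels)]
        np.testing.assert_allclose(d1, d2)

    def test_single_class_rejected(self):
        z = sf.ExpressionMatrix(["a", "b"], ["s1", "s2"], np.eye(2))
        with pytest.raises(ValidationError):
            sf.ktsp_score_pairs(z, [1, 1])

    def test_select_disjoint_pairs(self):
        mk = lambda i, j, d: sf.TSPPairScore(i, j, d, 0.0, 1.0, 1.0 - d)
        scores = [mk("a", "b", 0.9), mk("a", "c", 0.8), mk("c", "d", 0.7)]
        model = sf.ktsp_select(scores, 1)
        assert (model.pairs[0].gene_i, model.pairs[0].gene_j) == ("a", "b")
        with pytest.raises(ValidationError, match="2"):
            sf.ktsp_select(scores, 3)  # only 2 disjoint pairs exist

    def test_select_matches_exhaustive_for_k1(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((4, 16))
        labels = rng.integers(0, 2, 16)
        labels[0], labels[1] = 0, 1
        z = sf.ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{i}" for i in range(16)], X)
        scores = sf.ktsp_score_pairs(z, labels)
        model = sf.ktsp_select(scores, 1)
        best = max(scores, key=lambda p: (p.delta, p.gamma))
        assert model.pairs[0].delta == best.delta

    def test_classify_votes_and_label_flip_symmetry(self):
        X = np.array([[0.0, 0, 1, 1], [1.0, 1, 0, 0], [0.5, 0.5, 0.5, 0.5]])
        z = sf.ExpressionMatrix(["a", "b", "c"], list("wxyz"), X)
        labels = np.array([1, 1, 0, 0])
        model = sf.ktsp_select(sf.ktsp_score_pairs(z, labels), 1)
        pred = sf.ktsp_classify(z, model)
        np.testing.assert_array_equal(pred, labels)  # perfect training accuracy
        model_f = sf.ktsp_select(sf.ktsp_score_pairs(z, 1 - labels), 1)
        np.testing.assert_array_equal(sf.ktsp_classify(z, model_f), 1 - labels)

    def test_even_k_rejected(self):
        with pytest.raises(ValidationError):
            sf.ktsp_select([], 2)


class TestCombine:
    def test_union_order_and_dedup(self):
        sgr = sf.GeneSignature("sgr", ["A", "B"])
        tsp = sf.TSPClassifier([sf.TSPPairScore("B2", "C", 0.9, 0.0, 1.0, 0.1)], 1)
        out = sf.combine_candidates(sgr, tsp, ["D", "A"])
        assert out.genes == ["A", "B", "B2", "C", "D"]

    def test_fully_overlapping_inputs(self):
        sgr = sf.GeneSignature("sgr", ["A", "B"])
        out = sf.combine_candidates(sgr, None, ["A", "B"])
        assert out.genes == ["A", "B"]
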