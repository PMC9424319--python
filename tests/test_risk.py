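import numpy as np
import pytest

import sigforge as sf
from sigforge.exceptions import GeneLookupError, ValidationError

from oracles import brute_best_two_group_cut


def _scores(vals):
    return sf.RiskScoreVector([f"s{i}" for i in range(len(vals))], np.asarray(vals, float))


def _clin(n, seed=0, hazard=None):
    rng = np.random.default_rng(seed)
    h = np.full(n, 0.02) if hazard is None else hazard
    te = rng.exponential(1 / h)
    tc = np.minimum(rng.exponential(200, n), 240)
    return sf.ClinicalTable(
        [f"s{i}" for i in range(n)], np.minimum(te, tc), (te <= tc).astype(int)
    )


class TestPrognosticIndex:
    def test_zero_betas_give_zero_scores(self, tiny_expression):
        z = sf.zscore_vs_reference(tiny_expression)
        sig = sf.GeneSignature("s", ["A", "B"])
        out = sf.prognostic_index({"A": 0.0, "B": 0.0}, z, sig)
        np.testing.assert_allclose(out.score, 0.0)

    def test_single_gene_identity(self, tiny_expression):
        z = sf.zscore_vs_reference(tiny_expression)
        out = sf.prognostic_index({"A": 1.0}, z, sf.GeneSignature("s", ["A"]))
        np.testing.assert_allclose(out.score, z.values[0])

    def test_cancellation(self):
        z = sf.ExpressionMatrix(["A", "B"], ["s1", "s2"], np.array([[1.0, 2.0], [1.0, 2.0]]))
        out = sf.prognostic_index({"A": 1.0, "B": -1.0}, z, sf.GeneSignature("s", ["A", "B"]))
        np.testing.assert_allclose(out.score, 0.0)

    def test_missing_beta_rejected(self, tiny_expression):
        z = sf.zscore_vs_reference(tiny_expression)
        with pytest.raises(GeneLookupError):
            sf.prognostic_index({"A": 1.0}, z, sf.GeneSignature("s", ["A", "B"]))


class TestMetagene:
    def test_single_gene_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((3, 10))
        z = sf.ExpressionMatrix(["A", "B", "C"], [f"s{i}" for i in range(10)], vals)
        one = sf.metagene_score(z, sf.GeneSignature("s", ["B"]))
        np.testing.assert_allclose(one.score, vals[1])
        fwd = sf.metagene_score(z, sf.GeneSignature("s", ["A", "C"]))
        rev = sf.metagene_score(z, sf.GeneSignature("s", ["C", "A"]))
        np.testing.assert_allclose(fwd.score, rev.score)

    def test_opposite_rows_cancel(self):
        r = np.arange(5.0)
        z = sf.ExpressionMatrix(["A", "B"], [f"s{i}" for i in range(5)], np.vstack([r, -r]))
        out = sf.metagene_score(z, sf.GeneSignature("s", ["A", "B"]))
        np.testing.assert_allclose(out.score, 0.0)


class TestQuantileSplit:
    def test_quartile_counting(self):
        part = sf.quantile_split(_scores(range(1, 9)), mode="quartile")
        assert part.n_per_group == {"excluded": 4, "high": 2, "low": 2}

    def test_median_split_counts(self):
        part = sf.quantile_split(_scores(range(1, 9)), mode="median")
        assert part.n_per_group == {"high": 4, "low": 4}

    def test_all_tied_scores_rejected(self):
        with pytest.raises(ValidationError):
            sf.quantile_split(_scores([1.0] * 8), mode="median")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            sf.quantile_split(_scores([1.0, 2.0, 3.0]), mode="median")

    def test_tertile_excludes_middle_third(self):
        part = sf.quantile_split(_scores(range(1, 10)), mode="tertile-omit-middle")
        assert part.n_per_group["low"] == 3
        assert part.n_per_group["high"] == 3


class TestMaximizeRiskGroups:
    def test_selected_p_not_worse_than_median_split(self):
        rng = np.random.default_rng(5)
        n = 80
        clin = _clin(n, seed=5)
        scores = _scores(rng.standard_normal(n))
        part = sf.maximize_risk_groups(scores, clin, 2, 0.1, fit_cox=False)
        assert part.logrank.p <= part.median_split_p

    def test_matches_brute_force_scan(self):
        import math

        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 25
            clin = _clin(n, seed=seed)
            s = rng.standard_normal(n)
            part = sf.maximize_risk_groups(_scores(s), clin, 2, 0.1, fit_cox=False)
            best_p, best_cut = brute_best_two_group_cut(
                s, clin.time, clin.event, min_count=math.ceil(0.1 * n)
            )
            assert part.logrank.p == pytest.approx(best_p, rel=1e-9)
            assert part.cutpoints[0] == pytest.approx(best_cut)

    def test_p_non_increasing_as_min_frac_shrinks(self):
        rng = np.random.default_rng(6)
        n = 60
        clin = _clin(n, seed=6)
        scores = _scores(rng.standard_normal(n))
        p_tight = sf.maximize_risk_groups(scores, clin, 2, 0.3, fit_cox=False).logrank.p
        p_loose = sf.maximize_risk_groups(scores, clin, 2, 0.05, fit_cox=False).logrank.p
        assert p_loose <= p_tight

    def test_rank_invariance_of_grouping(self):
        rng = np.random.default_rng(7)
        n = 40
        clin = _clin(n, seed=7)
        s = rng.standard_normal(n)
        a = sf.maximize_risk_groups(_scores(s), clin, 2, 0.1, fit_cox=False)
        b = sf.maximize_risk_groups(_scores(np.exp(s)), clin, 2, 0.1, fit_cox=False)
        assert a.group == b.group

    def test_three_groups_infeasible(self):
        clin = _clin(10)
        with pytest.raises(ValidationError):
            sf.maximize_risk_groups(_scores(np.arange(10.0)), clin, 3, 0.4)

    def test_three_group_labels_ordered_by_score(self):
        rng = np.random.default_rng(8)
        n = 60
        clin = _clin(n, seed=8)
        s = rng.standard_normal(n)
        part = sf.maximize_risk_groups(_scores(s), clin, 3, 0.15, fit_cox=False)
        means = {
            g: np.mean([s[i] for i in range(n) if part.group[i] == g])
            for g in ("low", "medium", "high")
        }
        assert means["low"] < means["medium"] < means["high"]


class TestBestCutoffFDR:
    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        n = 50
        clin = _clin(n, seed=9)
        scan = sf.best_cutoff_fdr(_scores(rng.standard_normal(n)), clin)
        assert scan.selected_q >= scan.selected_p
        assert (scan.q >= scan.p - 1e-12).all()

    def test_window_validation(self):
        clin = _clin(20)
        with pytest.raises(ValidationError):
            sf.best_cutoff_fdr(_scores(np.arange(20.0)), clin, window=(0.5, 1.5))

    def test_needs_three_candidates(self):
        clin = _clin(4)
        with pytest.raises(ValidationError):
            sf.best_cutoff_fdr(_scores([1.0, 1.0, 2.0, 2.0]), clin)

    def test_null_raw_selection_is_inflated_and_bh_controls(self):
        """Min-p cutoff selection without correction is anti-conservative."""
        raw = adj = 0
        reps = 150
        for r in range(reps):
            rng = np.random.default_rng(r)
            n = 60
            clin = _clin(n, seed=10_000 + r)
            scan = sf.best_cutoff_fdr(_scores(rng.standard_normal(n)), clin)
            raw += scan.selected_p < 0.05
            adj += scan.selected_q < 0.05
        assert raw / reps > 0.05
        assert adj <= raw
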