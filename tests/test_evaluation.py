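import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_assoc, make_sim, random_sim
from oracles import aupr_brute, auc_brute, gba_brute

from drugfuse import (
    FusionParams,
    ValidationError,
    jaccard_similarity,
    loocv,
    paired_t_test,
    parameter_grid,
    pr_aupr,
    precision_recall_at_k,
    roc_auc,
)

score_lists = st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)


class TestRocAuc:
    @pytest.mark.parametrize("pos, neg, expected", [
        ([0.9], [0.1, 0.2], 1.0),
        ([0.5], [0.5], 0.5),
        ([0.8, 0.3], [0.6, 0.1], 0.75),  # 3 concordant of 4 pairs
    ])
    def test_examples(self, pos, neg, expected):
        assert roc_auc(pos, neg) == pytest.approx(expected, abs=1e-12)

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            roc_auc([], [0.1])

    @settings(max_examples=100, deadline=None)
    @given(pos=score_lists, neg=score_lists)
    def test_matches_pair_counting(self, pos, neg):
        assert roc_auc(pos, neg) == pytest.approx(auc_brute(pos, neg), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(pos=score_lists, neg=score_lists)
    def test_complement_identity(self, pos, neg):
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(pos=score_lists, neg=score_lists,
           delta=st.floats(0, 0.5, allow_nan=False))
    def test_shifting_positives_up_never_hurts(self, pos, neg, delta):
        shifted = [p + delta for p in pos]
        assert roc_auc(shifted, neg) >= roc_auc(pos, neg) - 1e-12

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score
        pos = rng.random(20)
        neg = rng.random(30)
        y = np.r_[np.ones(20), np.zeros(30)]
        assert roc_auc(pos, neg) == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)


class TestPrAupr:
    @pytest.mark.parametrize("pos, neg, expected", [
        ([0.9], [0.5, 0.1], 1.0),          # single positive ranked first of 3
        ([0.3], [0.8], 0.5),               # single positive ranked 2nd of 2
        ([0.9, 0.4], [0.6], (1 + 2 / 3) / 2),  # positives at ranks 1 and 3
    ])
    def test_examples(self, pos, neg, expected):
        assert pr_aupr(pos, neg) == pytest.approx(expected, abs=1e-12)

    def test_ties_are_pessimistic(self):
        # positive tied with a negative ranks below it
        assert pr_aupr([0.5], [0.5]) == pytest.approx(0.5)

    def test_empty_positive_error(self):
        with pytest.raises(ValidationError):
            pr_aupr([], [0.1])

    @settings(max_examples=100, deadline=None)
    @given(pos=score_lists, neg=score_lists)
    def test_matches_rank_enumeration(self, pos, neg):
        assert pr_aupr(pos, neg) == pytest.approx(aupr_brute(pos, neg), abs=1e-12)


class TestPrecisionRecallAtK:
    def test_single_hit_at_top(self):
        prec, rec = precision_recall_at_k([np.array([1])], 5)
        assert prec == pytest.approx(0.2) and rec == pytest.approx(1.0)

    def test_all_misses(self):
        prec, rec = precision_recall_at_k([np.array([8, 9])], 5)
        assert prec == 0.0 and rec == 0.0

    def test_matches_direct_count(self, rng):
        ranks = [rng.choice(np.arange(1, 31), size=rng.integers(1, 6),
                            replace=False) for _ in range(12)]
        for k in (5, 10, 15, 20):
            prec, rec = precision_recall_at_k(ranks, k)
            exp_p = np.mean([np.sum(r <= k) / k for r in ranks])
            exp_r = np.mean([np.sum(r <= k) / len(r) for r in ranks])
            assert prec == pytest.approx(exp_p) and rec == pytest.approx(exp_r)

    def test_recall_nondecreasing_in_k(self, rng):
        ranks = [rng.choice(np.arange(1, 41), size=4, replace=False)
                 for _ in range(8)]
        recalls = [precision_recall_at_k(ranks, k)[1] for k in range(1, 41)]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))


class TestLoocv:
    def test_perfect_separation_toy(self):
        sim = make_sim([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        assoc = make_assoc([[1, 0], [1, 0], [0, 1]])
        res = loocv(sim, assoc)
        # drugs d0/d1 recover each other's disease perfectly
        by_drug = dict(zip(res.evaluated_drug_ids, res.per_drug_auc))
        assert by_drug["d0"] == 1.0 and by_drug["d1"] == 1.0

    def test_identity_similarity_is_uninformative(self):
        sim = make_sim(np.eye(4))
        assoc = make_assoc([[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]])
        res = loocv(sim, assoc)
        assert np.allclose(res.per_drug_auc, 0.5)

    def test_matches_full_protocol_brute_force(self, rng):
        sim = random_sim(rng, 8)
        assoc = make_assoc((rng.random((8, 5)) < 0.4).astype(np.uint8))
        res = loocv(sim, assoc)
        for drug, auc, aupr in zip(res.evaluated_drug_ids, res.per_drug_auc,
                                   res.per_drug_aupr):
            i = sim.drug_ids.index(drug)
            held = assoc.values.copy()
            held[i] = 0  # remove the test drug's indications
            row = [gba_brute(sim.values, held, i, j) for j in range(5)]
            pos = [row[j] for j in range(5) if assoc.values[i, j] == 1]
            neg = [row[j] for j in range(5) if assoc.values[i, j] == 0]
            assert auc == pytest.approx(auc_brute(pos, neg), abs=1e-12)
            assert aupr == pytest.approx(aupr_brute(pos, neg), abs=1e-12)

    def test_heldout_row_cannot_influence_own_scores(self, rng):
        # the fold isolation the protocol relies on: replacing the held-out
        # drug's association row with arbitrary values leaves its scores
        # untouched, because the scoring rule excludes the self term
        from drugfuse import score_all
        sim = random_sim(rng, 6)
        assoc_vals = (rng.random((6, 4)) < 0.5).astype(np.uint8)
        tampered = assoc_vals.copy()
        tampered[2] = 1 - tampered[2]
        s1 = score_all(sim, make_assoc(assoc_vals)).values[2]
        s2 = score_all(sim, make_assoc(tampered)).values[2]
        np.testing.assert_allclose(s1, s2, atol=0)

    def test_drug_without_association_skipped_with_warning(self, rng):
        sim = random_sim(rng, 4)
        assoc = make_assoc([[1, 0], [0, 0], [1, 1], [0, 1]])
        with pytest.warns(UserWarning, match="no known association"):
            res = loocv(sim, assoc)
        assert res.skipped_drug_ids == ("d1",)
        assert "d1" not in res.evaluated_drug_ids


class TestPairedTTest:
    def test_identical_vectors(self):
        t, p = paired_t_test([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert t == 0.0 and p == 0.5

    def test_constant_positive_shift(self):
        t, p = paired_t_test([0.5, 0.75, 1.0], [0.25, 0.5, 0.75])
        assert t == np.inf and p == 0.0

    def test_closed_form_example(self):
        a = np.array([0.5, 0.6, 0.7])
        b = a - np.array([0.1, 0.2, 0.3])
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(3.4641016151377544, abs=1e-10)
        # independent route: closed-form statistic through the t survival fn
        assert p == pytest.approx(stats.t.sf(0.2 / (0.1 / np.sqrt(3)), 2),
                                  abs=1e-12)

    def test_one_sided_direction(self, rng):
        a = rng.random(30)
        b = a + 0.2 + rng.random(30) * 0.1
        _, p = paired_t_test(a, b)  # a is *worse*
        assert p > 0.95

    def test_too_short_error(self):
        with pytest.raises(ValidationError):
            paired_t_test([0.1], [0.2])


class TestParameterGrid:
    @pytest.fixture
    def small_instance(self):
        from conftest import make_profiles
        rng = np.random.default_rng(5)
        views = []
        for _ in range(3):
            mat = (rng.random((12, 30)) < 0.3).astype(np.uint8)
            views.append(jaccard_similarity(make_profiles(mat)))
        assoc_vals = (rng.random((12, 6)) < 0.4).astype(np.uint8)
        assoc_vals[:, 0] = 1
        return views, make_assoc(assoc_vals)

    def test_single_cell_reproduces_loocv(self, small_instance):
        views, assoc = small_instance
        from drugfuse import cross_diffuse
        grid = parameter_grid(views, assoc, k_values=[3], t_values=[2])
        fused = cross_diffuse(views, FusionParams(k=3, t=2))
        res = loocv(fused, assoc)
        assert len(grid.table) == 1
        assert grid.table.loc[0, "mean_auc"] == pytest.approx(res.mean_auc)
        assert grid.table.loc[0, "mean_aupr"] == pytest.approx(res.mean_aupr)
        assert grid.best_by_auc == (3, 2)

    def test_shape_and_determinism(self, small_instance):
        views, assoc = small_instance
        g1 = parameter_grid(views, assoc, k_values=[1, 3], t_values=[0, 1, 2])
        g2 = parameter_grid(views, assoc, k_values=[1, 3], t_values=[0, 1, 2])
        assert len(g1.table) == 6
        assert g1.table.equals(g2.table)
        assert g1.best_by_auc == g2.best_by_auc
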