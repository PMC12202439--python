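"""Rating binarization, selection filters, SVM-RFE, metrics and LOAO."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from neuroads import (
    accuracy,
    auc_score,
    f1_score,
    loao_evaluate,
    normalize_and_binarize,
    prune_redundant,
    relevance_filter,
    svm_rfe,
)
from neuroads.modeling import SelectionState
from neuroads.types import ParameterError


def synthetic_study(n_subjects=10, n_ads=8, n_features=40, n_informative=3,
                    seed=0, signal=2.0):
    """Random feature matrix + ratings with a planted linear signal."""
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:02d}" for i in range(n_subjects)]
    ads = [f"ad{j}" for j in range(n_ads)]
    index = pd.MultiIndex.from_product([subjects, ads], names=["subject_id", "ad_id"])
    n = len(index)
    X = rng.standard_normal((n, n_features))
    latent = X[:, :n_informative].sum(axis=1) / np.sqrt(n_informative)
    raw = np.clip(np.round(5.5 + 2.0 * signal * latent + rng.standard_normal(n)), 1, 10)
    features = pd.DataFrame(X, index=index,
                            columns=[f"f{k}" for k in range(n_features)])
    ratings = pd.DataFrame(dict(
        subject_id=index.get_level_values(0), ad_id=index.get_level_values(1),
        rating=raw.astype(int)))
    return features, normalize_and_binarize(ratings)


class TestNormalizeAndBinarize:
    def test_minmax_and_threshold(self):
        rt = pd.DataFrame(dict(subject_id=["a"] * 3, ad_id=list("xyz"),
                               rating=[2, 6, 10]))
        out = normalize_and_binarize(rt)
        np.testing.assert_allclose(out["normalized"], [0.0, 0.5, 1.0])
        assert list(out["label"]) == ["LR", "HR", "HR"]

    def test_constant_subject_maps_to_hr(self):
        rt = pd.DataFrame(dict(subject_id=["a"] * 2, ad_id=["x", "y"],
                               rating=[10, 10]))
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_and_binarize(rt)
        assert (out["normalized"] == 1.0).all()
        assert (out["label"] == "HR").all()

    def test_midpoint_is_high_rated(self):
        rt = pd.DataFrame(dict(subject_id=["a"] * 3, ad_id=list("xyz"),
                               rating=[1, 5, 9]))
        out = normalize_and_binarize(rt)
        assert out.loc[out["rating"] == 5, "label"].iloc[0] == "HR"


class TestPruneRedundant:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        X = pd.DataFrame(dict(a=a, b=a.copy(), c=rng.standard_normal(100)))
        state = prune_redundant(X, 0.8)
        assert state.stage1_kept == ("a", "c")

    def test_latent_factor_groups_match_graph_oracle(self):
        """10 columns from 3 well-separated latent factors: the kept count
        equals the number of connected components of the |r|>0.8 graph."""
        rng = np.random.default_rng(1)
        n = 400
        factors = rng.standard_normal((n, 3))
        cols = {}
        assignment = [0, 0, 0, 1, 1, 1, 2, 2, 2, 2]
        for k, g in enumerate(assignment):
            cols[f"f{k}"] = factors[:, g] + 0.05 * rng.standard_normal(n)
        X = pd.DataFrame(cols)
        state = prune_redundant(X, 0.8)
        # brute-force graph components of the |r|>0.8 adjacency
        C = np.abs(np.corrcoef(X.to_numpy().T))
        adj = C > 0.8
        import networkx as nx
        g = nx.from_numpy_array(adj)
        n_components = nx.number_connected_components(g)
        assert len(state.stage1_kept) == n_components == 3

    def test_threshold_one_keeps_everything(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        X = pd.DataFrame(dict(a=a, b=a.copy(), c=-a))
        state = prune_redundant(X, 1.0)
        assert len(state.stage1_kept) == 3

    def test_zero_variance_dropped_with_warning(self):
        X = pd.DataFrame(dict(a=np.ones(50), b=np.random.default_rng(3).standard_normal(50),
                              c=np.random.default_rng(4).standard_normal(50)))
        with pytest.warns(UserWarning, match="zero-variance"):
            state = prune_redundant(X, 0.8)
        assert "a" not in state.stage1_kept
        assert state.dropped_zero_variance == ("a",)


class TestRelevanceFilter:
    def test_perfectly_relevant_kept_both_signs(self):
        rng = np.random.default_rng(5)
        r = rng.uniform(0, 1, 80)
        X = pd.DataFrame(dict(pos=r.copy(), neg=-r, noise=rng.standard_normal(80)))
        state = relevance_filter(X, r, 0.1)
        assert "pos" in state.stage2_kept
        assert "neg" in state.stage2_kept  # absolute-value rule

    def test_null_keep_rate_matches_pearson_null(self):
        """Independent noise features at n=160 pass |r|>0.1 with probability
        ~0.21 (two-sided tail of the null Pearson distribution)."""
        rng = np.random.default_rng(6)
        n, p = 160, 3000
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"f{k}" for k in range(p)])
        r = rng.uniform(0, 1, n)
        state = relevance_filter(X, r, 0.1)
        from scipy import stats
        t = 0.1 * np.sqrt(n - 2) / np.sqrt(1 - 0.01)
        expected = 2 * stats.t.sf(t, df=n - 2)
        assert len(state.stage2_kept) / p == pytest.approx(expected, abs=0.04)

    def test_empty_survivor_set_is_error(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(dict(a=rng.standard_normal(200), b=rng.standard_normal(200)))
        r = rng.uniform(0, 1, 200)
        with pytest.raises(ParameterError, match="threshold"):
            relevance_filter(X, r, 0.999)

    def test_subset_invariant(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((100, 20)),
                         columns=[f"f{k}" for k in range(20)])
        r = X["f0"].to_numpy() + 0.1 * rng.standard_normal(100)
        s1 = prune_redundant(X, 0.8)
        s2 = relevance_filter(X, r, 0.1, s1)
        assert set(s2.stage2_kept) <= set(s2.stage1_kept)

    def test_stage_order_enforced(self):
        with pytest.raises(ParameterError):
            SelectionState(stage1_kept=("a",), stage2_kept=("a", "b"))


class TestSvmRfe:
    def test_planted_separator_recovered(self):
        """A perfectly separating feature among noise is top-ranked and kept."""
        hits = 0
        runs = 50
        for s in range(runs):
            rng = np.random.default_rng(100 + s)
            n = 120
            y = rng.random(n) < 0.5
            X = pd.DataFrame(rng.standard_normal((n, 21)),
                             columns=["sig"] + [f"n{k}" for k in range(20)])
            X["sig"] = np.where(y, 1.0, -1.0) + 0.1 * rng.standard_normal(n)
            res = svm_rfe(X, y, seed=s)
            if res.ranking[0] == "sig" and "sig" in res.kept:
                hits += 1
        assert hits >= int(0.95 * runs)

    def test_pure_noise_contract(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((60, 2)), columns=["a", "b"])
        y = rng.random(60) < 0.5
        res = svm_rfe(X, y, seed=0)
        assert set(res.ranking) == {"a", "b"}
        assert len(res.kept) >= 1

    def test_single_class_is_error(self):
        X = pd.DataFrame(np.random.default_rng(10).standard_normal((20, 3)))
        with pytest.raises(ParameterError, match="single class"):
            svm_rfe(X, np.ones(20, dtype=bool))

    def test_elimination_order_matches_primal_refit_oracle(self):
        """Step-by-step elimination agrees with an independent oracle that
        refits a primal linear SVM and drops the smallest-|w| feature."""
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(11)
        n = 200
        y = rng.random(n) < 0.5
        ysign = np.where(y, 1.0, -1.0)
        X = pd.DataFrame({
            "strong": ysign * 2.0 + 0.2 * rng.standard_normal(n),
            "medium": ysign * 1.0 + 0.5 * rng.standard_normal(n),
            "weak": ysign * 0.4 + 0.9 * rng.standard_normal(n),
            "noise": rng.standard_normal(n),
        })
        res = svm_rfe(X, y, seed=0, c=1.0)

        cols = list(X.columns)
        Z = (X - X.mean()) / X.std(ddof=0)
        active = list(cols)
        oracle_elim = []
        while len(active) > 1:
            clf = LinearSVC(C=1.0, loss="hinge", max_iter=100000, tol=1e-8)
            clf.fit(Z[active].to_numpy(), y)
            drop = active[int(np.argmin(np.abs(clf.coef_[0])))]
            oracle_elim.append(drop)
            active.remove(drop)
        oracle_ranking = active + oracle_elim[::-1]
        assert list(res.ranking) == oracle_ranking


class TestMetrics:
    def test_hand_computed_accuracy_and_f1(self):
        assert accuracy(3, 4, 1, 2) == pytest.approx(0.7)
        assert f1_score(3, 1, 2) == pytest.approx(3 / 4.5)

    def test_perfect_prediction(self):
        assert accuracy(5, 5, 0, 0) == 1.0
        assert f1_score(5, 0, 0) == 1.0
        assert auc_score([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ParameterError):
            accuracy(0, 0, 0, 0)
        with pytest.raises(ParameterError):
            f1_score(0, 0, 0)

    def test_negative_counts_error(self):
        with pytest.raises(ParameterError):
            accuracy(-1, 1, 1, 1)

    def test_auc_matches_mann_whitney(self):
        rng = np.random.default_rng(12)
        scores = rng.standard_normal(200)
        labels = rng.random(200) < 0.4
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        expected = u / (labels.sum() * (~labels).sum())
        assert auc_score(scores, labels) == pytest.approx(expected)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(13)
        labels = rng.random(4000) < 0.5
        scores = rng.standard_normal(4000)
        assert auc_score(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_auc_is_undefined(self):
        assert np.isnan(auc_score([0.1, 0.9], [1, 1]))


class TestLoao:
    def test_fold_structure_and_monotone_selection(self):
        features, rt = synthetic_study(seed=14)
        report = loao_evaluate(features, rt, classifiers=("svm",), seed=0)
        assert len(report.per_fold) == 8
        assert report.per_fold["n_test"].sum() == len(features)
        assert (report.per_fold["n_test"] == 10).all()
        for state in report.selections.values():
            assert set(state.stage2_kept) <= set(state.stage1_kept)
            assert set(state.rfe_kept) <= set(state.stage2_kept)

    def test_single_class_test_fold_gives_undefined_auc(self):
        features, rt = synthetic_study(seed=15)
        rt = rt.copy()
        mask = rt["ad_id"] == "ad0"
        rt.loc[mask, ["rating", "normalized", "label"]] = [10, 1.0, "HR"]
        report = loao_evaluate(features, rt, classifiers=("svm",), seed=0)
        fold = report.per_fold[report.per_fold["ad_id"] == "ad0"]
        assert np.isnan(fold["auc"].iloc[0])
        others = report.per_fold[report.per_fold["ad_id"] != "ad0"]["auc"]
        assert report.averages["auc"].iloc[0] == pytest.approx(np.nanmean(others))

    def test_determinism(self):
        features, rt = synthetic_study(seed=16)
        a = loao_evaluate(features, rt, seed=0)
        b = loao_evaluate(features, rt, seed=0)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)
        pd.testing.assert_frame_equal(a.averages, b.averages)

    def test_all_four_classifiers_reported(self):
        features, rt = synthetic_study(seed=17)
        report = loao_evaluate(features, rt, seed=0)
        assert set(report.per_fold["model"]) == {"svm", "rf", "dt", "lr"}
        assert report.averages["accuracy"].between(0, 1).all()

    def test_report_csv_layout(self, tmp_path):
        features, rt = synthetic_study(seed=18)
        report = loao_evaluate(features, rt, classifiers=("svm", "lr"), seed=0)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert "svm_accuracy" in back.columns
        assert "average" in back.index
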