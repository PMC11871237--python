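"""Case splitting, voting, MIL fusion features and the silicon pipeline."""

import numpy as np
import pandas as pd
import pytest

from lrscape import silicon as si
from lrscape.silicon import (EvalReport, SelectionRule, SiliconDataset,
                             SlideBag, SplitConfig, VoteConfig, bow_features,
                             cluster_accuracy_table, correlation_filter,
                             evaluate, fit_slide_classifier, majority_vote,
                             net_benefit_curve, plh_features, risk_heatmap,
                             run_silicon_pipeline, select_clusters,
                             split_cases, train_patch_classifier)


def make_bag(likelihoods, label=1, slide_id="s"):
    n = len(likelihoods)
    coords = np.column_stack([np.zeros(n, int), np.arange(n)])
    return SlideBag(slide_id=slide_id, label=label,
                    likelihoods=np.asarray(likelihoods, float), coords=coords)


class TestSplitCases:
    CASES = {f"c{i}": i % 2 for i in range(10)}

    def test_eight_two_split(self):
        train, test = split_cases(self.CASES, SplitConfig(seed=0))
        assert len(train) == 8 and len(test) == 2
        # stratified: one test case per class
        assert sorted(self.CASES[c] for c in test) == [0, 1]

    def test_no_leakage_any_seed(self):
        for seed in range(25):
            train, test = split_cases(self.CASES, SplitConfig(seed=seed))
            assert set(train) | set(test) == set(self.CASES)
            assert not set(train) & set(test)
            assert test  # never empty

    def test_same_seed_identical(self):
        assert split_cases(self.CASES, SplitConfig(seed=7)) == \
            split_cases(self.CASES, SplitConfig(seed=7))

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            split_cases({"a": 1, "b": 1, "c": 1}, SplitConfig(seed=0))

    def test_too_few_cases_is_error(self):
        with pytest.raises(ValueError):
            split_cases({"a": 0, "b": 1}, SplitConfig(seed=0))


class TestMajorityVote:
    def test_six_of_ten_is_positive(self):
        assert majority_vote([1] * 6 + [0] * 4) == 1

    def test_exactly_half_is_negative(self):
        assert majority_vote([1] * 5 + [0] * 5) == 0  # strict > rule

    def test_single_positive_patch(self):
        assert majority_vote([1]) == 1

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_monotone_in_positive_count(self):
        votes = [majority_vote([1] * k + [0] * (10 - k)) for k in range(11)]
        assert votes == sorted(votes)
        assert votes[5] == 0 and votes[6] == 1


class TestPlh:
    def test_two_patch_example(self):
        feats = plh_features(make_bag([0.1, 0.9]), n_bins=2)
        np.testing.assert_allclose(feats, [0.5, 0.5])

    def test_identical_likelihoods_one_hot(self):
        feats = plh_features(make_bag([0.25] * 7), n_bins=10)
        expected = np.zeros(10)
        expected[2] = 1.0
        np.testing.assert_allclose(feats, expected)

    def test_probability_one_falls_in_last_bin(self):
        feats = plh_features(make_bag([1.0]), n_bins=10)
        assert feats[-1] == 1.0

    def test_order_invariance_and_normalization(self, rng):
        p = rng.uniform(0, 1, 30)
        a = plh_features(make_bag(p))
        b = plh_features(make_bag(p[::-1]))
        np.testing.assert_allclose(a, b)
        assert a.sum() == pytest.approx(1.0)


class TestBow:
    def test_ubiquitous_word_has_idf_one(self):
        """A word present in every training bag gets idf exactly 1, so the
        feature equals the raw term frequency."""
        corpus = [make_bag([0.05] * 4), make_bag([0.05, 0.95])]
        query = make_bag([0.05, 0.05, 0.95, 0.95])
        feats = bow_features(corpus, query, n_words=16)
        assert feats[0] == pytest.approx(0.5)  # word 0 in both bags: tf * 1

    def test_single_patch_is_one_hot_tf(self):
        corpus = [make_bag([0.5]), make_bag([0.99])]
        feats = bow_features(corpus, make_bag([0.5]), n_words=16)
        assert np.count_nonzero(feats) == 1
        assert feats[8] > 0  # 0.5 * 16 = word 8

    def test_hand_computed_three_slide_corpus(self):
        """2-word vocabulary, 3 training bags: df = (3, 1), so idf_0 = ln(1)+1
        and idf_1 = ln(2)+1; query tf = (0.75, 0.25)."""
        corpus = [make_bag([0.1, 0.2]), make_bag([0.3, 0.8]), make_bag([0.4])]
        query = make_bag([0.1, 0.2, 0.3, 0.9])
        feats = bow_features(corpus, query, n_words=2)
        np.testing.assert_allclose(
            feats, [0.75 * 1.0, 0.25 * (np.log(2.0) + 1.0)])

    def test_duplicated_training_bag_changes_nothing_for_df_ratio(self):
        """idf uses (1+N)/(1+n_w); duplicating the whole corpus keeps every
        word's document-frequency ratio, so features move only through the
        shared +1 smoothing and ordering is preserved."""
        corpus = [make_bag([0.1, 0.2]), make_bag([0.8])]
        query = make_bag([0.1, 0.8])
        a = bow_features(corpus, query, n_words=4)
        b = bow_features(corpus * 10, query, n_words=4)
        assert np.array_equal(np.argsort(a), np.argsort(b))

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            bow_features([], make_bag([0.5]))


class TestCorrelationFilter:
    def test_perfectly_correlated_copy_dropped(self, rng):
        f1 = rng.normal(size=40)
        X = np.column_stack([f1, 2.0 * f1, rng.normal(size=40)])
        kept = correlation_filter(X)
        assert len(kept) == 2
        assert not ({0, 1} <= set(kept))  # at most one of the two copies

    def test_orthogonal_features_all_kept(self, rng):
        X, _ = np.linalg.qr(rng.normal(size=(50, 8)))
        kept = correlation_filter(X)
        assert sorted(kept) == list(range(8))

    def test_kept_set_satisfies_threshold_pairwise(self, rng):
        X = rng.normal(size=(60, 50))
        X[:, 25:] += X[:, :25]  # induce correlations
        kept = correlation_filter(X, r_threshold=0.8, max_features=32)
        assert len(kept) <= 32
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert abs(np.corrcoef(X[:, a], X[:, b])[0, 1]) < 0.8

    def test_visits_by_decreasing_variance(self, rng):
        X = np.column_stack([rng.normal(0, 1, 40), rng.normal(0, 10, 40)])
        X[:, 0] = X[:, 1] * 0.1 + 1e-9 * rng.normal(size=40)  # near copies
        kept = correlation_filter(X)
        assert kept == [1]  # the high-variance one wins

    def test_all_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            correlation_filter(np.ones((10, 3)))


class TestSlideClassifiers:
    @pytest.mark.parametrize("model", ["svm_rbf", "knn", "random_forest"])
    def test_separable_problem_perfect_accuracy(self, model, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(5, 0.3, (20, 4))])
        y = np.repeat([0, 1], 20)
        clf = fit_slide_classifier(X, y, model=model, seed=0)
        assert (clf.predict(X) == y).all()
        assert (clf.predict_proba(X)[:, 1] > 0.5).astype(int).tolist() == y.tolist()

    def test_permuted_labels_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        aucs = []
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            X = r.normal(size=(60, 5))
            y = r.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            Xte, yte = r.normal(size=(60, 5)), r.integers(0, 2, 60)
            clf = fit_slide_classifier(X, y, model="svm_rbf", seed=rep)
            aucs.append(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_single_class_is_error(self, rng):
        with pytest.raises(ValueError):
            fit_slide_classifier(rng.normal(size=(10, 3)), np.ones(10))

    def test_unknown_model_is_error(self, rng):
        with pytest.raises(ValueError):
            fit_slide_classifier(rng.normal(size=(10, 3)),
                                 np.repeat([0, 1], 5), model="mlp")


class TestEvaluate:
    def test_perfect_scores(self):
        labels = np.array([0, 0, 1, 1])
        report = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert report.accuracy == 1.0 and report.auc == 1.0
        assert report.confusion == {"TP": 2, "FP": 0, "TN": 2, "FN": 0}

    def test_net_benefit_treat_none_is_zero(self):
        labels = np.array([0, 1, 0, 1])
        nb = net_benefit_curve(labels, np.array([0.1, 0.9, 0.2, 0.8]))
        assert (nb.treat_none == 0).all()

    def test_net_benefit_hand_example(self):
        """Prevalence 0.3 (3 of 10), perfect classifier at p_t = 0.2:
        NB = 3/10 - 0 = 0.3; treat-all = 0.3 - 0.7 * 0.25 = 0.125."""
        labels = np.array([1, 1, 1] + [0] * 7)
        scores = np.where(labels == 1, 0.9, 0.1)
        nb = net_benefit_curve(labels, scores, thresholds=[0.2])
        assert nb.model.iloc[0] == pytest.approx(0.3)
        assert nb.treat_all.iloc[0] == pytest.approx(0.3 - 0.7 * (0.2 / 0.8))

    def test_net_benefit_treat_all_at_prevalence_threshold(self):
        labels = np.array([1] * 3 + [0] * 7)
        nb = net_benefit_curve(labels, np.full(10, 0.99), thresholds=[0.3])
        odds = 0.3 / 0.7
        assert nb.treat_all.iloc[0] == pytest.approx(0.3 - 0.7 * odds)

    def test_single_class_labels_is_error(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.4, 0.6]), np.array([1, 1]))


def tiny_dataset(seed=0, n_cases=12, informative_cluster=0, n_clusters=3,
                 sep=4.0):
    """Synthetic patch dataset: one cluster's features carry the slide label,
    the rest are noise. One slide per case, 6 patches per slide (2/cluster)."""
    r = np.random.default_rng(seed)
    feats, slide_ids, clusters, coords = [], [], [], []
    labels, cases = {}, {}
    for i in range(n_cases):
        sid, label = f"slide_{i:03d}", i % 2
        labels[sid], cases[sid] = label, f"case_{i:03d}"
        for c in range(n_clusters):
            for p in range(2):
                mu = sep * label if c == informative_cluster else 0.0
                feats.append(r.normal(mu, 1.0, size=4))
                slide_ids.append(sid)
                clusters.append(c)
                coords.append((c, p))
    return SiliconDataset(features=np.vstack(feats),
                          slide_ids=np.array(slide_ids),
                          clusters=np.array(clusters),
                          coords=np.array(coords), labels=labels, cases=cases)


class TestClusterScreening:
    def test_informative_cluster_scores_high_noise_low(self):
        ds = tiny_dataset(seed=1, n_cases=24, sep=6.0)
        train = sorted(ds.labels)[:16]
        val = sorted(ds.labels)[16:]
        patch_labels = np.array([ds.labels[s] for s in ds.slide_ids])
        models = {}
        for c in ds.cluster_ids:
            mask = ds.patch_mask(train, [c])
            models[c] = train_patch_classifier(ds.features[mask], patch_labels[mask])
        acc = cluster_accuracy_table(models, ds, val).set_index("cluster")
        assert acc.loc[0, "accuracy"] == 1.0
        assert acc.loc[1, "accuracy"] < 1.0 or acc.loc[2, "accuracy"] < 1.0

    def test_missing_validation_patches_give_nan(self):
        ds = tiny_dataset(seed=2)
        patch_labels = np.array([ds.labels[s] for s in ds.slide_ids])
        mask = ds.patch_mask(sorted(ds.labels), [0])
        model = train_patch_classifier(ds.features[mask], patch_labels[mask])
        acc = cluster_accuracy_table({0: model}, ds, validation_slides=[])
        assert np.isnan(acc.accuracy.iloc[0])
        assert acc.n_slides.iloc[0] == 0


class TestSelectClusters:
    ACC = pd.DataFrame({
        "cluster": [0, 1, 2, 3, 4, 5],
        "backbone": ["b"] * 6,
        "accuracy": [0.7, 0.72, 0.55, 0.5, 0.68, 0.71],
    })

    def test_bottom_two_dropped(self):
        assert select_clusters(self.ACC, SelectionRule("bottom_k", 2)) == [0, 1, 4, 5]

    def test_threshold_rule(self):
        assert select_clusters(self.ACC, SelectionRule("threshold", 0.7)) == [0, 1, 5]

    def test_threshold_zero_keeps_all(self):
        assert select_clusters(self.ACC, SelectionRule("threshold", 0.0)) == list(range(6))

    def test_explicit_rule(self):
        assert select_clusters(self.ACC, SelectionRule("explicit", [3, 1])) == [1, 3]

    def test_dropping_everything_is_error(self):
        with pytest.raises(ValueError):
            select_clusters(self.ACC, SelectionRule("threshold", 1.1))

    def test_bottom_k_never_empties(self):
        assert select_clusters(self.ACC, SelectionRule("bottom_k", 99)) == [1]

    def test_unknown_mode_is_error(self):
        with pytest.raises(ValueError):
            SelectionRule("best_k", 2)


class TestPipeline:
    def test_all_cluster_selection_makes_arms_identical(self):
        """When the rule keeps every cluster, the selection and no-selection
        arms share the exact same code path and seeds — predictions must be
        bit-identical."""
        ds = tiny_dataset(seed=3, n_cases=20)
        out = run_silicon_pipeline(ds, rule=SelectionRule("threshold", 0.0),
                                   split_cfg=SplitConfig(seed=0), seed=0)
        assert out["selected_clusters"] == ds.cluster_ids
        a = out["selection"]["report"].predictions
        b = out["no_selection"]["report"].predictions
        assert (a.score.to_numpy() == b.score.to_numpy()).all()

    def test_split_has_no_case_leakage(self):
        ds = tiny_dataset(seed=4, n_cases=20)
        out = run_silicon_pipeline(ds, split_cfg=SplitConfig(seed=1), seed=1)
        train_cases = {ds.cases[s] for s in out["train_slides"]}
        test_cases = {ds.cases[s] for s in out["test_slides"]}
        assert not train_cases & test_cases

    def test_heatmap_dimensions_and_values(self):
        ds = tiny_dataset(seed=5, n_cases=20)
        out = run_silicon_pipeline(ds, rule=SelectionRule("threshold", 0.0),
                                   split_cfg=SplitConfig(seed=2), seed=2)
        grid = (int(ds.coords[:, 0].max()) + 1, int(ds.coords[:, 1].max()) + 1)
        for heat in out["no_selection"]["heatmaps"].values():
            assert heat.shape == grid
            vals = heat[~np.isnan(heat)]
            assert ((0 <= vals) & (vals <= 1)).all()

    def test_risk_heatmap_roundtrip(self):
        bag = make_bag([0.25, 0.75])
        heat = risk_heatmap(bag, (1, 2))
        np.testing.assert_allclose(heat, [[0.25, 0.75]])


class TestPatchClassifier:
    def test_single_class_is_error(self, rng):
        with pytest.raises(ValueError):
            train_patch_classifier(rng.normal(size=(10, 3)), np.zeros(10))

    def test_separable_patches_learned(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(4, 0.3, (30, 4))])
        y = np.repeat([0, 1], 30)
        model = train_patch_classifier(X, y)
        p = model.predict_proba1(X)
        assert (p[:30] < 0.5).all() and (p[30:] > 0.5).all()
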