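"""Silicon pathological region selection and multiple-instance slide fusion.

Workflow on a weakly labeled, patch-clustered slide cohort:

1. split cases (not slides) 8:2 into training and testing cohorts;
2. per morphological cluster, train a patch classifier on slide-inherited
   labels and score it on validation slides by strict-majority voting;
3. drop uninformative clusters (threshold / bottom-k / explicit rule);
4. summarize each slide's selected-cluster patch likelihoods as a Patch
   Likelihood Histogram (PLH) and a TF-IDF bag-of-words vector;
5. variance-ordered greedy correlation filtering (|r| < 0.8, top 32);
6. fit an SVM-RBF / KNN / random-forest slide classifier and evaluate
   accuracy, ROC AUC, confusion matrix and decision-curve net benefit,
   with and without region selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplitConfig",
    "VoteConfig",
    "SelectionRule",
    "SlideBag",
    "EvalReport",
    "SiliconDataset",
    "split_cases",
    "train_patch_classifier",
    "majority_vote",
    "cluster_accuracy_table",
    "select_clusters",
    "plh_features",
    "bow_features",
    "correlation_filter",
    "fit_slide_classifier",
    "evaluate",
    "run_silicon_pipeline",
]


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.8
    seed: int = 666

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class VoteConfig:
    positive_fraction_threshold: float = 0.5  # strictly greater wins

    def __post_init__(self):
        if not 0 < self.positive_fraction_threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class SelectionRule:
    mode: str = "bottom_k"  # threshold | bottom_k | explicit
    value: object = 2

    def __post_init__(self):
        if self.mode not in ("threshold", "bottom_k", "explicit"):
            raise ValueError(f"unknown selection mode {self.mode!r}")


@dataclass
class SlideBag:
    slide_id: str
    label: int
    likelihoods: np.ndarray  # patch positive-class probabilities, selected clusters
    coords: np.ndarray       # (n, 2) grid row/col per patch

    def __post_init__(self):
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if len(self.likelihoods) < 1:
            raise ValueError("a slide bag needs at least one patch")
        if np.any(self.likelihoods < 0) or np.any(self.likelihoods > 1):
            raise ValueError("likelihoods must be in [0, 1]")


@dataclass
class EvalReport:
    accuracy: float
    auc: float
    confusion: dict[str, int]              # TP / FP / TN / FN
    net_benefit: pd.DataFrame = field(repr=False)
    predictions: pd.DataFrame = field(repr=False)


@dataclass
class SiliconDataset:
    """Patch features with cluster assignments, slide labels and case ids."""

    features: np.ndarray    # n_patches x d
    slide_ids: np.ndarray   # per patch
    clusters: np.ndarray    # per patch cluster id
    coords: np.ndarray      # per patch (row, col)
    labels: dict[str, int]  # slide -> {0, 1}
    cases: dict[str, str]   # slide -> case

    def patch_mask(self, slides, cluster_ids=None) -> np.ndarray:
        mask = np.isin(self.slide_ids, list(slides))
        if cluster_ids is not None:
            mask &= np.isin(self.clusters, list(cluster_ids))
        return mask

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.clusters))


# ---------------------------------------------------------------------------
# splitting and patch classifiers
# ---------------------------------------------------------------------------

def split_cases(case_labels: dict[str, int], cfg: SplitConfig = SplitConfig()):
    """Case-level stratified split: all slides of a case stay on one side."""
    by_class: dict[int, list[str]] = {}
    for case, label in sorted(case_labels.items()):
        by_class.setdefault(int(label), []).append(case)
    if any(len(v) < 2 for v in by_class.values()) or len(by_class) < 2:
        raise ValueError("need at least 2 cases per class")
    rng = np.random.default_rng(cfg.seed)
    train, test = [], []
    for label in sorted(by_class):
        cases = by_class[label]
        order = rng.permutation(len(cases))
        n_train = int(round(cfg.train_fraction * len(cases)))
        n_train = min(max(n_train, 1), len(cases) - 1)
        train.extend(cases[i] for i in order[:n_train])
        test.extend(cases[i] for i in order[n_train:])
    return sorted(train), sorted(test)


class LogisticPatchTrainer:
    """Default desk-scale trainer: standardized logistic regression on patch
    embeddings. Any trainer returning an object with ``predict_proba1`` works
    (a CNN fine-tuner satisfies the same contract)."""

    def __init__(self, seed: int = 666, C: float = 1.0):
        self.seed = seed
        self.C = C

    def __call__(self, X: np.ndarray, y: np.ndarray):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, max_iter=2000, random_state=self.seed),
        ).fit(X, y)

        class _Wrapped:
            def predict_proba1(self, Xq):
                return model.predict_proba(Xq)[:, 1]

            def predict(self, Xq):
                return model.predict(Xq)

        return _Wrapped()


def train_patch_classifier(X: np.ndarray, y: np.ndarray, trainer=None):
    """Patch-level probability model from slide-inherited (weak) labels."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("patch training set contains a single class")
    trainer = trainer or LogisticPatchTrainer()
    return trainer(np.asarray(X, dtype=float), y)


# ---------------------------------------------------------------------------
# voting, selection
# ---------------------------------------------------------------------------

def majority_vote(patch_predictions, cfg: VoteConfig = VoteConfig()) -> int:
    """1 iff strictly more than the threshold fraction of patches are 1."""
    preds = np.asarray(patch_predictions, dtype=int)
    if preds.size == 0:
        raise ValueError("empty patch prediction set")
    return int(np.mean(preds == 1) > cfg.positive_fraction_threshold)


def cluster_accuracy_table(models: dict[int, object], dataset: SiliconDataset,
                           validation_slides, cfg: VoteConfig = VoteConfig(),
                           backbone: str = "default") -> pd.DataFrame:
    """Slide-level voting accuracy of each cluster's patch model.

    For every cluster with a model, each validation slide's patches in that
    cluster are classified and majority-voted into a slide label; accuracy
    is against the true slide labels. Clusters with no validation patches
    get a missing accuracy.
    """
    rows = []
    for cluster_id in sorted(models):
        model = models[cluster_id]
        correct, total = 0, 0
        for slide in validation_slides:
            mask = dataset.patch_mask([slide], [cluster_id])
            if not mask.any():
                continue
            preds = (model.predict_proba1(dataset.features[mask]) > 0.5).astype(int)
            vote = majority_vote(preds, cfg)
            correct += int(vote == dataset.labels[slide])
            total += 1
        acc = correct / total if total else np.nan
        rows.append({"cluster": cluster_id, "backbone": backbone,
                     "accuracy": acc, "n_slides": total})
    return pd.DataFrame(rows)


def select_clusters(acc: pd.DataFrame, rule: SelectionRule = SelectionRule()) -> list[int]:
    """Keep informative clusters: accuracy threshold, drop the bottom k, or
    an explicit (pathologist-informed) id list. Never returns an empty set."""
    if acc.empty:
        raise ValueError("empty cluster accuracy table")
    mean_acc = acc.groupby("cluster")["accuracy"].mean()
    if rule.mode == "explicit":
        selected = [int(c) for c in rule.value if c in mean_acc.index]
    elif rule.mode == "threshold":
        selected = [int(c) for c, a in mean_acc.items() if a >= rule.value]
    else:  # bottom_k
        k = int(rule.value)
        order = mean_acc.sort_values(kind="stable")
        dropped = set(order.index[:min(k, len(order) - 1)])
        selected = [int(c) for c in mean_acc.index if c not in dropped]
    if not selected:
        raise ValueError("selection rule would drop every cluster")
    return sorted(selected)


# ---------------------------------------------------------------------------
# MIL fusion features
# ---------------------------------------------------------------------------

def plh_features(bag: SlideBag, n_bins: int = 10) -> np.ndarray:
    """Patch likelihood histogram: equal-width bins on [0, 1] (a likelihood
    of exactly 1.0 falls in the last bin), normalized to sum to 1."""
    if len(bag.likelihoods) == 0:
        raise ValueError("empty slide bag")
    counts, _ = np.histogram(bag.likelihoods, bins=n_bins, range=(0.0, 1.0))
    return counts / counts.sum()


def _word_indices(likelihoods: np.ndarray, n_words: int) -> np.ndarray:
    idx = np.floor(likelihoods * n_words).astype(int)
    return np.clip(idx, 0, n_words - 1)


def bow_features(training_bags: list[SlideBag], bag: SlideBag,
                 n_words: int = 16) -> np.ndarray:
    """TF-IDF over discretized-likelihood words.

    Words are the indices of ``n_words`` equal-width likelihood bins.
    tf = word count / bag size; idf = ln((1 + N) / (1 + n_w)) + 1 with the
    document frequency n_w counted on the training bags only, so a word
    present in every training slide has idf exactly 1.
    """
    if not training_bags:
        raise ValueError("empty training corpus")
    N = len(training_bags)
    df = np.zeros(n_words)
    for tb in training_bags:
        df[np.unique(_word_indices(tb.likelihoods, n_words))] += 1
    idf = np.log((1.0 + N) / (1.0 + df)) + 1.0
    words = _word_indices(bag.likelihoods, n_words)
    tf = np.bincount(words, minlength=n_words) / len(words)
    return tf * idf


def correlation_filter(features: np.ndarray, r_threshold: float = 0.8,
                       max_features: int = 32) -> list[int]:
    """Greedy redundancy filter: visit features by decreasing variance, keep
    one iff |Pearson r| with every kept feature is below the threshold, stop
    at ``max_features``. Zero-variance features are never kept."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 slides")
    var = X.var(axis=0)
    if np.all(var == 0):
        raise ValueError("all features have zero variance")
    order = np.argsort(-var, kind="stable")
    kept: list[int] = []
    for j in order:
        if var[j] == 0 or len(kept) >= max_features:
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if abs(r) >= r_threshold:
                ok = False
                break
        if ok:
            kept.append(int(j))
    return kept


# ---------------------------------------------------------------------------
# slide classifiers and evaluation
# ---------------------------------------------------------------------------

def fit_slide_classifier(features: np.ndarray, labels, model: str = "svm_rbf",
                         seed: int = 666):
    """Fixed-hyperparameter probabilistic slide classifier.

    svm_rbf: C=1, gamma=1/d, Platt-scaled probabilities; knn: k=5 distance
    weighted; random_forest: 500 seeded trees.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("slide training set contains a single class")
    if model == "svm_rbf":
        clf = make_pipeline(StandardScaler(),
                            SVC(C=1.0, gamma="auto", kernel="rbf",
                                probability=True, random_state=seed))
    elif model == "knn":
        n_neighbors = min(5, len(y) - 1)
        clf = make_pipeline(StandardScaler(),
                            KNeighborsClassifier(n_neighbors=n_neighbors, weights="distance"))
    elif model == "random_forest":
        clf = RandomForestClassifier(n_estimators=500, random_state=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    with warnings.catch_warnings():
        # Platt-scaled SVC emits a deprecation notice on recent sklearn;
        # the behavior is unchanged for the pinned usage here.
        warnings.simplefilter("ignore", FutureWarning)
        return clf.fit(np.asarray(features, dtype=float), y)


def net_benefit_curve(labels: np.ndarray, scores: np.ndarray,
                      thresholds=None) -> pd.DataFrame:
    """Decision-curve net benefit NB(p_t) = TP/N - FP/N * p_t / (1 - p_t),
    classifying positive at score >= p_t, with treat-all and treat-none
    references."""
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        pred = scores >= pt
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        odds = pt / (1.0 - pt)
        rows.append({
            "p_t": pt,
            "model": tp / n - fp / n * odds,
            "treat_all": prevalence - (1.0 - prevalence) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def evaluate(scores: np.ndarray, labels, slide_ids=None) -> EvalReport:
    """Accuracy at 0.5, trapezoidal ROC AUC, confusion matrix and net benefit."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation needs both classes")
    pred = (scores > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    predictions = pd.DataFrame({
        "slide_id": slide_ids if slide_ids is not None else np.arange(len(labels)),
        "label": labels, "score": scores, "prediction": pred,
    })
    return EvalReport(
        accuracy=float(np.mean(pred == labels)),
        auc=float(roc_auc_score(labels, scores)),
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        net_benefit=net_benefit_curve(labels, scores),
        predictions=predictions,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _slide_bags(dataset: SiliconDataset, slides, selected, patch_model) -> list[SlideBag]:
    bags = []
    for slide in slides:
        mask = dataset.patch_mask([slide], selected)
        if not mask.any():
            # a slide with no patch in the selected regions falls back to
            # its full patch set rather than being dropped
            warnings.warn(f"slide {slide} has no patch in selected clusters; using all patches")
            mask = dataset.patch_mask([slide])
        bags.append(SlideBag(
            slide_id=slide, label=dataset.labels[slide],
            likelihoods=patch_model.predict_proba1(dataset.features[mask]),
            coords=dataset.coords[mask],
        ))
    return bags


def _fusion_matrix(train_bags: list[SlideBag], bags: list[SlideBag],
                   n_bins: int, n_words: int) -> np.ndarray:
    return np.vstack([
        np.concatenate([plh_features(b, n_bins), bow_features(train_bags, b, n_words)])
        for b in bags
    ])


def risk_heatmap(bag: SlideBag, grid_shape: tuple[int, int]) -> np.ndarray:
    """Patch probabilities mapped back to grid coordinates (NaN = no patch)."""
    heat = np.full(grid_shape, np.nan)
    for (row, col), p in zip(bag.coords.astype(int), bag.likelihoods):
        heat[row, col] = p
    return heat


def run_silicon_pipeline(dataset: SiliconDataset,
                         rule: SelectionRule = SelectionRule(),
                         split_cfg: SplitConfig = SplitConfig(),
                         vote_cfg: VoteConfig = VoteConfig(),
                         slide_model: str = "svm_rbf",
                         n_bins: int = 10, n_words: int = 16,
                         r_threshold: float = 0.8, max_features: int = 32,
                         seed: int = 666, trainer=None) -> dict:
    """Run the MIL fusion chain twice — with cluster selection and with all
    clusters — on the same case split and seeds; return paired reports,
    the cluster accuracy table, selected clusters, and per-slide heatmaps.
    """
    case_labels = {}
    for slide, case in dataset.cases.items():
        case_labels[case] = dataset.labels[slide]
    train_cases, test_cases = split_cases(case_labels, split_cfg)
    slides_of = lambda cases: sorted(s for s, c in dataset.cases.items() if c in set(cases))
    train_slides, test_slides = slides_of(train_cases), slides_of(test_cases)

    # inner case split of the training cohort for cluster screening
    inner_cfg = SplitConfig(train_fraction=0.75, seed=split_cfg.seed + 1)
    fit_cases, val_cases = split_cases({c: case_labels[c] for c in train_cases}, inner_cfg)
    fit_slides, val_slides = slides_of(fit_cases), slides_of(val_cases)

    trainer = trainer or LogisticPatchTrainer(seed=seed)
    patch_labels = np.array([dataset.labels[s] for s in dataset.slide_ids])

    models = {}
    for cluster_id in dataset.cluster_ids:
        mask = dataset.patch_mask(fit_slides, [cluster_id])
        if mask.sum() < 4 or len(np.unique(patch_labels[mask])) < 2:
            continue
        models[cluster_id] = train_patch_classifier(
            dataset.features[mask], patch_labels[mask], trainer)
    acc = cluster_accuracy_table(models, dataset, val_slides, vote_cfg)
    selected = select_clusters(acc, rule)

    arms = {}
    for arm, clusters in (("selection", selected), ("no_selection", dataset.cluster_ids)):
        mask = dataset.patch_mask(train_slides, clusters)
        patch_model = train_patch_classifier(dataset.features[mask], patch_labels[mask], trainer)
        train_bags = _slide_bags(dataset, train_slides, clusters, patch_model)
        test_bags = _slide_bags(dataset, test_slides, clusters, patch_model)
        Xtr = _fusion_matrix(train_bags, train_bags, n_bins, n_words)
        Xte = _fusion_matrix(train_bags, test_bags, n_bins, n_words)
        kept = correlation_filter(Xtr, r_threshold, max_features)
        clf = fit_slide_classifier(Xtr[:, kept], [b.label for b in train_bags],
                                   model=slide_model, seed=seed)
        test_scores = clf.predict_proba(Xte[:, kept])[:, 1]
        report = evaluate(test_scores, [b.label for b in test_bags],
                          slide_ids=[b.slide_id for b in test_bags])
        grid = (int(dataset.coords[:, 0].max()) + 1, int(dataset.coords[:, 1].max()) + 1)
        heatmaps = {b.slide_id: risk_heatmap(b, grid) for b in test_bags}
        arms[arm] = {"report": report, "clusters": list(clusters),
                     "kept_features": kept, "heatmaps": heatmaps}

    return {"cluster_accuracy": acc, "selected_clusters": selected,
            "train_slides": train_slides, "test_slides": test_slides,
            "selection": arms["selection"], "no_selection": arms["no_selection"]}
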