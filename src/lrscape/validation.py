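"""Replicated planted-signal experiments exercising the full pipeline.

These runners define the synthetic study conditions used to validate the
screening cascade and the Silicon region-selection strategy; the test suite
and the results-reproduction script both call them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import histoprep, silicon
from .lrpairs import (CutoffSearchConfig, RsfConfig, fit_penalized_cox,
                      rsf_importance, screen_pairs)
from .syndata import (BulkCohortSpec, SyntheticWsiSpec, WsiDataset,
                      gen_bulk_cohort, gen_synthetic_wsis)

__all__ = [
    "cascade_recovery_experiment",
    "build_silicon_dataset",
    "silicon_benefit_experiment",
]


# study conditions: 2 planted pairs (log-HR 1 per sd) among 30 noise pairs,
# n = 300, moderate censoring
CASCADE_SPEC = dict(n_samples=300, n_pairs=32, n_prognostic=2,
                    effect_sizes=(1.0, 1.0), censoring_rate=0.4)


def run_cascade(spec: BulkCohortSpec, alpha: float = 0.05, ntree: int = 300,
                seed: int = 666):
    """screen -> importance filter -> penalized Cox on one synthetic cohort.

    Returns ``(model, cohort, screened_names, retained_names)``; the model is
    None when a stage leaves too few pairs to continue.
    """
    cohort = gen_bulk_cohort(spec)
    screened = screen_pairs(cohort.scores, cohort.os, cohort.pfi,
                            CutoffSearchConfig(), alpha=alpha, seed=seed)
    names = [r.pair for r in screened]
    if not names:
        return None, cohort, names, []
    sub = cohort.scores.restrict(names)
    if len(names) >= 2:
        table = rsf_importance(sub, cohort.os, RsfConfig(ntree=ntree, seed=seed))
        retained = sorted(table.index[table.retained])
    else:
        retained = names
    if not retained:
        return None, cohort, names, retained
    model = fit_penalized_cox(cohort.scores.restrict(retained), cohort.os,
                              n_folds=5, seed=seed)
    return model, cohort, names, retained


def cascade_recovery_experiment(seed: int = 1, n_reps: int = 20,
                                ntree: int = 300) -> dict:
    """Fraction of replicates where the cascade's final model gives both
    planted pairs a nonzero coefficient of the correct (positive) sign."""
    successes = 0
    screened_hits = 0
    for rep in range(n_reps):
        spec = BulkCohortSpec(seed=seed * 10_000 + rep, **CASCADE_SPEC)
        model, cohort, screened, _ = run_cascade(spec, seed=seed * 10_000 + rep)
        planted = set(cohort.prognostic_pairs)
        if planted <= set(screened):
            screened_hits += 1
        if model is not None and all(
                model.coefficients.get(p, 0.0) > 0 for p in planted):
            successes += 1
    return {"recovery_rate": successes / n_reps,
            "screen_hit_rate": screened_hits / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Silicon benefit on synthetic slides
# ---------------------------------------------------------------------------

# study conditions: ~60 slides of 16 tiles, 2 informative + 2 pure-noise
# texture classes; tiles rendered at 96 px (texture statistics are
# resolution-free; see the methods note)
WSI_SPEC = dict(n_slides=60, tiles_per_side=4, tile_px=96, n_classes=4,
                informative_classes=(0, 1))


@dataclass
class SiliconRun:
    selection_accuracy: float
    no_selection_accuracy: float
    selection_auc: float
    no_selection_auc: float
    noise_cluster_accuracies: list[float]
    selected_clusters: list[int]


def build_silicon_dataset(wsi: WsiDataset, embedder=None,
                          use_true_classes: bool = True,
                          n_components: int = 32, k: int | None = None,
                          seed: int = 666) -> silicon.SiliconDataset:
    """Embed every tile of a synthetic slide set into a SiliconDataset.

    With ``use_true_classes`` the generator's ground-truth class map serves
    as the cluster assignment; otherwise patches are PCA-reduced and K-means
    clustered into ``k`` morphological clusters.
    """
    embedder = embedder or histoprep.HandcraftedEmbedder()
    keys, feats, clusters, coords = [], [], [], []
    for slide_id in wsi.slide_ids:
        for row, col, class_id, pixels in wsi.tiles(slide_id):
            keys.append(slide_id)
            feats.append(embedder(pixels))
            clusters.append(class_id)
            coords.append((row, col))
    features = np.vstack(feats)
    clusters = np.asarray(clusters)
    if not use_true_classes:
        fm = histoprep.FeatureMatrix(keys=list(zip(keys, *np.asarray(coords).T)), values=features)
        reduced, _ = histoprep.reduce_features(fm, n_components=n_components, seed=seed)
        model = histoprep.cluster_patches(reduced, k=k or wsi.spec.n_classes, seed=seed)
        clusters = np.array([model.assignment[key] for key in fm.keys])
        features = reduced.values
    return silicon.SiliconDataset(
        features=features, slide_ids=np.asarray(keys), clusters=clusters,
        coords=np.asarray(coords), labels=wsi.labels, cases=wsi.cases)


def silicon_benefit_experiment(seed: int = 1, n_reps: int = 10) -> dict:
    """Selection vs no-selection arms over replicated synthetic cohorts.

    Success in a replicate = the selection arm's slide accuracy is at least
    the no-selection arm's. Also pools the voting accuracies of the
    pure-noise texture classes (expected near chance).
    """
    wins = 0
    noise_accs: list[float] = []
    runs: list[SiliconRun] = []
    for rep in range(n_reps):
        rep_seed = seed * 10_000 + rep
        wsi = gen_synthetic_wsis(SyntheticWsiSpec(seed=rep_seed, **WSI_SPEC))
        dataset = build_silicon_dataset(wsi)
        result = silicon.run_silicon_pipeline(
            dataset, rule=silicon.SelectionRule("bottom_k", 2),
            split_cfg=silicon.SplitConfig(seed=rep_seed), seed=rep_seed)
        sel = result["selection"]["report"]
        nosel = result["no_selection"]["report"]
        acc_table = result["cluster_accuracy"].set_index("cluster")["accuracy"]
        noise = [float(acc_table[c]) for c in acc_table.index
                 if c not in wsi.spec.informative_classes and np.isfinite(acc_table[c])]
        noise_accs.extend(noise)
        runs.append(SiliconRun(sel.accuracy, nosel.accuracy, sel.auc, nosel.auc,
                               noise, result["selected_clusters"]))
        if sel.accuracy >= nosel.accuracy:
            wins += 1
    return {
        "benefit_rate": wins / n_reps,
        "mean_selection_accuracy": float(np.mean([r.selection_accuracy for r in runs])),
        "mean_no_selection_accuracy": float(np.mean([r.no_selection_accuracy for r in runs])),
        "mean_selection_auc": float(np.mean([r.selection_auc for r in runs])),
        "mean_noise_cluster_accuracy": float(np.mean(noise_accs)) if noise_accs else float("nan"),
        "n_reps": n_reps,
        "runs": runs,
    }
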