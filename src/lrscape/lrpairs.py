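"""Ligand-receptor pair scoring and survival screening from bulk expression.

The screening cascade mirrors a common prognostic-signature workflow for
bulk tumor cohorts:

1. score each ligand-receptor pair per sample (geometric mean of the two
   genes' normalized expression — "both sides expressed" semantics);
2. dichotomize each pair at the optimal cutpoint (maximally selected
   log-rank statistic, group fractions restricted to [0.3, 0.7]) for two
   endpoints, overall survival (OS) and progression-free interval (PFI),
   and keep pairs significant for BOTH with an agreeing hazard direction;
3. rank the survivors with random-survival-forest permutation importance;
4. fit an L1-penalized Cox model over the retained pairs, with the penalty
   chosen at minimum cross-validated partial-likelihood deviance.

The maximally selected statistic is computed as a standardized linear rank
statistic with log-rank (martingale) scores; its p-value comes from a
seeded permutation null of the survival labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = [
    "LRPair",
    "ExpressionMatrix",
    "PairScoreMatrix",
    "SurvivalTable",
    "CutoffSearchConfig",
    "CutoffResult",
    "RsfConfig",
    "PenalizedCoxModel",
    "compute_pair_scores",
    "logrank_scores",
    "best_cutoff",
    "screen_pairs",
    "rsf_importance",
    "fit_penalized_cox",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor gene pair, named ``LIGAND_RECEPTOR``."""

    ligand_gene: str
    receptor_gene: str

    @property
    def name(self) -> str:
        return f"{self.ligand_gene}_{self.receptor_gene}"

    @classmethod
    def from_name(cls, name: str) -> "LRPair":
        ligand, _, receptor = name.partition("_")
        if not ligand or not receptor:
            raise ValueError(f"pair name {name!r} is not LIGAND_RECEPTOR")
        return cls(ligand, receptor)


class ExpressionMatrix:
    """Non-negative normalized expression, genes x samples."""

    def __init__(self, values, genes, samples):
        values = np.asarray(values, dtype=float)
        genes = list(genes)
        samples = list(samples)
        if values.shape != (len(genes), len(samples)):
            raise ValueError("expression shape does not match gene/sample ids")
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("expression must be finite and non-negative")
        self.values = values
        self.genes = genes
        self.samples = samples
        self._gene_index = {g: i for i, g in enumerate(genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(), frame.index, frame.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


class PairScoreMatrix:
    """Per-sample activity score for each ligand-receptor pair."""

    def __init__(self, values, pairs, samples, dropped_pairs=()):
        values = np.asarray(values, dtype=float)
        self.pairs = [p if isinstance(p, LRPair) else LRPair.from_name(p) for p in pairs]
        self.samples = list(samples)
        if values.shape != (len(self.pairs), len(self.samples)):
            raise ValueError("score shape does not match pair/sample ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("pair scores must be finite")
        self.values = values
        self.dropped_pairs = list(dropped_pairs)
        self._pair_index = {p.name: i for i, p in enumerate(self.pairs)}
        if len(self._pair_index) != len(self.pairs):
            raise ValueError("pair names must be unique")

    @property
    def pair_names(self) -> list[str]:
        return [p.name for p in self.pairs]

    def row(self, pair_name: str) -> np.ndarray:
        return self.values[self._pair_index[pair_name]]

    def restrict(self, pair_names) -> "PairScoreMatrix":
        idx = [self._pair_index[n] for n in pair_names]
        return PairScoreMatrix(self.values[idx], [self.pairs[i] for i in idx], self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pair_names, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairScoreMatrix":
        return cls(frame.to_numpy(), frame.index, frame.columns)


@dataclass
class SurvivalTable:
    """Right-censored time-to-event data for one endpoint (OS or PFI)."""

    sample: np.ndarray
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self):
        self.sample = np.asarray(self.sample)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample) == len(self.time) == len(self.event)):
            raise ValueError("sample/time/event lengths differ")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.time)

    def reindex(self, samples) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample)}
        try:
            idx = [pos[s] for s in samples]
        except KeyError as exc:
            raise ValueError(f"sample {exc.args[0]!r} missing from survival table") from None
        return SurvivalTable(np.asarray(samples), self.time[idx], self.event[idx], self.endpoint)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample, "time": self.time, "event": self.event})


@dataclass(frozen=True)
class CutoffSearchConfig:
    minprop: float = 0.3
    maxprop: float = 0.7
    method: str = "log-rank"
    n_permutations: int = 1000

    def __post_init__(self):
        if not (0 < self.minprop <= self.maxprop < 1):
            raise ValueError("need 0 < minprop <= maxprop < 1")


@dataclass
class CutoffResult:
    pair: str | None
    cutoff: float
    max_logrank_stat: float
    p_value: float
    direction: str  # "favorable" | "unfavorable" for the high-score group
    p_os: float | None = None
    p_pfi: float | None = None


@dataclass(frozen=True)
class RsfConfig:
    ntree: int = 1000
    seed: int = 666
    importance_threshold: float = 0.3
    n_repeats: int = 3
    min_samples_leaf: int = 15

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


@dataclass
class PenalizedCoxModel:
    """L1-penalized Cox model over pair scores; eta_i = sum_k beta_k s_ki."""

    coefficients: dict[str, float]
    lambda_: float
    cv_deviance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def pair_names(self) -> list[str]:
        return list(self.coefficients)

    def to_json_dict(self) -> dict:
        return {"lambda": self.lambda_, "coefficients": dict(self.coefficients)}


# ---------------------------------------------------------------------------
# pair scoring
# ---------------------------------------------------------------------------

def compute_pair_scores(expr: ExpressionMatrix, pairs) -> PairScoreMatrix:
    """Score each pair as sqrt(ligand * receptor) per sample.

    Pairs whose ligand or receptor gene is absent from ``expr`` are dropped
    and listed in the result's ``dropped_pairs``.
    """
    pairs = [p if isinstance(p, LRPair) else LRPair.from_name(p) for p in pairs]
    kept, dropped, rows = [], [], []
    for pair in pairs:
        if pair.ligand_gene in expr and pair.receptor_gene in expr:
            kept.append(pair)
            rows.append(np.sqrt(expr.row(pair.ligand_gene) * expr.row(pair.receptor_gene)))
        else:
            dropped.append(pair)
    if not kept:
        raise ValueError("no ligand-receptor pair has both genes in the expression matrix")
    return PairScoreMatrix(np.vstack(rows), kept, expr.samples, dropped_pairs=dropped)


# ---------------------------------------------------------------------------
# maximally selected log-rank cutpoint
# ---------------------------------------------------------------------------

def logrank_scores(time, event) -> np.ndarray:
    """Log-rank (martingale) scores a_i = event_i - NelsonAalen(t_i).

    The scores sum to zero exactly; a positive score marks an earlier-than-
    expected event, a negative score a long censored follow-up.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    unique_t, inverse = np.unique(time, return_inverse=True)
    deaths = np.bincount(inverse, weights=event.astype(float), minlength=len(unique_t))
    counts = np.bincount(inverse, minlength=len(unique_t))
    n_at_risk = len(time) - np.concatenate(([0], np.cumsum(counts)[:-1]))
    cumhaz = np.cumsum(deaths / n_at_risk)
    return event - cumhaz[inverse]


def _standardized_scan(a_sorted_cumsum: np.ndarray, sigma2: float, n: int) -> np.ndarray:
    """Z_k for low group = first k+1 samples in score order, all k."""
    m = np.arange(1, n + 1, dtype=float)
    var = m * (n - m) / (n - 1) * sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, a_sorted_cumsum / np.sqrt(var), 0.0)
    return z


def _admissible_split_indices(s_sorted: np.ndarray, minprop: float, maxprop: float) -> np.ndarray:
    """Indices k such that the split low = {score <= s_sorted[k]} is admissible.

    Candidate cutoffs sit at the last occurrence of each distinct score value
    (excluding the largest, which would leave the high group empty).
    """
    n = len(s_sorted)
    last_of_value = np.nonzero(np.diff(s_sorted) > 0)[0]
    frac = (last_of_value + 1) / n
    return last_of_value[(frac >= minprop) & (frac <= maxprop)]


def best_cutoff(scores, surv: SurvivalTable, cfg: CutoffSearchConfig = CutoffSearchConfig(),
                seed: int = 0, pair: str | None = None) -> CutoffResult:
    """Optimal dichotomizing cutpoint by the maximally selected log-rank statistic.

    Evaluates the standardized two-sample log-rank statistic (linear rank
    statistic with log-rank scores, permutation moments) at every distinct
    score value whose induced split leaves both group fractions within
    ``[minprop, maxprop]``; samples with score equal to the cutoff fall in
    the low group. The p-value is the permutation-null probability that the
    maximal |Z| over admissible splits exceeds the observed one.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(surv):
        raise ValueError("scores and survival table differ in length")
    if len(scores) < 10:
        raise ValueError("need at least 10 samples for cutpoint search")
    # canonical order makes the result independent of input sample order
    canon = np.lexsort((surv.event, surv.time, scores))
    s = scores[canon]
    time = surv.time[canon]
    event = surv.event[canon]

    a = logrank_scores(time, event)
    n = len(a)
    sigma2 = float(np.sum(a**2) / n)
    if sigma2 <= 0:
        raise ValueError("all samples censored: log-rank scores are degenerate")

    splits = _admissible_split_indices(s, cfg.minprop, cfg.maxprop)
    if len(splits) == 0:
        raise ValueError("no admissible cutoff (scores tied within the quantile band)")

    csum = np.cumsum(a)
    z_all = _standardized_scan(csum, sigma2, n)
    z = z_all[splits]
    best = int(np.argmax(np.abs(z)))
    k = int(splits[best])
    observed = float(abs(z[best]))
    direction = "unfavorable" if csum[k] < 0 else "favorable"

    # permutation null: permute the survival scores against the score order
    rng = np.random.default_rng(seed)
    B = cfg.n_permutations
    perm = rng.permuted(np.broadcast_to(np.arange(n), (B, n)).copy(), axis=1)
    csum_perm = np.cumsum(a[perm], axis=1)
    m = np.arange(1, n + 1, dtype=float)
    var = m * (n - m) / (n - 1) * sigma2
    z_perm = np.abs(csum_perm[:, splits]) / np.sqrt(var[splits])
    max_perm = z_perm.max(axis=1)
    p = float((1 + np.sum(max_perm >= observed - 1e-12)) / (B + 1))

    return CutoffResult(pair=pair, cutoff=float(s[k]), max_logrank_stat=observed,
                        p_value=p, direction=direction)


def _pair_seed(seed: int, pair_name: str) -> int:
    """Deterministic per-pair seed, independent of pair ordering."""
    return (int(seed) ^ zlib.crc32(pair_name.encode())) % (2**31 - 1)


def screen_pairs(scores: PairScoreMatrix, os: SurvivalTable, pfi: SurvivalTable,
                 cfg: CutoffSearchConfig = CutoffSearchConfig(), alpha: float = 0.05,
                 seed: int = 666) -> list[CutoffResult]:
    """Keep pairs significant for both OS and PFI with an agreeing direction.

    Returns one :class:`CutoffResult` per retained pair (the OS cutpoint,
    annotated with both endpoint p-values); the favorable/unfavorable label
    partitions the output.
    """
    if set(os.sample) != set(scores.samples) or set(pfi.sample) != set(scores.samples):
        raise ValueError("survival tables and score matrix cover different samples")
    os = os.reindex(scores.samples)
    pfi = pfi.reindex(scores.samples)
    retained: list[CutoffResult] = []
    for pair in scores.pairs:
        row = scores.row(pair.name)
        ps = _pair_seed(seed, pair.name)
        try:
            res_os = best_cutoff(row, os, cfg, seed=ps, pair=pair.name)
            res_pfi = best_cutoff(row, pfi, cfg, seed=ps + 1, pair=pair.name)
        except ValueError:
            continue  # tied scores or degenerate endpoint: not screenable
        if (res_os.p_value <= alpha and res_pfi.p_value <= alpha
                and res_os.direction == res_pfi.direction):
            res_os.p_os = res_os.p_value
            res_os.p_pfi = res_pfi.p_value
            retained.append(res_os)
    retained.sort(key=lambda r: r.pair)
    return retained


# ---------------------------------------------------------------------------
# random survival forest importance
# ---------------------------------------------------------------------------

def rsf_importance(scores: PairScoreMatrix, surv: SurvivalTable,
                   cfg: RsfConfig = RsfConfig()) -> pd.DataFrame:
    """Permutation variable importance from a random survival forest.

    Importance of a pair = drop in concordance when its column is permuted
    (averaged over ``cfg.n_repeats`` permutations). Raw importances are
    clipped at 0 and scaled by the largest one, so the unit-free threshold
    reads "at least this fraction of the top pair's importance"; pairs with
    scaled importance > ``importance_threshold`` are flagged ``retained``.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    if len(scores.pairs) < 2:
        raise ValueError("need at least 2 pairs for importance ranking")
    surv = surv.reindex(scores.samples)
    if surv.event.sum() == 0:
        raise ValueError("all-censored cohort: survival forest is undefined")

    X = scores.values.T.copy()
    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)
    forest = RandomSurvivalForest(
        n_estimators=cfg.ntree, min_samples_leaf=cfg.min_samples_leaf,
        random_state=cfg.seed, n_jobs=1,
    ).fit(X, y)
    baseline = forest.score(X, y)

    rng = np.random.default_rng(cfg.seed)
    raw = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(cfg.n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - forest.score(Xp, y))
        raw[j] = np.mean(drops)

    clipped = np.clip(raw, 0.0, None)
    top = clipped.max()
    scaled = clipped / top if top > 0 else np.zeros_like(raw)
    table = pd.DataFrame({
        "pair": scores.pair_names,
        "importance": raw,
        "importance_scaled": scaled,
        "retained": scaled > cfg.importance_threshold,
    }).set_index("pair")
    return table


# ---------------------------------------------------------------------------
# penalized Cox
# ---------------------------------------------------------------------------

def _cox_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> float:
    """Breslow partial log-likelihood."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time: risk set grows
    eta = eta[order]
    t = time[order]
    e = event[order]
    # log of running sum of exp(eta) over the risk set (numerically stabilized)
    c = eta.max()
    cum = np.cumsum(np.exp(eta - c))
    # samples tied on time share the same risk set: take cum at last tied index
    last_idx = np.arange(len(t))
    for start in range(len(t) - 2, -1, -1):
        if t[start] == t[start + 1]:
            last_idx[start] = last_idx[start + 1]
    log_risk = np.log(cum[last_idx]) + c
    return float(np.sum(e * (eta - log_risk)))


def fit_penalized_cox(scores: PairScoreMatrix, surv: SurvivalTable, n_folds: int = 10,
                      seed: int = 666, alpha: float | None = None,
                      n_alphas: int = 50) -> PenalizedCoxModel:
    """L1-penalized Cox over pair scores, penalty at minimum CV deviance.

    Fits a lasso path with :class:`CoxnetSurvivalAnalysis`; the
    cross-validated partial-likelihood deviance of each penalty uses the
    Verweij-van Houwelingen decomposition (full-data likelihood minus
    training-fold likelihood). Set ``alpha`` to force a penalty and skip CV.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    surv = surv.reindex(scores.samples)
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    X = scores.values.T.copy()
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate design: a pair has constant scores")
    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)

    cv_table = None
    if alpha is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                      alpha_min_ratio=0.01).fit(X, y)
        alphas = path.alphas_
        folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        # the solver may truncate the requested path per fold, so key the
        # deviances on the alphas each fold actually fitted
        dev_by_alpha: dict[float, list[float]] = {float(a): [] for a in alphas}
        for tr, _te in folds.split(X):
            fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas).fit(X[tr], y[tr])
            for a_idx, a in enumerate(fit.alphas_):
                beta = fit.coef_[:, a_idx]
                ll_full = _cox_loglik(X, surv.time, surv.event, beta)
                ll_train = _cox_loglik(X[tr], surv.time[tr], surv.event[tr], beta)
                dev_by_alpha[float(a)].append(-2.0 * (ll_full - ll_train))
        complete = [a for a in dev_by_alpha if len(dev_by_alpha[a]) == n_folds]
        if not complete:
            raise RuntimeError("no penalty value converged in every fold")
        mean_dev = {a: float(np.mean(dev_by_alpha[a])) for a in complete}
        alpha = min(mean_dev, key=mean_dev.get)
        cv_table = pd.DataFrame({"alpha": list(mean_dev), "cv_deviance": list(mean_dev.values())})

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[alpha]).fit(X, y)
    beta = final.coef_[:, 0]
    coefficients = {name: float(b) for name, b in zip(scores.pair_names, beta) if b != 0.0}
    return PenalizedCoxModel(coefficients=coefficients, lambda_=float(alpha), cv_deviance=cv_table)
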