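"""Risk scoring, optimal-cutoff stratification and group comparison.

Applies a pair-coefficient Cox model (freshly fitted or the shipped
published 14-pair signature) to a pair-score matrix, dichotomizes the
linear predictor at the optimal OS cutpoint, and compares the resulting
high/low risk groups with Kaplan-Meier curves and a log-rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .lrpairs import (CutoffSearchConfig, PairScoreMatrix, PenalizedCoxModel,
                      SurvivalTable, best_cutoff)

__all__ = [
    "RiskStratification",
    "GroupComparison",
    "load_published_model",
    "risk_score",
    "stratify",
    "compare_groups",
]


@dataclass
class RiskStratification:
    sample: np.ndarray
    score: np.ndarray
    cutoff: float
    group: np.ndarray  # "high" where score > cutoff, else "low"
    endpoint: str = "OS"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample, "score": self.score, "group": self.group})


@dataclass
class GroupComparison:
    logrank_stat: float
    p_value: float
    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)


def load_published_model() -> PenalizedCoxModel:
    """The published 14-pair L1-Cox signature shipped with the package."""
    text = resources.files("lrscape.data").joinpath("published_lr_cox_model.json").read_text()
    payload = json.loads(text)
    return PenalizedCoxModel(coefficients=payload["coefficients"],
                             lambda_=payload["lambda"] if payload["lambda"] is not None else float("nan"))


def risk_score(scores: PairScoreMatrix, model: PenalizedCoxModel) -> pd.Series:
    """Linear predictor eta_i = sum_k beta_k * s_ki per sample."""
    missing = [p for p in model.pair_names if p not in scores.pair_names]
    if missing:
        raise KeyError(f"pair scores missing for model pairs: {', '.join(missing)}")
    eta = np.zeros(len(scores.samples))
    for name, beta in model.coefficients.items():
        eta += beta * scores.row(name)
    return pd.Series(eta, index=scores.samples, name="risk_score")


def stratify(eta: pd.Series, surv_os: SurvivalTable | None = None,
             cfg: CutoffSearchConfig = CutoffSearchConfig(),
             cutoff: float | None = None, seed: int = 666) -> RiskStratification:
    """Dichotomize the risk score at the optimal OS cutpoint.

    When ``cutoff`` is supplied (test-set mode) it is applied verbatim;
    otherwise the cutpoint maximizing the standardized log-rank statistic
    on ``surv_os`` is used. High-risk means score strictly above the cutoff.
    """
    samples = np.asarray(eta.index)
    values = eta.to_numpy(dtype=float)
    if cutoff is None:
        if surv_os is None:
            raise ValueError("either a survival table or an explicit cutoff is required")
        surv_os = surv_os.reindex(samples)
        res = best_cutoff(values, surv_os, cfg, seed=seed, pair="risk_score")
        cutoff = res.cutoff
    group = np.where(values > cutoff, "high", "low")
    return RiskStratification(sample=samples, score=values, cutoff=float(cutoff), group=group)


def compare_groups(strat: RiskStratification, surv: SurvivalTable) -> GroupComparison:
    """Kaplan-Meier per risk group plus a two-sample log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    surv = surv.reindex(strat.sample)
    high = strat.group == "high"
    if high.all() or not high.any():
        raise ValueError("both risk groups must be non-empty")

    result = logrank_test(surv.time[high], surv.time[~high],
                          event_observed_A=surv.event[high],
                          event_observed_B=surv.event[~high])

    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter().fit(surv.time[mask], surv.event[mask])
        table = km.survival_function_.reset_index()
        table.columns = ["time", "survival"]
        at_risk = [int(np.sum(surv.time[mask] >= t)) for t in table["time"]]
        table["at_risk"] = at_risk
        curves[label] = table
    return GroupComparison(logrank_stat=float(result.test_statistic),
                           p_value=float(result.p_value), km_curves=curves)
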