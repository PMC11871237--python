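"""Spot-level ligand-receptor enrichment and knn colocalization scoring.

Given a spatial slide (spots with coordinates and per-spot ligand/receptor
expression), spots are categorized by membership in the top-20% expression
sets of the ligand and the receptor, and each spot gets an interaction
score: the larger of (own ligand x max receptor among its k=6 nearest
neighbors) and (own receptor x max ligand among neighbors), log1p
transformed and capped at the 95th percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpatialSlide",
    "ColocConfig",
    "ColocResult",
    "categorize_spots",
    "knn_interaction_score",
    "coloc_summary",
    "plot_coloc",
]

CATEGORY_COLORS = {  # the conventional 3-color scheme
    "ligand_high": "#1f77b4",   # blue
    "receptor_high": "#2ca02c", # green
    "BothHigh": "#d62728",      # red
    "none": "#d3d3d3",
}


@dataclass
class SpatialSlide:
    """Spots with coordinates and one ligand/receptor expression vector each."""

    spot_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ligand: np.ndarray
    receptor: np.ndarray
    region: np.ndarray | None = None  # optional per-spot region labels

    def __post_init__(self):
        self.spot_id = np.asarray(self.spot_id)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.receptor = np.asarray(self.receptor, dtype=float)
        n = len(self.spot_id)
        if not all(len(v) == n for v in (self.x, self.y, self.ligand, self.receptor)):
            raise ValueError("spot arrays must share one length")
        if len(set(self.spot_id.tolist())) != n:
            raise ValueError("spot ids must be unique")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if np.any(self.ligand < 0) or np.any(self.receptor < 0):
            raise ValueError("expression must be non-negative")
        if self.region is not None:
            self.region = np.asarray(self.region)
            if len(self.region) != n:
                raise ValueError("region labels length mismatch")

    def __len__(self) -> int:
        return len(self.spot_id)

    def to_frame(self) -> pd.DataFrame:
        d = {"spot_id": self.spot_id, "x": self.x, "y": self.y,
             "ligand": self.ligand, "receptor": self.receptor}
        if self.region is not None:
            d["region"] = self.region
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ligand_col: str = "ligand",
                   receptor_col: str = "receptor") -> "SpatialSlide":
        region = frame["region"].to_numpy() if "region" in frame else None
        return cls(frame["spot_id"].to_numpy(), frame["x"].to_numpy(),
                   frame["y"].to_numpy(), frame[ligand_col].to_numpy(),
                   frame[receptor_col].to_numpy(), region=region)


@dataclass(frozen=True)
class ColocConfig:
    q_high: float = 0.80   # spots above this expression quantile are "high"
    k: int = 6             # nearest neighbors, self excluded
    cap_q: float = 0.95    # percentile cap on the transformed score
    transform: str = "log1p"

    def __post_init__(self):
        if not 0 < self.q_high < 1:
            raise ValueError("q_high must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.cap_q <= 1:
            raise ValueError("cap_q must be in (0, 1]")


@dataclass
class ColocResult:
    spot_id: np.ndarray
    category: np.ndarray        # ligand_high / receptor_high / BothHigh / none
    g: np.ndarray               # raw max-product interaction score
    c: np.ndarray               # log1p-transformed, percentile-capped score
    cap_value: float
    ligand_high: np.ndarray     # boolean membership sets
    receptor_high: np.ndarray
    region: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"spot_id": self.spot_id, "category": self.category, "g": self.g, "c": self.c}
        if self.region is not None:
            d["region"] = self.region
        return pd.DataFrame(d)


def _top_set(values: np.ndarray, q_high: float) -> np.ndarray:
    """Rank rule for "top (1 - q_high) fraction of spots": the ceil((1-q)n)
    largest values, extended to all spots tied with the smallest included one."""
    n = len(values)
    m = math.ceil((1.0 - q_high) * n)
    m = max(min(m, n), 1)
    threshold = np.sort(values)[n - m]
    return values >= threshold


def categorize_spots(slide: SpatialSlide, cfg: ColocConfig = ColocConfig()):
    """Label each spot ligand_high / receptor_high / BothHigh / none.

    Returns ``(category, ligand_high_mask, receptor_high_mask)``; the single
    label uses priority BothHigh > ligand_high > receptor_high.
    """
    if len(slide) < 5:
        raise ValueError("need at least 5 spots")
    if np.all(slide.ligand == 0) and np.all(slide.receptor == 0):
        raise ValueError("both genes are all-zero on this slide")
    lig_high = _top_set(slide.ligand, cfg.q_high)
    rec_high = _top_set(slide.receptor, cfg.q_high)
    category = np.full(len(slide), "none", dtype=object)
    category[rec_high] = "receptor_high"
    category[lig_high] = "ligand_high"
    category[lig_high & rec_high] = "BothHigh"
    return category, lig_high, rec_high


def _knn_indices(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per spot (self excluded), distance ties broken by
    spot index order for cross-platform determinism."""
    n = len(x)
    pts = np.column_stack([x, y])
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    idx = np.empty((n, k), dtype=int)
    order_ids = np.arange(n)
    for i in range(n):
        # lexsort: primary key distance, secondary key spot index
        ordering = np.lexsort((order_ids, d2[i]))
        idx[i] = ordering[:k]
    return idx


def knn_interaction_score(slide: SpatialSlide, cfg: ColocConfig = ColocConfig()) -> ColocResult:
    """Max-product neighbor interaction score with log1p transform and cap.

    For each spot i with neighbor set N(i) (k nearest by Euclidean distance,
    self excluded): g_i = max(L_i * max_{j in N(i)} R_j,
    R_i * max_{j in N(i)} L_j); c_i = min(log1p(g_i), Q) where Q is the
    ``cap_q`` quantile of the transformed scores.
    """
    n = len(slide)
    if n < cfg.k + 1:
        raise ValueError(f"need at least k+1={cfg.k + 1} spots")
    nbr = _knn_indices(slide.x, slide.y, cfg.k)
    max_r = slide.receptor[nbr].max(axis=1)
    max_l = slide.ligand[nbr].max(axis=1)
    g = np.maximum(slide.ligand * max_r, slide.receptor * max_l)
    t = np.log1p(g)
    cap = float(np.quantile(t, cfg.cap_q))
    c = np.minimum(t, cap)
    if n < 5 or (np.all(slide.ligand == 0) and np.all(slide.receptor == 0)):
        # degenerate for enrichment (tiny or silent slide): scores stand alone
        category = np.full(n, "none", dtype=object)
        lig_high = rec_high = np.zeros(n, dtype=bool)
    else:
        category, lig_high, rec_high = categorize_spots(slide, cfg)
    return ColocResult(spot_id=slide.spot_id, category=category, g=g, c=c,
                       cap_value=cap, ligand_high=lig_high, receptor_high=rec_high,
                       region=slide.region)


def coloc_summary(result: ColocResult, regions=None) -> pd.DataFrame:
    """Per-region mean/max capped score and category counts.

    ``regions`` may be per-spot labels, a list of ``(label, declared)`` via a
    pandas Categorical, or None (one global row). Declared regions with no
    spots report count 0 and missing means.
    """
    n = len(result.spot_id)
    if regions is None:
        regions = result.region
    if regions is None:
        regions = np.full(n, "all", dtype=object)
    declared = None
    if isinstance(regions, pd.Categorical):
        declared = list(regions.categories)
        regions = np.asarray(regions)
    regions = np.asarray(regions)
    if len(regions) != n:
        raise ValueError("region labels length mismatch")
    if declared is None:
        declared = sorted(set(regions.tolist()))

    rows = []
    for label in declared:
        mask = regions == label
        count = int(mask.sum())
        row = {"region": label, "n_spots": count,
               "mean_c": float(result.c[mask].mean()) if count else np.nan,
               "max_c": float(result.c[mask].max()) if count else np.nan}
        for cat in ("ligand_high", "receptor_high", "BothHigh", "none"):
            row[f"n_{cat}"] = int(np.sum(result.category[mask] == cat)) if count else 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def plot_coloc(slide: SpatialSlide, result: ColocResult, path=None):
    """Scatter the slide twice: categories (3-color scheme) and capped score."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for cat, color in CATEGORY_COLORS.items():
        mask = result.category == cat
        axes[0].scatter(slide.x[mask], slide.y[mask], s=8, c=color, label=cat)
    axes[0].set_title("enrichment categories")
    axes[0].legend(fontsize=7)
    sc = axes[1].scatter(slide.x, slide.y, s=8, c=result.c, cmap="viridis")
    fig.colorbar(sc, ax=axes[1], label="capped interaction score")
    axes[1].set_title("colocalization score")
    for ax in axes:
        ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
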