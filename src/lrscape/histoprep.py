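"""Whole-slide tiling, stain normalization, patch embedding and clustering.

Slides are cut into non-overlapping 512x512 tiles (configurable); tiles that
are mostly white background (per-pixel mean-RGB brightness above 216) are
discarded. Retained tiles can be stain-normalized against a reference
(sparse non-negative two-stain separation in optical-density space, in the
spirit of structure-preserving color normalization), embedded into a fixed-
dimension feature vector, reduced with PCA, and K-means clustered into
morphological regions.

The default embedder is a deterministic hand-crafted descriptor (color
histograms, gray-level co-occurrence texture and edge statistics); any
callable with a declared output dimension — e.g. a CNN's global-average-pool
features — satisfies the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import sobel

__all__ = [
    "TileConfig",
    "Patch",
    "StainProfile",
    "FeatureMatrix",
    "ClusterModel",
    "tile_slide",
    "estimate_stain_profile",
    "normalize_stain",
    "HandcraftedEmbedder",
    "embed_patches",
    "PcaReducer",
    "reduce_features",
    "cluster_patches",
    "render_cluster_map",
]


@dataclass(frozen=True)
class TileConfig:
    tile_px: int = 512
    brightness_threshold: float = 216.0  # 0-255; above = background pixel
    min_tissue_fraction: float = 0.5

    def __post_init__(self):
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        if not 0 <= self.brightness_threshold <= 255:
            raise ValueError("brightness_threshold must be in [0, 255]")


@dataclass
class Patch:
    slide_id: str
    row: int
    col: int
    pixels: np.ndarray  # (tile_px, tile_px, 3) uint8
    warning: str | None = None

    @property
    def key(self) -> tuple:
        return (self.slide_id, self.row, self.col)


def tile_slide(image: np.ndarray, cfg: TileConfig = TileConfig(),
               slide_id: str = "slide") -> tuple[list[Patch], pd.DataFrame]:
    """Non-overlapping row-major tiling with white-background rejection.

    A tile is rejected when the fraction of pixels brighter than
    ``brightness_threshold`` (per-pixel mean of R, G, B) exceeds
    ``1 - min_tissue_fraction``. Partial edge tiles are discarded. Returns
    the retained patches and a manifest covering the full grid with a
    ``status`` column (retained / background).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    h, w = image.shape[:2]
    px = cfg.tile_px
    if h < px or w < px:
        raise ValueError("image smaller than one tile")
    patches: list[Patch] = []
    records = []
    for row in range(h // px):
        for col in range(w // px):
            block = image[row * px:(row + 1) * px, col * px:(col + 1) * px, :3]
            brightness = block.astype(float).mean(axis=2)
            bg_fraction = float(np.mean(brightness > cfg.brightness_threshold))
            retained = bg_fraction <= 1.0 - cfg.min_tissue_fraction
            records.append({"slide_id": slide_id, "row": row, "col": col,
                            "status": "retained" if retained else "background"})
            if retained:
                patches.append(Patch(slide_id, row, col, block.astype(np.uint8)))
    return patches, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# stain normalization
# ---------------------------------------------------------------------------

@dataclass
class StainProfile:
    """Two-stain basis in optical-density space plus robust concentration scale."""

    basis: np.ndarray       # (2, 3), rows unit-norm, non-negative
    conc_scale: np.ndarray  # (2,), 99th-percentile concentration per stain

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        self.conc_scale = np.asarray(self.conc_scale, dtype=float)
        if self.basis.shape != (2, 3):
            raise ValueError("stain basis must be 2 x 3")


_OD_EPS = 1e-6


def _to_od(pixels: np.ndarray) -> np.ndarray:
    rgb = np.clip(pixels.reshape(-1, 3).astype(float), 1.0, 255.0)
    return -np.log(rgb / 255.0)


def _from_od(od: np.ndarray, shape) -> np.ndarray:
    rgb = 255.0 * np.exp(-od)
    return np.clip(rgb, 0, 255).reshape(shape).astype(np.uint8)


def _order_basis(basis: np.ndarray) -> np.ndarray:
    """Deterministic stain order: most blue-absorbing (eosin-like, high R-OD)
    last; sorted by the ratio of red to blue optical density."""
    ratio = basis[:, 0] / (basis[:, 2] + _OD_EPS)
    return basis[np.argsort(ratio)]


def estimate_stain_profile(pixels: np.ndarray, seed: int = 0,
                           max_pixels: int = 5000) -> StainProfile:
    """Sparse non-negative two-stain basis from one patch.

    Dictionary learning with non-negativity on both the basis and the codes,
    on a subsample of tissue (non-white) pixels in OD space; a fixed
    iteration budget and seeded initialization keep it deterministic.
    """
    from sklearn.decomposition import DictionaryLearning

    od = _to_od(pixels)
    tissue = od[od.sum(axis=1) > 0.15]
    if len(tissue) < 20 or np.linalg.matrix_rank(np.cov(tissue.T)) < 2:
        raise ValueError("degenerate patch: not enough stain variation")
    rng = np.random.default_rng(seed)
    if len(tissue) > max_pixels:
        tissue = tissue[rng.choice(len(tissue), max_pixels, replace=False)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dl = DictionaryLearning(n_components=2, positive_code=True, positive_dict=True,
                                fit_algorithm="cd", transform_algorithm="lasso_cd",
                                alpha=0.1, max_iter=60, tol=1e-4, random_state=seed)
        dl.fit(tissue)
    basis = dl.components_
    norms = np.linalg.norm(basis, axis=1, keepdims=True)
    basis = np.abs(basis) / np.maximum(norms, _OD_EPS)
    basis = _order_basis(basis)
    conc = _concentrations(od, basis)
    scale = np.percentile(conc, 99, axis=0)
    return StainProfile(basis=basis, conc_scale=np.maximum(scale, _OD_EPS))


def _concentrations(od: np.ndarray, basis: np.ndarray) -> np.ndarray:
    sol, *_ = np.linalg.lstsq(basis.T, od.T, rcond=None)
    return np.clip(sol.T, 0.0, None)


def normalize_stain(patch: Patch, reference: StainProfile, seed: int = 0) -> tuple[Patch, np.ndarray]:
    """Map a patch's stain concentrations onto a reference profile.

    Returns the recomposed 8-bit patch (for visualization) and the
    per-channel z-scored float image (the embedding input). Degenerate
    single-color patches pass through unchanged with a warning flag.
    """
    try:
        own = estimate_stain_profile(patch.pixels, seed=seed)
    except ValueError as exc:
        z = _zscore_channels(patch.pixels)
        return Patch(patch.slide_id, patch.row, patch.col, patch.pixels,
                     warning=str(exc)), z
    od = _to_od(patch.pixels)
    conc = _concentrations(od, own.basis)
    conc *= reference.conc_scale / own.conc_scale
    od_new = conc @ reference.basis
    pixels = _from_od(od_new, patch.pixels.shape)
    out = Patch(patch.slide_id, patch.row, patch.col, pixels)
    return out, _zscore_channels(pixels)


def _zscore_channels(pixels: np.ndarray) -> np.ndarray:
    x = pixels.astype(float)
    mean = x.reshape(-1, 3).mean(axis=0)
    std = x.reshape(-1, 3).std(axis=0)
    return (x - mean) / np.maximum(std, 1e-8)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

class HandcraftedEmbedder:
    """Deterministic 56-d patch descriptor: per-channel color histograms,
    HSV moments, gray-level co-occurrence texture and edge statistics.

    A drop-in stand-in for a CNN global-average-pool embedding: any callable
    mapping a (H, W, 3) uint8 array to a fixed-length vector works.
    """

    dim = 56

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        x = np.asarray(pixels)
        feats = []
        for ch in range(3):  # 3 x 8 = 24 color histogram bins
            hist, _ = np.histogram(x[..., ch], bins=8, range=(0, 256))
            feats.append(hist / hist.sum())
        hsv = rgb2hsv(x)
        feats.append(hsv.reshape(-1, 3).mean(axis=0))  # 3
        feats.append(hsv.reshape(-1, 3).std(axis=0))   # 3
        gray = (rgb2gray(x) * 255).astype(np.uint8)
        glcm = graycomatrix(gray // 16, distances=[1, 4], angles=[0, np.pi / 2],
                            levels=16, symmetric=True, normed=True)
        for prop in ("contrast", "homogeneity", "energy", "correlation"):
            feats.append(graycoprops(glcm, prop).ravel())  # 4 x 4 = 16
        edges = sobel(gray.astype(float) / 255.0)
        hist, _ = np.histogram(edges, bins=8, range=(0, 0.5))
        feats.append(hist / max(hist.sum(), 1))  # 8
        feats.append([float(edges.mean()), float(edges.std())])  # 2
        vec = np.concatenate([np.atleast_1d(np.asarray(f, dtype=float)) for f in feats])
        assert vec.shape == (self.dim,)
        return vec


@dataclass
class FeatureMatrix:
    keys: list[tuple]           # (slide_id, row, col) per row
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != self.values.shape[0]:
            raise ValueError("keys / feature rows mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def embed_patches(patches, extractor=None) -> FeatureMatrix:
    """Apply a fixed-dimension extractor to every patch.

    ``patches`` is an iterable of :class:`Patch` or ``(key, pixels)`` tuples.
    The extractor must declare its output dimension via a ``dim`` attribute;
    a mismatching returned vector is an error.
    """
    extractor = extractor or HandcraftedEmbedder()
    declared = getattr(extractor, "dim", None)
    keys, rows = [], []
    for item in patches:
        if isinstance(item, Patch):
            key, pixels = item.key, item.pixels
        else:
            key, pixels = item
        vec = np.asarray(extractor(pixels), dtype=float)
        if declared is not None and vec.shape != (declared,):
            raise ValueError(f"extractor returned dim {vec.shape} but declared {declared}")
        keys.append(key)
        rows.append(vec)
    return FeatureMatrix(keys=keys, values=np.vstack(rows))


# ---------------------------------------------------------------------------
# reduction and clustering
# ---------------------------------------------------------------------------

class PcaReducer:
    """Standardize-then-PCA, fitted on training patches and frozen for
    held-out data.

    Columns are z-scored with training statistics before PCA because the
    descriptor mixes scales (histogram fractions vs. co-occurrence contrast);
    unscaled PCA would be dominated by the largest-magnitude channels.
    """

    def __init__(self, n_components: int = 32, seed: int = 666,
                 standardize: bool = True):
        self.n_components = n_components
        self.seed = seed
        self.standardize = standardize
        self._pca = None
        self._mean = None
        self._std = None

    def _scale(self, values: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return values
        return (values - self._mean) / self._std

    def fit(self, fm: FeatureMatrix) -> "PcaReducer":
        from sklearn.decomposition import PCA

        self._mean = fm.values.mean(axis=0)
        self._std = np.maximum(fm.values.std(axis=0), 1e-8)
        x = self._scale(fm.values)
        n = min(self.n_components, fm.values.shape[0] - 1, fm.dim)
        rank = np.linalg.matrix_rank(x - x.mean(axis=0))
        if rank < n:
            warnings.warn(f"rank-deficient features: keeping {rank} of {n} components")
            n = max(rank, 1)
        self._pca = PCA(n_components=n, svd_solver="full", random_state=self.seed).fit(x)
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self._pca is None:
            raise RuntimeError("reducer not fitted")
        return FeatureMatrix(keys=fm.keys, values=self._pca.transform(self._scale(fm.values)))

    @property
    def explained_variance_ratio_(self):
        return self._pca.explained_variance_ratio_


def reduce_features(fm: FeatureMatrix, n_components: int = 32,
                    seed: int = 666) -> tuple[FeatureMatrix, PcaReducer]:
    """Fit PCA on ``fm`` and project it; the reducer is returned for
    held-out patches."""
    if fm.values.shape[0] <= n_components:
        raise ValueError("need more patches than components")
    reducer = PcaReducer(n_components, seed).fit(fm)
    return reducer.transform(fm), reducer


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignment: dict[tuple, int]  # patch key -> cluster id

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        d = ((fm.values[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


def cluster_patches(fm: FeatureMatrix, k: int = 6, seed: int = 666,
                    n_init: int = 10) -> ClusterModel:
    """Seeded K-means over reduced features; best inertia of ``n_init`` runs."""
    from sklearn.cluster import KMeans

    if fm.values.shape[0] < k:
        raise ValueError("fewer patches than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(fm.values)
    assignment = {key: int(lab) for key, lab in zip(fm.keys, km.labels_)}
    return ClusterModel(k=k, centroids=km.cluster_centers_, assignment=assignment)


_CLUSTER_PALETTE = np.array([
    [31, 119, 180], [255, 127, 14], [44, 160, 44], [214, 39, 40],
    [148, 103, 189], [140, 86, 75], [227, 119, 194], [127, 127, 127],
], dtype=np.uint8)


def render_cluster_map(manifest: pd.DataFrame, assignment: dict[tuple, int],
                       cell_px: int = 16) -> np.ndarray:
    """Slide-level cluster map: one color per cluster id (consistent across
    slides), background tiles blank (white)."""
    rows = int(manifest["row"].max()) + 1
    cols = int(manifest["col"].max()) + 1
    img = np.full((rows * cell_px, cols * cell_px, 3), 255, dtype=np.uint8)
    for rec in manifest.itertuples():
        if getattr(rec, "status", "retained") != "retained":
            continue
        key = (rec.slide_id, rec.row, rec.col)
        if key not in assignment:
            raise KeyError(f"no cluster assignment for tile {key}")
        color = _CLUSTER_PALETTE[assignment[key] % len(_CLUSTER_PALETTE)]
        img[rec.row * cell_px:(rec.row + 1) * cell_px,
            rec.col * cell_px:(rec.col + 1) * cell_px] = color
    return img
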