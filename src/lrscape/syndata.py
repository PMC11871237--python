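"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all deterministic under a fixed seed:

* a censored bulk cohort whose hazard depends on a planted subset of
  ligand-receptor pair scores (proportional-hazards, exponential baseline);
* a spatial spot grid with planted ligand-receptor co-expression hotspots
  (Poisson counts);
* tiled procedural-texture "slides" from visually distinct tissue classes,
  where only designated informative classes carry the slide label signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .lrpairs import LRPair, PairScoreMatrix, SurvivalTable
from .spatialcoloc import SpatialSlide

__all__ = [
    "BulkCohortSpec",
    "SpatialSlideSpec",
    "SyntheticWsiSpec",
    "BulkCohort",
    "WsiDataset",
    "gen_bulk_cohort",
    "gen_spatial_slide",
    "gen_synthetic_wsis",
]


# ---------------------------------------------------------------------------
# bulk cohort with planted prognostic pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkCohortSpec:
    """A censored-survival cohort with planted prognostic pair scores.

    Defaults emulate an HPV-negative HNSC-sized cohort: ~400 samples,
    exponential baseline hazard giving a median OS of roughly 3 years, and
    about half the follow-ups censored.
    """

    n_samples: int = 395
    n_pairs: int = 50
    n_prognostic: int = 3
    effect_sizes: tuple = (1.0, 1.0, 1.0)   # log hazard ratio per sd of score
    baseline_hazard: float = np.log(2) / 1100.0  # per day
    censoring_rate: float = 0.5
    noise_sd: float = 0.5                   # sd of log pair scores
    pfi_hazard_multiplier: float = 1.0      # progression hazard vs death hazard
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_prognostic > self.n_pairs:
            raise ValueError("n_prognostic cannot exceed n_pairs")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if len(self.effect_sizes) != self.n_prognostic:
            raise ValueError("effect_sizes length must equal n_prognostic")


@dataclass
class BulkCohort:
    scores: PairScoreMatrix
    os: SurvivalTable
    pfi: SurvivalTable
    prognostic_pairs: list[str]
    effect_sizes: dict[str, float]

    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.os.sample, "os_time": self.os.time, "os_event": self.os.event,
            "pfi_time": self.pfi.time, "pfi_event": self.pfi.event,
        })


def _censoring_rate_for(lam: np.ndarray, mu: float) -> float:
    return float(np.mean(mu / (mu + lam)))


def _solve_censoring_hazard(lam: np.ndarray, target: float) -> float:
    """Exponential censoring hazard mu with P(C < T) approximately target."""
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, float(lam.mean())
    while _censoring_rate_for(lam, hi) < target:
        hi *= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _censoring_rate_for(lam, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_bulk_cohort(spec: BulkCohortSpec) -> BulkCohort:
    """Pair scores plus OS and PFI endpoints under proportional hazards.

    Pair scores are log-normal; the first ``n_prognostic`` pairs enter the
    log hazard linearly through their within-cohort standardized values with
    the given effect sizes. Event times are exponential (inverse transform);
    progression-free times satisfy PFI <= OS by construction; censoring is
    independent exponential, solved to hit the requested rate on average.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_pairs
    pair_mu = rng.normal(1.0, 0.4, size=p)
    log_scores = pair_mu[:, None] + spec.noise_sd * rng.normal(size=(p, n))
    values = np.exp(log_scores)
    pairs = [LRPair(f"LIG{k}", f"REC{k}") for k in range(p)]
    samples = [f"S{i:04d}" for i in range(n)]
    scores = PairScoreMatrix(values, pairs, samples)

    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
    beta = np.asarray(spec.effect_sizes, dtype=float)
    eta = beta @ z[: spec.n_prognostic] if spec.n_prognostic else np.zeros(n)
    lam = spec.baseline_hazard * np.exp(eta)

    t_os = rng.exponential(1.0, size=n) / lam
    t_prog = rng.exponential(1.0, size=n) / (lam * spec.pfi_hazard_multiplier)
    t_pfi = np.minimum(t_prog, t_os)

    mu = _solve_censoring_hazard(lam, spec.censoring_rate)
    cens = rng.exponential(1.0 / mu, size=n) if mu > 0 else np.full(n, np.inf)

    os_time = np.minimum(t_os, cens)
    os_event = (t_os <= cens).astype(int)
    pfi_time = np.minimum(t_pfi, cens)
    pfi_event = (t_pfi <= cens).astype(int)
    # guard against zero times from extreme hazards
    os_time = np.maximum(os_time, 1e-6)
    pfi_time = np.maximum(pfi_time, 1e-6)

    prognostic = [pairs[k].name for k in range(spec.n_prognostic)]
    return BulkCohort(
        scores=scores,
        os=SurvivalTable(np.asarray(samples), os_time, os_event, "OS"),
        pfi=SurvivalTable(np.asarray(samples), pfi_time, pfi_event, "PFI"),
        prognostic_pairs=prognostic,
        effect_sizes=dict(zip(prognostic, beta.tolist())),
    )


# ---------------------------------------------------------------------------
# spatial slide with planted hotspots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialSlideSpec:
    """A regular spot grid with co-expression hotspots for one pair."""

    grid_w: int = 30
    grid_h: int = 30
    n_hotspots: int = 3
    hotspot_radius: float = 3.0
    ligand_bg: float = 2.0
    receptor_bg: float = 2.0
    hotspot_gain: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_w * self.grid_h < 1:
            raise ValueError("grid must contain at least one spot")
        if self.hotspot_gain <= 1:
            raise ValueError("hotspot_gain must exceed 1")
        if self.n_hotspots > 0 and self.hotspot_radius >= max(self.grid_w, self.grid_h):
            raise ValueError("hotspot radius larger than the grid")


def gen_spatial_slide(spec: SpatialSlideSpec) -> SpatialSlide:
    """Poisson spot counts; inside hotspot discs both means are multiplied
    by ``hotspot_gain``. Ground-truth membership is recorded in ``region``
    ("hotspot" / "background")."""
    rng = np.random.default_rng(spec.seed)
    xs, ys = np.meshgrid(np.arange(spec.grid_w), np.arange(spec.grid_h))
    x = xs.ravel().astype(float)
    y = ys.ravel().astype(float)
    n = len(x)

    in_hotspot = np.zeros(n, dtype=bool)
    for _ in range(spec.n_hotspots):
        cx = rng.uniform(0, spec.grid_w - 1)
        cy = rng.uniform(0, spec.grid_h - 1)
        in_hotspot |= (x - cx) ** 2 + (y - cy) ** 2 <= spec.hotspot_radius**2

    gain = np.where(in_hotspot, spec.hotspot_gain, 1.0)
    ligand = rng.poisson(spec.ligand_bg * gain).astype(float)
    receptor = rng.poisson(spec.receptor_bg * gain).astype(float)
    spot_id = np.array([f"spot_{i:05d}" for i in range(n)])
    region = np.where(in_hotspot, "hotspot", "background")
    return SpatialSlide(spot_id, x, y, ligand, receptor, region=region)


# ---------------------------------------------------------------------------
# synthetic tiled "whole slide images"
# ---------------------------------------------------------------------------

# distinct per-class base colors on a pale stained-tissue palette (RGB)
_CLASS_COLORS = np.array([
    [196, 148, 196],  # violet
    [150, 170, 210],  # slate blue
    [220, 170, 150],  # salmon
    [160, 200, 160],  # sage
    [210, 200, 140],  # ochre
    [170, 160, 200],  # lavender
    [200, 150, 160],  # rose
    [150, 200, 200],  # teal
], dtype=float)

# per-class blob smoothing scale: changes texture grain between classes
_CLASS_SCALES = np.array([3.0, 6.0, 2.0, 4.5, 8.0, 1.5, 5.0, 2.5])


@dataclass(frozen=True)
class SyntheticWsiSpec:
    """Tiled texture slides where only some classes carry label signal.

    Each tile belongs to one of ``n_classes`` visually distinct texture
    classes (base color + blob grain). The slide label shifts the blob
    coverage of tiles from ``informative_classes`` only
    (``label_coverage`` per label); all other classes use a fixed
    class-specific coverage, so their tiles carry no label signal by
    construction.
    """

    n_slides: int = 60
    tiles_per_side: int = 4
    tile_px: int = 512
    n_classes: int = 6
    informative_classes: tuple = (0, 1)
    class_mix: tuple | None = None          # per-class tile proportions
    label_coverage: tuple = (0.30, 0.60)    # blob coverage for label 0 / 1
    base_coverage: float = 0.45             # coverage of non-informative tiles
    two_slide_case_fraction: float = 0.15   # cases contributing two slides
    seed: int = 0

    def __post_init__(self):
        if not self.informative_classes:
            raise ValueError("informative_classes must be non-empty")
        if not set(self.informative_classes) <= set(range(self.n_classes)):
            raise ValueError("informative_classes must be class ids")
        if self.n_classes > len(_CLASS_COLORS):
            raise ValueError(f"at most {len(_CLASS_COLORS)} texture classes supported")


@dataclass
class WsiDataset:
    """Lazy synthetic slide collection: tiles are rendered on demand,
    deterministically from (seed, slide, row, col)."""

    spec: SyntheticWsiSpec
    manifest: pd.DataFrame = field(repr=False)  # slide_id, case_id, row, col, class_id
    labels: dict[str, int]
    cases: dict[str, str]                       # slide_id -> case_id

    @property
    def slide_ids(self) -> list[str]:
        return sorted(self.labels)

    def _tile_params(self, slide_id: str, class_id: int) -> float:
        if class_id in self.spec.informative_classes:
            return self.spec.label_coverage[self.labels[slide_id]]
        return self.spec.base_coverage

    def render_tile(self, slide_id: str, row: int, col: int, class_id: int) -> np.ndarray:
        coverage = self._tile_params(slide_id, class_id)
        slide_idx = int(slide_id.split("_")[-1])
        seed_seq = np.random.SeedSequence([self.spec.seed, slide_idx, row, col])
        return _texture_tile(class_id, coverage, self.spec.tile_px,
                             np.random.default_rng(seed_seq))

    def tiles(self, slide_id: str):
        """Yield (row, col, class_id, pixels) for one slide."""
        sub = self.manifest[self.manifest.slide_id == slide_id]
        for rec in sub.itertuples():
            yield rec.row, rec.col, rec.class_id, self.render_tile(slide_id, rec.row, rec.col, rec.class_id)

    def render_slide(self, slide_id: str) -> np.ndarray:
        """Assemble the full slide image from its tiles."""
        t, px = self.spec.tiles_per_side, self.spec.tile_px
        img = np.full((t * px, t * px, 3), 255, dtype=np.uint8)
        for row, col, _cls, pixels in self.tiles(slide_id):
            img[row * px:(row + 1) * px, col * px:(col + 1) * px] = pixels
        return img

    def write(self, out_dir):
        """PNG tiles in a slide-per-directory layout plus a manifest TSV."""
        from pathlib import Path
        from PIL import Image

        out = Path(out_dir)
        for slide_id in self.slide_ids:
            d = out / slide_id
            d.mkdir(parents=True, exist_ok=True)
            for row, col, _cls, pixels in self.tiles(slide_id):
                Image.fromarray(pixels).save(d / f"tile_r{row}_c{col}.png")
        manifest = self.manifest.copy()
        manifest["label"] = manifest.slide_id.map(self.labels)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def _texture_tile(class_id: int, coverage: float, tile_px: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Procedural tissue-like texture: smoothed noise thresholded into dark
    blobs over a class-specific base color; blob area fraction = coverage."""
    scale = _CLASS_SCALES[class_id] * tile_px / 96.0
    noise = rng.standard_normal((tile_px, tile_px))
    smooth = ndimage.gaussian_filter(noise, sigma=scale, mode="wrap")
    threshold = np.quantile(smooth, 1.0 - coverage)
    blobs = smooth >= threshold

    base = _CLASS_COLORS[class_id]
    img = np.empty((tile_px, tile_px, 3), dtype=float)
    img[:] = base
    img[blobs] = base * 0.45  # darker "nuclei" blobs
    img += rng.normal(0, 4.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def gen_synthetic_wsis(spec: SyntheticWsiSpec) -> WsiDataset:
    """Slide labels, case ids, per-tile class map and lazy tile renderer.

    Labels are balanced Bernoulli(0.5); tile classes are multinomial from
    ``class_mix`` (uniform by default), with at least one informative tile
    forced per slide; a fraction of cases contributes two slides (for
    leakage-safe case-level splitting downstream).
    """
    rng = np.random.default_rng(spec.seed)
    mix = np.asarray(spec.class_mix if spec.class_mix is not None
                     else np.ones(spec.n_classes) / spec.n_classes, dtype=float)
    mix = mix / mix.sum()

    # assign slides to cases: some cases get two slides
    slide_ids = [f"slide_{i:03d}" for i in range(spec.n_slides)]
    cases: dict[str, str] = {}
    labels: dict[str, int] = {}
    i = 0
    case_idx = 0
    while i < spec.n_slides:
        case_id = f"case_{case_idx:03d}"
        label = int(rng.integers(0, 2))
        n_here = 2 if (rng.random() < spec.two_slide_case_fraction and i + 1 < spec.n_slides) else 1
        for _ in range(n_here):
            cases[slide_ids[i]] = case_id
            labels[slide_ids[i]] = label
            i += 1
        case_idx += 1

    rows = []
    n_tiles = spec.tiles_per_side**2
    for slide_id in slide_ids:
        classes = rng.choice(spec.n_classes, size=n_tiles, p=mix)
        if not np.isin(classes, spec.informative_classes).any():
            classes[rng.integers(0, n_tiles)] = rng.choice(spec.informative_classes)
        for t in range(n_tiles):
            rows.append({"slide_id": slide_id, "case_id": cases[slide_id],
                         "row": t // spec.tiles_per_side, "col": t % spec.tiles_per_side,
                         "class_id": int(classes[t])})
    manifest = pd.DataFrame(rows)
    return WsiDataset(spec=spec, manifest=manifest, labels=labels, cases=cases)
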