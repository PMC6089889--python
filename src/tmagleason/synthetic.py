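"""Synthetic TMA-spot images with ground-truth Gleason annotations.

The generator stands in for a scanned, pathologist-annotated prostate
tissue-microarray cohort: each spot is a stained tissue disk on a bright
background, partitioned into angular regions that each carry one
annotation (Benign or Gleason pattern 3/4/5) and a texture implementing
that pattern's architectural definition:

* Benign — large, sparse glands with a dark basal ring and a wide lumen;
* Gleason 3 — small, round, well-separated glands;
* Gleason 4 — small glands allowed to fuse into chains, plus cribriform
  "sieve" discs with multiple small punched lumens;
* Gleason 5 — solid sheets of epithelium with dense nuclei, no lumens.

Cohorts link each spot to a drawn composite Gleason score (the region
areas realize the score) and to a synthetic survival record whose hazard
increases with the risk tier of the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PATTERNS",
    "MASK_CODES",
    "TextureParams",
    "SyntheticSpotConfig",
    "AnnotatedSpot",
    "HazardParams",
    "CohortFixture",
    "ProbabilityMap",
    "generate_spot",
    "generate_label_mask",
    "generate_cohort",
    "one_hot_probability_map",
    "region_spec_for_score",
    "patch_texture_stats",
    "DEFAULT_SCORE_MIX",
]

PATTERNS = ("benign", "G3", "G4", "G5")
#: mask encoding: 0 = unannotated/background, then 1..4
MASK_CODES = {"benign": 1, "G3": 2, "G4": 3, "G5": 4}

# color palette (RGB uint8), loosely H&E: pink stroma, purple epithelium
COLOR_BACKGROUND = (244, 242, 246)
COLOR_STROMA = (229, 175, 204)
COLOR_EPITHELIUM = (160, 110, 180)
COLOR_BASAL = (110, 70, 140)
COLOR_LUMEN = (250, 250, 252)
COLOR_NUCLEUS = (64, 36, 100)

#: reference spot side in pixels (0.23 um/px scan); texture sizes below
#: are expressed at this scale and shrink proportionally for smaller spots
REFERENCE_SPOT_PX = 3100


@dataclass(frozen=True)
class TextureParams:
    """Gland geometry of one Gleason pattern at reference resolution."""

    gland_radius: float         # px, epithelial disk radius
    spacing: float              # px, center-to-center grid spacing
    lumen_ratio: float          # lumen radius / gland radius
    fusion_jitter: float        # placement jitter as a fraction of spacing
    nucleus_density: float      # nuclei per 1000 px^2 of region (G5 sheets)
    cribriform_every: int = 0   # every n-th gland becomes a cribriform disc


DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "benign": TextureParams(gland_radius=58, spacing=260, lumen_ratio=0.74,
                            fusion_jitter=0.15, nucleus_density=0.0),
    "G3": TextureParams(gland_radius=26, spacing=80, lumen_ratio=0.52,
                        fusion_jitter=0.12, nucleus_density=0.0),
    "G4": TextureParams(gland_radius=26, spacing=44, lumen_ratio=0.30,
                        fusion_jitter=0.35, nucleus_density=0.0,
                        cribriform_every=7),
    "G5": TextureParams(gland_radius=20, spacing=26, lumen_ratio=0.0,
                        fusion_jitter=0.4, nucleus_density=1.6),
}


@dataclass
class SyntheticSpotConfig:
    spot_size_px: int = REFERENCE_SPOT_PX
    region_spec: list[tuple[str, float]] = field(default_factory=list)
    texture_params: dict[str, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES))
    rng_seed: int = 0
    noise_sigma: float = 3.0
    disk_radius_fraction: float = 0.48

    def __post_init__(self):
        fractions = [f for _, f in self.region_spec]
        if any(f < 0 for f in fractions):
            raise ValueError("region area fractions must be nonnegative")
        if sum(fractions) > 1.0 + 1e-9:
            raise ValueError(
                f"region area fractions sum to {sum(fractions):.3f} > 1")
        for pattern, _ in self.region_spec:
            if pattern not in MASK_CODES:
                raise ValueError(f"unknown pattern {pattern!r}")


@dataclass
class AnnotatedSpot:
    """A spot raster, its label mask and an optional generating config."""

    spot_id: str
    image: np.ndarray | None        # (S, S, 3) uint8
    mask: np.ndarray | None         # (S, S) uint8, codes 0..4
    config: SyntheticSpotConfig | None = None

    def realize(self) -> "AnnotatedSpot":
        """Return a copy with image and mask generated (deterministic)."""
        if self.image is not None and self.mask is not None:
            return self
        if self.config is None:
            raise ValueError(f"spot {self.spot_id} has no data and no config")
        rgb, mask = generate_spot(self.config)
        return AnnotatedSpot(self.spot_id, rgb, mask, self.config)

    def realize_mask(self) -> np.ndarray:
        """Only the label mask (much cheaper than a full render)."""
        if self.mask is not None:
            return self.mask
        if self.config is None:
            raise ValueError(f"spot {self.spot_id} has no data and no config")
        return generate_label_mask(self.config)


# --------------------------------------------------------------------------
# drawing helpers

def _disk_offsets(radius: float) -> np.ndarray:
    r = max(int(np.ceil(radius)), 1)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp(canvas: np.ndarray, centers: np.ndarray, radius: float, value) -> None:
    """Paint filled disks of one radius at integer centers, clipped."""
    if len(centers) == 0:
        return
    offs = _disk_offsets(radius)
    coords = centers[:, None, :] + offs[None, :, :]
    coords = coords.reshape(-1, 2)
    H, W = canvas.shape[:2]
    ok = ((coords[:, 0] >= 0) & (coords[:, 0] < H)
          & (coords[:, 1] >= 0) & (coords[:, 1] < W))
    coords = coords[ok]
    canvas[coords[:, 0], coords[:, 1]] = value


def _grid_centers(rng, region_mask: np.ndarray, spacing: float,
                  jitter: float) -> np.ndarray:
    """Jittered-grid points that fall inside ``region_mask``."""
    H, W = region_mask.shape
    ys = np.arange(spacing / 2, H, spacing)
    xs = np.arange(spacing / 2, W, spacing)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.stack([gy.ravel(), gx.ravel()], axis=1)
    pts += rng.uniform(-jitter * spacing, jitter * spacing, size=pts.shape)
    pts = np.rint(pts).astype(np.int64)
    ok = ((pts[:, 0] >= 0) & (pts[:, 0] < H) & (pts[:, 1] >= 0) & (pts[:, 1] < W))
    pts = pts[ok]
    return pts[region_mask[pts[:, 0], pts[:, 1]]]


def _ring_nuclei(rng, centers: np.ndarray, radius: float) -> np.ndarray:
    """Nucleus positions along the epithelial ring of each gland."""
    if len(centers) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    n_per = max(int(2 * np.pi * radius / 9), 4)
    ang = rng.uniform(0, 2 * np.pi, size=(len(centers), n_per))
    rr = radius * rng.uniform(0.82, 1.0, size=ang.shape)
    pos = np.stack([centers[:, None, 0] + rr * np.sin(ang),
                    centers[:, None, 1] + rr * np.cos(ang)], axis=2)
    return np.rint(pos.reshape(-1, 2)).astype(np.int64)


def _draw_gland_pattern(rng, rgb, region_mask, params: TextureParams,
                        scale: float, benign: bool) -> None:
    r = max(params.gland_radius * scale, 2.0)
    spacing = max(params.spacing * scale, 2 * r * 0.8)
    centers = _grid_centers(rng, region_mask, spacing, params.fusion_jitter)
    if len(centers) == 0:
        return
    crib = params.cribriform_every
    if crib:
        is_crib = np.arange(len(centers)) % crib == crib - 1
        plain, crib_centers = centers[~is_crib], centers[is_crib]
    else:
        plain, crib_centers = centers, np.zeros((0, 2), np.int64)

    _stamp(rgb, plain, r, COLOR_EPITHELIUM)
    if benign:
        # dark basal outline: slightly larger darker disk under the lumen
        _stamp(rgb, plain, r, COLOR_BASAL)
        _stamp(rgb, plain, r * 0.93, COLOR_EPITHELIUM)
    if params.lumen_ratio > 0:
        _stamp(rgb, plain, max(r * params.lumen_ratio, 1.0), COLOR_LUMEN)
    _stamp(rgb, _ring_nuclei(rng, plain, r * 0.97), max(2.2 * scale, 1.0),
           COLOR_NUCLEUS)

    if len(crib_centers):
        R = r * 2.6
        _stamp(rgb, crib_centers, R, COLOR_EPITHELIUM)
        holes = []
        for c in crib_centers:
            n_holes = rng.integers(5, 9)
            ang = rng.uniform(0, 2 * np.pi, n_holes)
            rad = rng.uniform(0.15, 0.75, n_holes) * R
            holes.append(np.stack([c[0] + rad * np.sin(ang),
                                   c[1] + rad * np.cos(ang)], axis=1))
        holes = np.rint(np.concatenate(holes)).astype(np.int64)
        _stamp(rgb, holes, max(r * 0.33, 1.0), COLOR_LUMEN)
        _stamp(rgb, _ring_nuclei(rng, crib_centers, R * 0.95),
               max(2.2 * scale, 1.0), COLOR_NUCLEUS)


def _draw_solid_sheet(rng, rgb, region_mask, params: TextureParams,
                      scale: float) -> None:
    """Gleason-5 texture: near-solid epithelium with dense nuclei."""
    r = max(params.gland_radius * scale, 2.0)
    centers = _grid_centers(rng, region_mask, max(params.spacing * scale, 3.0),
                            params.fusion_jitter)
    _stamp(rgb, centers, r, COLOR_EPITHELIUM)
    area = int(region_mask.sum())
    n_nuclei = int(area * params.nucleus_density / 1000.0)
    if n_nuclei:
        idx = np.flatnonzero(region_mask.ravel())
        pick = rng.choice(idx, size=min(n_nuclei, idx.size), replace=False)
        pts = np.stack(np.unravel_index(pick, region_mask.shape), axis=1)
        _stamp(rgb, pts, max(2.6 * scale, 1.0), COLOR_NUCLEUS)


# --------------------------------------------------------------------------

def _disk_and_sectors(config: SyntheticSpotConfig, rng):
    """Tissue disk plus the angular sector selection of each region."""
    S = config.spot_size_px
    yy, xx = np.ogrid[:S, :S]
    cy = cx = (S - 1) / 2.0
    rad = config.disk_radius_fraction * S
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad * rad
    angle = np.arctan2(yy - cy, xx - cx)  # [-pi, pi)
    start = rng.uniform(-np.pi, np.pi)
    rel = np.mod(angle - start, 2 * np.pi)
    lo = 0.0
    sectors = []
    for pattern, frac in config.region_spec:
        hi = lo + frac * 2 * np.pi
        sectors.append((pattern, disk & (rel >= lo) & (rel < hi)))
        lo = hi
    return disk, sectors


def generate_label_mask(config: SyntheticSpotConfig) -> np.ndarray:
    """Only the label mask of `generate_spot` (cheap: no texture render).

    Identical to the mask returned by ``generate_spot`` for the same
    config.
    """
    rng = np.random.default_rng(config.rng_seed)
    _, sectors = _disk_and_sectors(config, rng)
    mask = np.zeros((config.spot_size_px,) * 2, dtype=np.uint8)
    for pattern, sel in sectors:
        mask[sel] = MASK_CODES[pattern]
    return mask


def generate_spot(config: SyntheticSpotConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one spot; returns (rgb uint8 (S,S,3), mask uint8 (S,S)).

    The tissue disk is split into angular sectors whose areas are
    proportional to the requested region fractions; any remainder stays
    unannotated stroma (mask code 0).  Identical configs (including the
    seed) produce bit-identical output.
    """
    S = config.spot_size_px
    rng = np.random.default_rng(config.rng_seed)
    scale = S / REFERENCE_SPOT_PX

    disk, sectors = _disk_and_sectors(config, rng)
    mask = np.zeros((S, S), dtype=np.uint8)
    for pattern, sel in sectors:
        mask[sel] = MASK_CODES[pattern]

    rgb = np.empty((S, S, 3), dtype=np.uint8)
    rgb[...] = COLOR_BACKGROUND
    rgb[disk] = COLOR_STROMA

    for pattern, sel in sectors:
        params = config.texture_params[pattern]
        if pattern == "G5":
            _draw_solid_sheet(rng, rgb, sel, params, scale)
        else:
            _draw_gland_pattern(rng, rgb, sel, params, scale,
                                benign=(pattern == "benign"))

    if config.noise_sigma > 0:
        noise = rng.standard_normal(rgb.shape, dtype=np.float32)
        noise *= config.noise_sigma
        rgb = np.clip(rgb.astype(np.float32) + noise, 0, 255).astype(np.uint8)
    return rgb, mask


# --------------------------------------------------------------------------
# probability-map fixture

@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities over (Benign, G3, G4, G5)."""

    probs: np.ndarray               # (H, W, 4) float32
    tissue_mask: np.ndarray         # (H, W) bool
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.tissue_mask.shape


def one_hot_probability_map(label_mask: np.ndarray,
                            smoothing: float = 0.0) -> ProbabilityMap:
    """Probability-map fixture built directly from a label mask.

    At every annotated pixel the labeled channel gets ``1 - smoothing``
    and the remaining mass is spread uniformly over the other three
    channels; unannotated pixels are treated as non-tissue (all zeros).
    """
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must be in [0, 1)")
    tissue = label_mask > 0
    H, W = label_mask.shape
    probs = np.zeros((H, W, 4), dtype=np.float32)
    off = smoothing / 3.0
    for code in range(1, 5):
        sel = label_mask == code
        probs[sel] = off
        probs[sel, code - 1] = 1.0 - smoothing
    return ProbabilityMap(probs=probs, tissue_mask=tissue,
                          meta={"source": "one_hot", "smoothing": smoothing})


# --------------------------------------------------------------------------
# cohorts

#: class balance loosely imitating a prostatectomy TMA test cohort
DEFAULT_SCORE_MIX = {0: 0.13, 6: 0.25, 7: 0.30, 8: 0.12, 9: 0.12, 10: 0.08}

#: composite score -> (primary, secondary) used to realize region areas
_SCORE_PATTERNS = {6: ("G3", "G3"), 7: ("G3", "G4"), 8: ("G4", "G4"),
                   9: ("G4", "G5"), 10: ("G5", "G5")}


@dataclass(frozen=True)
class HazardParams:
    """Exponential survival model with a hazard ratio per risk tier.

    Risk tiers follow the usual grouping: low (benign or score 6),
    intermediate (7), high (>= 8); the hazard of tier t is
    ``baseline_hazard * ratio**t``.  ``per="score"`` instead multiplies
    per unit of composite score above 6.
    """

    baseline_hazard: float = 0.004      # events per month in the low tier
    ratio: float = 3.0
    per: str = "tier"                   # "tier" or "score"
    censor_horizon: float = 120.0       # months, uniform censoring window


def _risk_tier(score: int) -> int:
    if score <= 6:
        return 0
    if score == 7:
        return 1
    return 2


def region_spec_for_score(score: int, rng) -> list[tuple[str, float]]:
    """Region areas realizing ``score`` under the 0.25-threshold scoring.

    Score 0 means benign-only tissue.  Mixed scores (7, 9) get primary
    ~0.50 and secondary ~0.35 of the annotated area; pure scores a single
    ~0.80 region; the rest is benign epithelium, so that exactly the
    intended patterns clear the 0.25 weight threshold.
    """
    jit = lambda a, b: float(rng.uniform(a, b))
    if score == 0:
        return [("benign", jit(0.9, 1.0))]
    primary, secondary = _SCORE_PATTERNS[score]
    if primary == secondary:
        main = jit(0.75, 0.85)
        return [(primary, main), ("benign", round(1 - main - 0.02, 3))]
    p = jit(0.48, 0.54)
    s = jit(0.33, 0.37)
    return [(primary, p), (secondary, s), ("benign", round(1 - p - s - 0.02, 3))]


@dataclass
class CohortFixture:
    """Spots plus the linked clinical table (synthetic)."""

    spots: list[AnnotatedSpot]
    clinical: pd.DataFrame          # spot_id, true_score, time_months, event

    def __post_init__(self):
        ids = {s.spot_id for s in self.spots}
        missing = set(self.clinical["spot_id"]) - ids
        if missing:
            raise ValueError(f"clinical rows reference unknown spots: {missing}")
        if (self.clinical["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")

    def spot(self, spot_id: str) -> AnnotatedSpot:
        for s in self.spots:
            if s.spot_id == spot_id:
                return s.realize()
        raise KeyError(spot_id)


def generate_cohort(n_spots: int,
                    score_mix: dict[int, float] | None = None,
                    hazard: HazardParams = HazardParams(),
                    rng_seed: int = 0,
                    spot_size_px: int = REFERENCE_SPOT_PX,
                    materialize: bool = False) -> CohortFixture:
    """Draw a cohort of annotated spots with linked survival records.

    Each spot's composite score is drawn from ``score_mix`` (score 0 =
    benign) and realized geometrically by `region_spec_for_score`; its
    survival time is exponential with the tier (or score) dependent
    hazard, censored uniformly on ``[0, censor_horizon]``.  With
    ``materialize=False`` the spot rasters are generated lazily via
    ``AnnotatedSpot.realize()``.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    mix = dict(DEFAULT_SCORE_MIX if score_mix is None else score_mix)
    total = sum(mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"score_mix must sum to 1 (got {total})")
    if hazard.per not in ("tier", "score"):
        raise ValueError("hazard.per must be 'tier' or 'score'")

    rng = np.random.default_rng(rng_seed)
    scores = rng.choice(sorted(mix), p=[mix[k] for k in sorted(mix)],
                        size=n_spots)
    spots, rows = [], []
    for i, score in enumerate(scores):
        score = int(score)
        spot_id = f"spot{i:04d}"
        cfg = SyntheticSpotConfig(
            spot_size_px=spot_size_px,
            region_spec=region_spec_for_score(score, rng),
            rng_seed=int(rng.integers(2**31)),
        )
        spot = AnnotatedSpot(spot_id, None, None, cfg)
        if materialize:
            spot = spot.realize()
        spots.append(spot)

        if hazard.per == "tier":
            lam = hazard.baseline_hazard * hazard.ratio ** _risk_tier(score)
        else:
            lam = hazard.baseline_hazard * hazard.ratio ** max(score - 6, 0)
        t_event = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        t_cens = rng.uniform(0, hazard.censor_horizon)
        time = max(min(t_event, t_cens), 1e-3)
        rows.append({"spot_id": spot_id, "true_score": score,
                     "time_months": float(time),
                     "event": int(t_event <= t_cens)})
    return CohortFixture(spots=spots, clinical=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# texture statistics (used to verify pattern separability)

def patch_texture_stats(patch_rgb: np.ndarray, min_area: int = 12,
                        tissue_mask: np.ndarray | None = None) -> dict:
    """Gland count and lumen-area fraction of an RGB patch.

    Lumens are near-white pixel blobs; glands are counted as connected
    lumen components of at least ``min_area`` pixels.  ``tissue_mask``
    restricts the measurement to tissue (the spot background is bright
    and would otherwise count as lumen).
    """
    from scipy import ndimage

    white = (patch_rgb > 235).all(axis=-1)
    if tissue_mask is not None:
        white &= tissue_mask
    labeled, n = ndimage.label(white)
    if n:
        areas = np.bincount(labeled.ravel())[1:]
        count = int((areas >= min_area).sum())
        lumen_fraction = float(areas[areas >= min_area].sum()) / white.size
    else:
        count, lumen_fraction = 0, 0.0
    return {"gland_count": count, "lumen_fraction": lumen_fraction}
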