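"""Synthetic dermoscopy-attribute dataset generator.

Emits lesion-like RGB images and per-attribute binary masks in the exact
ISIC Task-2 layout (``<id>.jpg`` + ``<id>_attribute_<name>.png``), so the
whole pipeline is exercisable without any download.  The generator
reproduces the two statistical properties the method is built around:

* image-level imbalance — each attribute is present in a Bernoulli fraction
  of images matching the ISIC 2018 Task 2 composition (pigment network
  0.587, milia-like cysts 0.263, globules 0.232, negative network 0.073,
  streaks 0.039);
* pixel-level sparsity — a positive mask covers only a configurable small
  fraction of the lesion (default 0.2-5% of the lesion area), the regime in
  which plain per-pixel losses collapse to the background class.

Geometry is a stylised rendering of each attribute's morphology: a line
lattice for the pigment network, scattered discs for globules, radial
border segments for streaks, thin curvilinear tracks for the negative
network and tiny bright dots for milia-like cysts.  Structures are painted
into the image (dark for pigmented patterns, bright for hypopigmented
ones), so the masks are learnable from pixels.  "Easy mode" uses larger,
higher-contrast structures for fast CPU training checks; it does not
change the layout or bookkeeping.  Photorealism is a non-goal.

Every random draw descends from one ``numpy.random.SeedSequence``, so the
dataset is bit-reproducible at every granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line

from .dataset_io import ATTRIBUTES, DatasetManifest, write_mask

__all__ = ["SynthConfig", "make_lesion_image", "make_attribute_mask", "generate_dataset"]

#: Image-level attribute prevalences mirroring the ISIC 2018 Task 2 count
#: ratios (counts 1522/189/681/602/100 of 2594 images).
DEFAULT_PREVALENCE: dict[str, float] = {
    "pigment_network": 0.587,
    "negative_network": 0.073,
    "milia_like_cyst": 0.263,
    "globules": 0.232,
    "streaks": 0.039,
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the sparse "paper mode"."""

    n_images: int = 100
    side: int = 512
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    area_fraction: tuple[float, float] = (0.002, 0.05)
    noise_level: float = 0.03
    hair_probability: float = 0.2
    easy: bool = False
    correlated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side % 32 != 0:
            raise ValueError("side must be divisible by 32")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        lo, hi = self.area_fraction
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("area_fraction must satisfy 0 < lo < hi < 1")
        for attr, p in self.prevalence.items():
            if attr not in ATTRIBUTES:
                raise ValueError(f"unknown attribute {attr!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError("prevalences must lie in [0, 1]")

    @classmethod
    def easy_mode(
        cls, n_images: int = 200, side: int = 96, attribute: str = "globules", seed: int = 0
    ) -> "SynthConfig":
        """Large, high-contrast structures of one attribute: a CPU-scale
        sanity-check regime (foreground still only ~1-2% of the image)."""
        prevalence = {a: 0.0 for a in ATTRIBUTES}
        prevalence[attribute] = 0.7
        return cls(
            n_images=n_images,
            side=side,
            prevalence=prevalence,
            area_fraction=(0.04, 0.09),
            noise_level=0.015,
            hair_probability=0.0,
            easy=True,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Image synthesis


def make_lesion_image(
    side: int,
    seed,
    noise_level: float = 0.03,
    hair_probability: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """A skin-toned background with one elliptical pigmented lesion.

    Returns ``(image, lesion_mask)``: float32 HWC RGB in [0, 1] and a bool
    array marking the lesion region.  ``seed`` may be anything
    ``numpy.random.default_rng`` accepts (int or SeedSequence).
    """
    if side < 64:
        raise ValueError("side must be >= 64")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)

    skin = np.array([0.87, 0.72, 0.63], dtype=np.float32)
    grad_dir = rng.normal(size=2)
    grad = (grad_dir[0] * yy + grad_dir[1] * xx) / side
    grad = (grad - grad.min()) / max(np.ptp(grad), 1e-9) - 0.5
    img = skin[None, None, :] * (1.0 + 0.08 * grad[:, :, None])

    cy, cx = side / 2 + rng.uniform(-0.08, 0.08, 2) * side
    ry = rng.uniform(0.20, 0.30) * side
    rx = rng.uniform(0.20, 0.30) * side
    rot = rng.uniform(0, np.pi)
    lesion = np.zeros((side, side), dtype=bool)
    rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=(side, side), rotation=rot)
    lesion[rr, cc] = True

    brown = np.array([0.45, 0.30, 0.22], dtype=np.float32) * rng.uniform(0.85, 1.1)
    dist = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    shade = np.clip(1.15 - 0.45 * (1.0 - dist), 0.6, 1.15).astype(np.float32)
    img[lesion] = brown[None, :] * shade[lesion, None]
    img = ndi.gaussian_filter(img, sigma=(1.5, 1.5, 0))

    if rng.random() < hair_probability:
        for _ in range(rng.integers(2, 7)):
            img = _draw_hair(img, rng)

    img += rng.normal(0.0, noise_level, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0).astype(np.float32), lesion


def _draw_hair(img: np.ndarray, rng) -> np.ndarray:
    """One dark arc-like stroke, emulating hair occlusion artifacts."""
    side = img.shape[0]
    p0 = rng.uniform(0, side, 2)
    p2 = rng.uniform(0, side, 2)
    p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3, 2) * side
    ts = np.linspace(0.0, 1.0, 4 * side)
    pts = ((1 - ts)[:, None] ** 2 * p0 + 2 * (ts * (1 - ts))[:, None] * p1 + ts[:, None] ** 2 * p2)
    pts = np.round(pts).astype(int)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < side) & (pts[:, 1] >= 0) & (pts[:, 1] < side)
    img[pts[ok, 0], pts[ok, 1]] = img[pts[ok, 0], pts[ok, 1]] * 0.3
    return img


# ---------------------------------------------------------------------------
# Attribute-mask geometry


def _paint_clipped(mask: np.ndarray, rr: np.ndarray, cc: np.ndarray, allowed: np.ndarray) -> None:
    side = mask.shape[0]
    ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
    rr, cc = rr[ok], cc[ok]
    ok = allowed[rr, cc]
    mask[rr[ok], cc[ok]] = 1


def _disc_element(mask, allowed, rng, lesion_area, frac_lo, frac_hi):
    r = max(1, int(round(np.sqrt(rng.uniform(frac_lo, frac_hi) * lesion_area / np.pi))))
    centers = np.argwhere(allowed)
    cy, cx = centers[rng.integers(len(centers))]
    rr, cc = _draw_disk((cy, cx), r, shape=mask.shape)
    _paint_clipped(mask, rr, cc, allowed)


def _line_element(mask, allowed, rng, p0, p1, thickness=1):
    rr, cc = _draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    for off in range(thickness):
        _paint_clipped(mask, rr + off, cc, allowed)


def _walk_element(mask, allowed, rng, n_steps):
    """Thin curvilinear track: a persistent random walk."""
    starts = np.argwhere(allowed)
    pos = starts[rng.integers(len(starts))].astype(float)
    ang = rng.uniform(0, 2 * np.pi)
    pts = []
    for _ in range(n_steps):
        ang += rng.normal(0.0, 0.35)
        pos = pos + np.array([np.sin(ang), np.cos(ang)])
        pts.append(pos.copy())
    pts = np.round(np.array(pts)).astype(int)
    _paint_clipped(mask, pts[:, 0], pts[:, 1], allowed)


def _lesion_geometry(lesion: np.ndarray):
    centroid = np.array(ndi.center_of_mass(lesion))
    area = float(lesion.sum())
    radius = np.sqrt(area / np.pi)
    return centroid, area, radius


def make_attribute_mask(
    attribute: str,
    lesion_mask: np.ndarray,
    seed,
    area_fraction: tuple[float, float] = (0.002, 0.05),
    easy: bool = False,
) -> np.ndarray:
    """Binary mask of one attribute inside the lesion.

    Elements of the attribute-specific geometry are added until the painted
    area falls inside ``area_fraction`` times the lesion area (streaks may
    extend into a thin band just outside the lesion border).
    """
    if attribute not in ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}")
    lesion_mask = lesion_mask.astype(bool)
    if not lesion_mask.any():
        raise ValueError("lesion region is empty")
    rng = np.random.default_rng(seed)
    lo, hi = area_fraction
    centroid, area, radius = _lesion_geometry(lesion_mask)
    lo_px = lo * area
    hi_px = hi * area
    if hi_px < 1.0:
        raise ValueError("area fraction unsatisfiable: lesion too small")
    target = rng.uniform(lo_px + 0.4 * (hi_px - lo_px), lo_px + 0.8 * (hi_px - lo_px))

    mask = np.zeros(lesion_mask.shape, dtype=np.uint8)
    allowed = lesion_mask
    if attribute == "streaks":
        allowed = ndi.binary_dilation(lesion_mask, iterations=max(2, int(0.04 * radius)))

    scale = 2.0 if easy else 1.0
    for _ in range(600):
        if mask.sum() >= target:
            break
        if attribute == "globules":
            _disc_element(mask, allowed, rng, area, 0.002 * scale**2, 0.006 * scale**2)
        elif attribute == "milia_like_cyst":
            _disc_element(mask, allowed, rng, area, 0.0003 * scale**2, 0.0012 * scale**2)
        elif attribute == "pigment_network":
            # one lattice chord: a jittered line through the lesion
            ang = rng.choice([rng.uniform(0, np.pi / 2), rng.uniform(np.pi / 2, np.pi)])
            d = np.array([np.sin(ang), np.cos(ang)])
            n = np.array([-d[1], d[0]])
            offset = rng.uniform(-0.9, 0.9) * radius
            p0 = centroid + offset * n - 1.2 * radius * d
            p1 = centroid + offset * n + 1.2 * radius * d
            _line_element(mask, allowed, rng, p0, p1, thickness=1 + int(easy))
        elif attribute == "streaks":
            ang = rng.uniform(0, 2 * np.pi)
            d = np.array([np.sin(ang), np.cos(ang)])
            r_edge = _ray_to_edge(lesion_mask, centroid, d)
            p0 = centroid + 0.70 * r_edge * d
            p1 = centroid + 1.08 * r_edge * d
            _line_element(mask, allowed, rng, p0, p1, thickness=1 + int(easy))
        else:  # negative_network
            _walk_element(mask, allowed, rng, n_steps=int(rng.integers(20, 60) * scale))
    painted = int(mask.sum())
    if painted < lo_px:
        raise RuntimeError(
            f"could not reach area fraction {lo} for {attribute} (painted {painted} px)"
        )
    return mask


def _ray_to_edge(lesion: np.ndarray, centroid: np.ndarray, direction: np.ndarray) -> float:
    """Distance from the centroid to the lesion border along a direction."""
    side = lesion.shape[0]
    r = 1.0
    while r < side:
        p = np.round(centroid + r * direction).astype(int)
        if not (0 <= p[0] < side and 0 <= p[1] < side) or not lesion[p[0], p[1]]:
            return r
        r += 1.0
    return r


# ---------------------------------------------------------------------------
# Dataset emission


_DARK_ATTRS = {"pigment_network", "globules", "streaks"}


def _paint_structures(img: np.ndarray, attribute: str, mask: np.ndarray, easy: bool) -> None:
    m = mask.astype(bool)
    if attribute in _DARK_ATTRS:
        img[m] = img[m] * (0.10 if easy else 0.40)
    else:  # hypopigmented / bright structures
        img[m] = img[m] * 0.25 + (0.90 if easy else 0.72)


def _draw_presence(rng, prevalence: dict[str, float], correlated: bool) -> dict[str, bool]:
    if not correlated:
        return {a: bool(rng.random() < prevalence.get(a, 0.0)) for a in ATTRIBUTES}
    # Gaussian-copula co-occurrence: one shared latent factor per image
    from scipy.stats import norm

    z = rng.normal()
    rho = 0.5
    out = {}
    for a in ATTRIBUTES:
        u = norm.cdf(rho * z + np.sqrt(1 - rho**2) * rng.normal())
        out[a] = bool(u < prevalence.get(a, 0.0))
    return out


def generate_dataset(config: SynthConfig, outdir) -> tuple[DatasetManifest, pd.DataFrame]:
    """Write ``n_images`` JPEGs plus ``5 * n_images`` mask PNGs.

    Returns the manifest and the generation ledger (one row per image with
    the exact painted pixel count per attribute; blanks count 0).  Also
    writes the ledger to ``<outdir>/ledger.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_images)
    rows = []
    manifest_rows = []
    for i, child in enumerate(children):
        img_seed, presence_seed, *mask_seeds = child.spawn(2 + len(ATTRIBUTES))
        image_id = f"ISIC_SYN_{i:07d}"
        img, lesion = make_lesion_image(
            config.side, img_seed, config.noise_level, config.hair_probability
        )
        presence = _draw_presence(
            np.random.default_rng(presence_seed), config.prevalence, config.correlated
        )
        ledger_row: dict = {"image_id": image_id}
        manifest_row: dict = {"image_id": image_id, "image_path": str(outdir / f"{image_id}.jpg")}
        for attr, mseed in zip(ATTRIBUTES, mask_seeds):
            if presence[attr]:
                mask = make_attribute_mask(attr, lesion, mseed, config.area_fraction, config.easy)
                _paint_structures(img, attr, mask, config.easy)
            else:
                mask = np.zeros((config.side, config.side), dtype=np.uint8)
            mask_path = outdir / f"{image_id}_attribute_{attr}.png"
            write_mask(mask_path, mask)
            ledger_row[f"painted_{attr}"] = int(mask.sum())
            manifest_row[f"mask_{attr}"] = str(mask_path)
            manifest_row[f"pos_{attr}"] = int(mask.sum())
        img_u8 = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(img_u8).save(outdir / f"{image_id}.jpg", quality=92)
        rows.append(ledger_row)
        manifest_rows.append(manifest_row)
    ledger = pd.DataFrame(rows)
    ledger.to_csv(outdir / "ledger.csv", index=False)
    return DatasetManifest(pd.DataFrame(manifest_rows)), ledger
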