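"""Synthetic ultrasound-style phantom generation.

Images emulate the statistical character of B-mode thyroid scans: a
smoothly varying tissue background under multiplicative Rayleigh speckle,
containing a small number of darker (hypoechoic) elliptical nodules with
blurred boundaries and low contrast against the surrounding texture.  The
paired binary mask is the *unblurred* ellipse union, so the foreground
fraction stays small and the boundary is deliberately harder than the
mask suggests.

Also provides the training-time augmentations: additive Gaussian noise,
histogram equalization, gamma remap, rectangular cutout and
contrast/brightness jitter.  Intensity-only operations never touch the
mask.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "augment"]


@dataclass
class PhantomSpec:
    """Distributional description of one synthetic image."""

    image_side: int = 256
    nodule_count_range: tuple[int, int] = (1, 3)
    nodule_radius_range: tuple[float, float] = (0.08, 0.2)  # fraction of side
    contrast: float = 0.35
    edge_blur_sigma: float = 2.0
    speckle_strength: float = 0.25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.nodule_radius_range
        nmax = self.nodule_count_range[1]
        # crude packing bound: total ellipse area must fit in half the frame
        if nmax * math.pi * hi * hi > 0.5:
            raise ValueError("nodule_radius_range too large for the requested count")
        if self.nodule_count_range[0] < 0 or nmax < self.nodule_count_range[0]:
            raise ValueError("invalid nodule_count_range")


def _ellipse_field(side: int, cx: float, cy: float, ax: float, ay: float,
                   theta: float) -> np.ndarray:
    """Normalized squared elliptical radius for every pixel (<=1 inside)."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    xr = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    yr = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    return (xr / ax) ** 2 + (yr / ay) ** 2


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom.

    Returns ``(image, mask)``: an 8-bit grayscale image and a boolean mask.
    Identical specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side

    # tissue background: smooth low-frequency intensity field
    base = gaussian_filter(rng.normal(0.0, 1.0, (side, side)), sigma=side / 8)
    base = 0.55 + 0.12 * base / max(base.std(), 1e-9)

    n_lo, n_hi = spec.nodule_count_range
    count = int(rng.integers(n_lo, n_hi + 1))
    mask = np.zeros((side, side), dtype=bool)
    attenuation = np.zeros((side, side))
    r_lo, r_hi = (r * side for r in spec.nodule_radius_range)
    ellipses = []
    for _ in range(count):
        ax = rng.uniform(r_lo, r_hi)
        ay = rng.uniform(r_lo, r_hi)
        margin = max(ax, ay) + 2
        cx = rng.uniform(margin, side - margin)
        cy = rng.uniform(margin, side - margin)
        theta = rng.uniform(0, math.pi)
        field = _ellipse_field(side, cx, cy, ax, ay, theta)
        mask |= field <= 1.0
        depth = spec.contrast * rng.uniform(0.7, 1.0)
        attenuation += depth * np.clip(1.0 - field, 0.0, 1.0) ** 0.5
        ellipses.append((cx, cy, ax, ay, theta))

    if spec.edge_blur_sigma > 0:
        attenuation = gaussian_filter(attenuation, sigma=spec.edge_blur_sigma)
    tissue = np.clip(base - attenuation, 0.02, 1.0)

    # multiplicative Rayleigh speckle, normalized to unit mean
    sigma = 1.0 / math.sqrt(math.pi / 2.0)
    speckle = rng.rayleigh(scale=sigma, size=(side, side))
    img = tissue * (1.0 + spec.speckle_strength * (speckle - 1.0))
    img = gaussian_filter(img, sigma=0.6)  # mild PSF smoothing
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img8, mask


def expected_foreground_fraction(spec: PhantomSpec) -> float:
    """Analytic upper bound on the mask fraction: ``n_max * pi * r_hi^2``."""
    return spec.nodule_count_range[1] * math.pi * spec.nodule_radius_range[1] ** 2


def generate_dataset(out_dir, n: int, spec: PhantomSpec | None = None,
                     seed: int = 0) -> list[str]:
    """Write ``images/*.png`` + ``masks/*.png`` pairs and a JSON manifest.

    Each image gets its own child seed derived from ``seed``; the manifest
    records the spec and all per-image seeds so any pair can be re-rendered.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    spec = spec or PhantomSpec()
    names = []
    records = []
    for i in range(n):
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        s = PhantomSpec(**{**asdict(spec), "seed": child_seed})
        s.nodule_count_range = tuple(s.nodule_count_range)
        s.nodule_radius_range = tuple(s.nodule_radius_range)
        img, mask = generate_phantom(s)
        name = f"phantom_{i:04d}.png"
        Image.fromarray(img, mode="L").save(out_dir / "images" / name)
        Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(out_dir / "masks" / name)
        names.append(name)
        rec = asdict(s)
        rec["name"] = name
        records.append(rec)
    manifest = {"seed": seed, "n": n, "images": records}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return names


# --------------------------------------------------------------- augments
def _hist_equalize(img: np.ndarray) -> np.ndarray:
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = hist.cumsum()
    nz = cdf[cdf > 0]
    if len(nz) == 0:
        return img
    cdf_min = nz[0]
    lut = np.round((cdf - cdf_min) / max(cdf[-1] - cdf_min, 1) * 255.0).clip(0, 255)
    return lut.astype(np.uint8)[img]


def augment(image: np.ndarray, mask: np.ndarray, seed: int,
            noise_sigma_range: tuple[float, float] = (0.01, 0.05),
            gamma_range: tuple[float, float] = (0.7, 1.4),
            max_cutout_area: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Apply a random subset of training augmentations to a (image, mask) pair.

    Ops: additive Gaussian noise, histogram equalization, gamma remap,
    rectangular cutout, contrast/brightness jitter.  Only the cutout is
    geometric in nature and even it leaves the mask untouched (it models
    occlusion of the image, not of the label).  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.uint8).copy()
    h, w = img.shape

    if rng.random() < 0.5:  # additive Gaussian noise
        sigma = rng.uniform(*noise_sigma_range) * 255.0
        img = np.clip(img + rng.normal(0, sigma, img.shape), 0, 255).astype(np.uint8)
    if rng.random() < 0.3:  # histogram equalization
        img = _hist_equalize(img)
    if rng.random() < 0.5:  # gamma remap
        gamma = rng.uniform(*gamma_range)
        img = np.clip(255.0 * (img / 255.0) ** gamma, 0, 255).astype(np.uint8)
    if rng.random() < 0.3:  # rectangular cutout
        area = rng.uniform(0.02, max_cutout_area) * h * w
        rh = int(np.sqrt(area * rng.uniform(0.5, 2.0)))
        rw = max(int(area / max(rh, 1)), 1)
        rh = min(max(rh, 1), h)
        rw = min(rw, w)
        top = int(rng.integers(0, h - rh + 1))
        left = int(rng.integers(0, w - rw + 1))
        img[top:top + rh, left:left + rw] = 0
    if rng.random() < 0.5:  # contrast/brightness jitter
        alpha = rng.uniform(0.8, 1.2)
        beta = rng.uniform(-20, 20)
        img = np.clip(alpha * img.astype(np.float64) + beta, 0, 255).astype(np.uint8)
    return img, np.asarray(mask).copy()
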