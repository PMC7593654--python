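"""Synthetic vessel phantoms for training and benchmarking.

Photoacoustic imaging targets are typically vasculature.  Real training
sets are usually built by segmenting vessels out of other modalities
(lung CT, retina scans), which yields two qualitatively different image
priors: one with piecewise-constant features and one with smoother
features.  This module emulates both with seeded random branching vessel
trees:

* ``family="piecewise"`` — trees rasterized with per-branch width and a
  per-structure intensity drawn from a small set of levels, so images
  take only a few distinct values;
* ``family="smooth"`` — the identical piecewise draw convolved with a
  Gaussian kernel and renormalized to peak 1.

Images are m-by-m, non-negative, with values in [0, 1].  Every image is a
pure function of its seed, and datasets carry a manifest from which they
can be regenerated bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "regenerate_from_manifest", "save_dataset", "load_dataset",
           "total_variation"]

_FAMILIES = ("piecewise", "smooth")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator (the image prior)."""

    family: str = "piecewise"
    image_size: int = 64
    n_structures: tuple[int, int] = (3, 7)
    width_range: tuple[float, float] = (1.5, 5.0)
    intensity_levels: tuple[float, ...] = (0.4, 0.7, 1.0)
    smooth_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, "
                             f"got {self.family!r}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        lo, hi = self.n_structures
        if not (1 <= lo <= hi):
            raise ValueError(f"n_structures range invalid: {self.n_structures}")
        wlo, whi = self.width_range
        if not (1.0 <= wlo <= whi <= self.image_size / 4):
            raise ValueError(
                f"width_range must lie in [1, m/4]={self.image_size / 4}, "
                f"got {self.width_range}")
        if not all(0.0 < v <= 1.0 for v in self.intensity_levels):
            raise ValueError(
                f"intensity_levels must lie in (0, 1], got "
                f"{self.intensity_levels}")
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be positive")


def _stamp_polyline(canvas: np.ndarray, pts: np.ndarray, width: float,
                    value: float) -> None:
    """Set pixels within width/2 of the sampled centerline to max(., value)."""
    m = canvas.shape[0]
    rad = width / 2.0
    r0 = max(int(np.floor(pts[:, 0].min() - rad)) - 1, 0)
    r1 = min(int(np.ceil(pts[:, 0].max() + rad)) + 2, m)
    c0 = max(int(np.floor(pts[:, 1].min() - rad)) - 1, 0)
    c1 = min(int(np.ceil(pts[:, 1].max() + rad)) + 2, m)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d2 = ((rr[:, :, None] - pts[None, None, :, 0]) ** 2
          + (cc[:, :, None] - pts[None, None, :, 1]) ** 2).min(axis=2)
    mask = d2 <= rad * rad
    region = canvas[r0:r1, c0:c1]
    region[mask] = np.maximum(region[mask], value)


def _grow_tree(canvas: np.ndarray, rng: np.random.Generator,
               spec: PhantomSpec, value: float) -> None:
    m = spec.image_size
    wlo, whi = spec.width_range
    start = rng.uniform(0.15 * m, 0.85 * m, size=2)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    width = rng.uniform(wlo, whi)

    def grow(p, angle, width, depth):
        n_seg = int(rng.integers(2, 5))
        for _ in range(n_seg):
            length = m * rng.uniform(0.08, 0.20)
            angle = angle + rng.uniform(-0.55, 0.55)
            q = p + length * np.array([np.sin(angle), np.cos(angle)])
            ts = np.linspace(0.0, 1.0, max(int(2 * length), 2))
            _stamp_polyline(canvas, p + ts[:, None] * (q - p), width, value)
            p = q
            if depth < 2 and rng.uniform() < 0.35:
                branch_angle = angle + rng.choice([-1.0, 1.0]) \
                    * rng.uniform(0.4, 1.1)
                grow(p.copy(), branch_angle, max(0.7 * width, wlo), depth + 1)

    grow(start, angle, width, 0)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate one phantom image from a spec (deterministic in the seed).

    Returns an ``image_size``-square array with values in [0, 1].  The
    piecewise family takes at most ``len(intensity_levels) + 1`` distinct
    values; the smooth family is the same draw convolved with a Gaussian
    of ``smooth_sigma`` pixels and renormalized to peak 1.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.image_size
    canvas = np.zeros((m, m))
    n_trees = int(rng.integers(spec.n_structures[0],
                               spec.n_structures[1] + 1))
    for _ in range(n_trees):
        value = float(rng.choice(np.asarray(spec.intensity_levels)))
        _grow_tree(canvas, rng, spec, value)
    if spec.family == "smooth":
        canvas = gaussian_filter(canvas, spec.smooth_sigma, mode="constant")
        peak = canvas.max()
        if peak > 0:
            canvas = canvas / peak
    return np.clip(canvas, 0.0, 1.0)


def _per_image_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence((base_seed, index)
                                      ).generate_state(1)[0] % (2 ** 31))


def generate_dataset(spec: PhantomSpec, n: int, seed: int | None = None
                     ) -> tuple[np.ndarray, dict]:
    """Generate n phantoms plus a manifest sufficient to regenerate them.

    Per-image seeds are derived by hashing (base seed, index), so the
    dataset is independent of generation order and any subset can be
    reproduced from the manifest alone.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    base_seed = spec.seed if seed is None else seed
    seeds = [_per_image_seed(base_seed, i) for i in range(n)]
    images = np.stack([
        generate_phantom(_respec(spec, s)) for s in seeds])
    manifest = {
        "family": spec.family,
        "image_size": spec.image_size,
        "n_structures": list(spec.n_structures),
        "width_range": list(spec.width_range),
        "intensity_levels": list(spec.intensity_levels),
        "smooth_sigma": spec.smooth_sigma,
        "base_seed": int(base_seed),
        "n": int(n),
        "per_image_seeds": seeds,
    }
    return images, manifest


def _respec(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return PhantomSpec(
        family=spec.family, image_size=spec.image_size,
        n_structures=spec.n_structures, width_range=spec.width_range,
        intensity_levels=spec.intensity_levels,
        smooth_sigma=spec.smooth_sigma, seed=seed)


def regenerate_from_manifest(manifest: dict) -> np.ndarray:
    """Rebuild the exact dataset described by a manifest."""
    spec = PhantomSpec(
        family=manifest["family"], image_size=manifest["image_size"],
        n_structures=tuple(manifest["n_structures"]),
        width_range=tuple(manifest["width_range"]),
        intensity_levels=tuple(manifest["intensity_levels"]),
        smooth_sigma=manifest["smooth_sigma"])
    return np.stack([generate_phantom(_respec(spec, s))
                     for s in manifest["per_image_seeds"]])


def total_variation(img: np.ndarray) -> float:
    """Anisotropic TV seminorm: sum of absolute forward differences."""
    return float(np.abs(np.diff(img, axis=0)).sum()
                 + np.abs(np.diff(img, axis=1)).sum())


def save_dataset(path, images: np.ndarray, manifest: dict) -> None:
    with h5py.File(path, "w") as h:
        d = h.create_dataset("images", data=images)
        d.attrs["manifest"] = json.dumps(manifest)


def load_dataset(path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as h:
        d = h["images"]
        return d[()], json.loads(d.attrs["manifest"])
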