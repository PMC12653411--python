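"""Synthetic stained-smear scene generator and training augmentations.

Scenes emulate the challenges of stained blood-smear microscopy: elliptical
white blood cells, each a cytoplasm region (label 1) enclosing one nucleus
(label 2) over a textured background (label 0); stain color, brightness and
contrast vary between scenes; red-blood-cell-like distractor blobs clutter
the background (they carry no label); cells may optionally touch/overlap.
Label conflicts resolve nucleus > cytoplasm > background.

The generator is fully deterministic given (spec, seed): identical inputs
produce bit-identical scenes.

Augmentations follow the stochastic policy used for training: horizontal and
vertical flips and rotation (geometric; applied identically to image and
mask, mask with nearest-neighbor resampling), plus Gaussian noise and
brightness alteration (photometric; image only), each firing independently
with probability 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

__all__ = ["SceneSpec", "AugmentationConfig", "generate_scene", "augment",
           "generate_dataset", "PackingError"]


class PackingError(RuntimeError):
    """Raised when cells cannot be placed without overlap; consider
    ``allow_overlap=True`` or fewer/smaller cells."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic smear scene.

    Ranges are (low, high) and sampled uniformly. ``nucleus_fraction`` is
    the ratio of nucleus to cytoplasm radius and must stay below 1 so every
    nucleus lies strictly inside its cytoplasm. ``distractor_density`` is
    the expected number of background blobs per pixel.
    """

    image_size: tuple[int, int] = (224, 224)
    n_cells: tuple[int, int] = (1, 4)
    cytoplasm_radius: tuple[float, float] = (20.0, 45.0)
    nucleus_fraction: tuple[float, float] = (0.45, 0.7)
    brightness_jitter: tuple[float, float] = (-0.1, 0.1)
    noise_sigma: tuple[float, float] = (0.0, 0.03)
    allow_overlap: bool = False
    distractor_density: float = 3e-4
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.nucleus_fraction[0] <= self.nucleus_fraction[1] < 1):
            raise ValueError("nucleus_fraction range must lie in (0, 1)")
        if 2 * self.cytoplasm_radius[1] >= min(self.image_size):
            raise ValueError(
                f"cytoplasm_radius {self.cytoplasm_radius} too large for "
                f"image_size {self.image_size}")


@dataclass
class AugmentationConfig:
    """Firing probabilities and magnitudes of the augmentation policy."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rotate: float = 0.5
    p_noise: float = 0.5
    p_brightness: float = 0.5
    rotation_angles: tuple[int, ...] = (90, 180, 270)
    free_angle: bool = False  # arbitrary-angle rotation, nearest-neighbor mask
    noise_sigma: float = 0.02
    brightness_delta: float = 0.15

    def __post_init__(self):
        for name in ("p_hflip", "p_vflip", "p_rotate", "p_noise",
                     "p_brightness"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


def _smooth_noise(rng, shape, sigma_px=12.0):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)


def _ellipse_mask(shape, center, radii, rotation):
    rr, cc = draw_ellipse(center[0], center[1], radii[0], radii[1],
                          shape=shape, rotation=rotation)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene.

    Returns ``(image, mask)``: image is (H, W, 3) float32 in [0, 1], mask is
    (H, W) uint8 over {0, 1, 2}.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    labels = np.zeros((H, W), dtype=np.uint8)

    # -- background: pale stain wash with low-frequency texture
    base = np.array([0.87, 0.83, 0.90]) + rng.uniform(-0.04, 0.04, 3)
    image = np.empty((H, W, 3), dtype=np.float64)
    texture = _smooth_noise(rng, (H, W))
    for ch in range(3):
        image[:, :, ch] = base[ch] + 0.02 * texture

    # -- red-blood-cell-like distractors (background label)
    n_distract = rng.poisson(spec.distractor_density * H * W)
    rbc_color = np.array([0.89, 0.62, 0.60])
    for _ in range(n_distract):
        c = (rng.uniform(0, H), rng.uniform(0, W))
        r = rng.uniform(6, 12)
        rot = rng.uniform(0, np.pi)
        blob = _ellipse_mask((H, W), c, (r, r * rng.uniform(0.8, 1.0)), rot)
        inner = _ellipse_mask((H, W), c, (r * 0.55, r * 0.55), rot)
        col = rbc_color + rng.uniform(-0.05, 0.05, 3)
        image[blob] = image[blob] * 0.25 + 0.75 * col
        image[inner] = image[inner] * 0.5 + 0.5 * (col + 0.06)  # pale center

    # -- white blood cells
    n_cells = int(rng.integers(spec.n_cells[0], spec.n_cells[1] + 1))
    occupancy = np.zeros((H, W), dtype=bool)
    cyto_color = np.array([0.72, 0.60, 0.82])
    nuc_color = np.array([0.38, 0.20, 0.55])
    for _ in range(n_cells):
        for attempt in range(60):
            ry = rng.uniform(*spec.cytoplasm_radius)
            rx = ry * rng.uniform(0.7, 1.0)
            cy = rng.uniform(ry, H - ry)
            cx = rng.uniform(rx, W - rx)
            rot = rng.uniform(0, np.pi)
            cyto = _ellipse_mask((H, W), (cy, cx), (ry, rx), rot)
            if spec.allow_overlap or not (cyto & occupancy).any():
                break
        else:
            raise PackingError(
                f"could not place {n_cells} non-overlapping cells in "
                f"{spec.image_size}; set allow_overlap=True or reduce n_cells")
        occupancy |= cyto
        frac = rng.uniform(*spec.nucleus_fraction)
        # strict 1.5 px margin keeps the nucleus 4-connected-inside cytoplasm
        n_ry = min(frac * ry, ry - 1.5)
        n_rx = min(frac * rx, rx - 1.5)
        nucleus = _ellipse_mask((H, W), (cy, cx), (max(n_ry, 1.0),
                                                   max(n_rx, 1.0)), rot)
        nucleus &= cyto
        c_col = np.clip(cyto_color + rng.uniform(-0.06, 0.06, 3), 0, 1)
        n_col = np.clip(nuc_color + rng.uniform(-0.06, 0.06, 3), 0, 1)
        image[cyto] = image[cyto] * 0.15 + 0.85 * c_col
        image[nucleus] = image[nucleus] * 0.1 + 0.9 * n_col
        labels[cyto & (labels != 2)] = 1
        labels[nucleus] = 2

    # -- photometric variation
    image += rng.uniform(*spec.brightness_jitter)
    sigma = rng.uniform(*spec.noise_sigma)
    if sigma > 0:
        image += rng.normal(0.0, sigma, image.shape)
    return np.clip(image, 0.0, 1.0).astype(np.float32), labels


def generate_dataset(n_scenes: int, spec: SceneSpec | None = None,
                     start_seed: int = 0):
    """n scenes with seeds start_seed … start_seed+n−1 (element-wise
    reproducible)."""
    spec = spec or SceneSpec()
    scenes = []
    for i in range(n_scenes):
        d = spec.__dict__.copy()
        d["seed"] = start_seed + i
        scenes.append(generate_scene(SceneSpec(**d)))
    return scenes


def augment(image: np.ndarray, mask: np.ndarray, cfg: AugmentationConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply the stochastic augmentation policy to an (image, mask) pair.

    Geometric ops transform image and mask identically; photometric ops
    touch the image only. Draw order is fixed (hflip, vflip, rotate, noise,
    brightness) so a given generator state yields a reproducible result.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask are not aligned")
    if rng.random() < cfg.p_hflip:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.random() < cfg.p_vflip:
        image, mask = image[::-1].copy(), mask[::-1].copy()
    if rng.random() < cfg.p_rotate:
        if cfg.free_angle:
            angle = float(rng.uniform(0, 360))
            image = ndimage.rotate(image, angle, reshape=False, order=1,
                                   mode="nearest")
            mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                                  mode="nearest")
        else:
            angle = int(rng.choice(cfg.rotation_angles))
            k = angle // 90
            image = np.rot90(image, k, axes=(0, 1)).copy()
            mask = np.rot90(mask, k, axes=(0, 1)).copy()
    if rng.random() < cfg.p_noise:
        image = np.clip(image + rng.normal(0, cfg.noise_sigma, image.shape),
                        0, 1).astype(np.float32)
    if rng.random() < cfg.p_brightness:
        delta = rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
        image = np.clip(image + delta, 0, 1).astype(np.float32)
    return image.astype(np.float32), mask.astype(np.uint8)
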