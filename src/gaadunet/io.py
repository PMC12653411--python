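"""Image and mask file I/O.

Masks travel as single-channel index-palette PNGs whose pixel values are the
class IDs (0 background, 1 cytoplasm, 2 nucleus). Two display palettes are
provided, matching common visualization conventions for this task:
``bluered`` (nucleus blue, cytoplasm red) and ``whitegray`` (nucleus white,
cytoplasm gray).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["save_image", "load_image", "save_mask", "load_mask",
           "list_pairs", "PALETTES"]

PALETTES = {
    "bluered": {0: (0, 0, 0), 1: (220, 40, 40), 2: (40, 60, 220)},
    "whitegray": {0: (0, 0, 0), 1: (128, 128, 128), 2: (255, 255, 255)},
}


def save_image(path, image: np.ndarray):
    """Save an (H, W, 3) float [0,1] or uint8 image as RGB PNG."""
    image = np.asarray(image)
    if image.dtype.kind == "f":
        image = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(image, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    """Load an RGB image as (H, W, 3) float32 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
    return arr / 255.0


def save_mask(path, mask: np.ndarray, palette: str = "bluered"):
    """Save an integer class mask as an index-palette PNG."""
    mask = np.asarray(mask, dtype=np.uint8)
    im = Image.fromarray(mask, mode="P")
    pal = np.zeros(768, dtype=np.uint8)
    for idx, rgb in PALETTES[palette].items():
        pal[3 * idx: 3 * idx + 3] = rgb
    im.putpalette(pal.tolist())
    im.save(path)


def load_mask(path) -> np.ndarray:
    """Load a palette or grayscale PNG as an integer class mask."""
    with Image.open(path) as im:
        if im.mode not in ("P", "L"):
            raise ValueError(
                f"{path}: expected an index-palette mask, got mode {im.mode}")
        arr = np.asarray(im, dtype=np.uint8)
    return arr


def list_pairs(data_dir) -> tuple[list[tuple[Path, Path]], list[Path]]:
    """Pair ``images/*.png`` with ``masks/*.png`` by filename.

    Returns (pairs, images_without_mask).
    """
    data_dir = Path(data_dir)
    images = sorted((data_dir / "images").glob("*.png"))
    if not images:
        raise FileNotFoundError(f"no images under {data_dir / 'images'}")
    pairs, missing = [], []
    for img in images:
        mask = data_dir / "masks" / img.name
        if mask.exists():
            pairs.append((img, mask))
        else:
            missing.append(img)
    return pairs, missing
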