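"""Image and table I/O.

Images are exchanged as PNG/TIFF/JPEG; in memory every stage works on 2-D
float arrays in [0, 1].  RGB inputs are reduced to luminance; 8- and 16-bit
integer images are rescaled by their type maximum.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "load_image",
    "save_image",
    "save_pc_stack",
    "load_manifest",
]

_LUMA = np.array([0.2125, 0.7154, 0.0721])


def load_image(path) -> np.ndarray:
    """Load a gray image as float in [0, 1] (RGB converted by luminance)."""
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return arr


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale."""
    out = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(out * 255).astype(np.uint8))


def save_pc_stack(directory, stack, prefix: str = "pc") -> list[Path]:
    """Write each oriented PC map as an 8-bit PNG (values x 255, rounded)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for o in range(stack.pc.shape[0]):
        p = directory / f"{prefix}_o{o}.png"
        save_image(p, stack.pc[o])
        paths.append(p)
    return paths


def load_manifest(manifest_path, images_dir=None):
    """Read a dataset manifest CSV and load its images.

    The manifest must have ``id`` and ``label`` columns; images are read
    from ``<images_dir>/<id>.png``.  Returns (images, labels, ids,
    manifest frame).
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("id", "label"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    images_dir = Path(images_dir) if images_dir is not None else manifest_path.parent
    images = [load_image(images_dir / f"{img_id}.png") for img_id in manifest["id"]]
    return images, list(manifest["label"]), list(manifest["id"]), manifest
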