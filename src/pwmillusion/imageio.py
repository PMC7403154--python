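"""Image and metadata I/O.

Silhouettes and stimuli travel as grayscale PNG or PGM.  Values are scaled
to [0, 1]; RGB inputs are converted with ITU-R BT.709 luma weights
(0.2126 R + 0.7152 G + 0.0722 B).  Silhouettes on disk are usually
luminance-coded (dark figure on light background), so
:func:`read_source_image` inverts by default to obtain the signal map
(figure = 1) expected by the renderer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .halftone import HalftoneImage, SourceImage

__all__ = [
    "read_gray",
    "read_source_image",
    "read_halftone_image",
    "write_image",
    "write_metadata",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_gray(path) -> np.ndarray:
    """Read any PNG/PGM as a float array in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # pragma: no cover - depends on file contents
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
        scale = 255.0
    else:
        arr = arr.astype(float)
        scale = {np.uint8: 255.0, np.uint16: 65535.0}.get(
            np.asarray(img).dtype.type, float(arr.max()) or 1.0)
    return np.clip(arr / scale, 0.0, 1.0)


def read_source_image(path, binarize: bool = True,
                      invert: bool = True) -> SourceImage:
    """Load a silhouette as a signal map.

    ``invert=True`` (default) treats dark pixels as the figure; with
    ``binarize`` the result is thresholded at 0.5.
    """
    arr = read_gray(path)
    if invert:
        arr = 1.0 - arr
    if binarize:
        arr = (arr >= 0.5).astype(float)
    return SourceImage(arr)


def read_halftone_image(path) -> HalftoneImage:
    """Load a rendered binary stimulus (0 = ink)."""
    arr = read_gray(path)
    return HalftoneImage((arr >= 0.5).astype(float))


def write_image(path, image) -> None:
    """Write an array, SourceImage or HalftoneImage as 8-bit grayscale.

    HalftoneImage values are written as-is (0 = black ink); SourceImage is
    written luminance-coded (figure = dark) so a write/read round trip with
    the default flags is the identity.
    """
    path = Path(path)
    if isinstance(image, HalftoneImage):
        arr = image.values
    elif isinstance(image, SourceImage):
        arr = 1.0 - image.values
    else:
        arr = np.asarray(image, dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        if lo < 0.0 or hi > 1.0:
            arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def write_metadata(path, params: dict) -> None:
    """Write a JSON sidecar with every parameter of a run."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True,
                                     default=default) + "\n")
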