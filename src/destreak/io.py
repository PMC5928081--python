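"""Image and dataset file I/O.

Two complementary containers are used throughout the pipeline:

* 16-bit grayscale PNG/TIFF for previews and user-supplied slices.  Pixel
  values are stored as rounded counts on the 12-bit scale (0..4095 inside a
  16-bit container), the convention of stored CT data; export clips, the
  in-memory pipeline never does.
* a lossless float container (``.npz``) carrying the raw float64 pixels plus
  pixel size, intensity scale and metadata, for exact round-trips inside the
  pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantoms import Image2D, INTENSITY_SCALE_12BIT

__all__ = [
    "write_image_u16",
    "read_image_u16",
    "save_image_npz",
    "load_image_npz",
    "read_image_any",
]


def write_image_u16(path, image: Image2D) -> None:
    """Export as 16-bit grayscale PNG/TIFF, clipped to [0, intensity_scale]."""
    counts = np.clip(np.rint(image.pixels), 0, image.intensity_scale)
    iio.imwrite(Path(path), counts.astype(np.uint16))


def read_image_u16(
    path,
    pixel_size: float = 0.61,
    intensity_scale: float = INTENSITY_SCALE_12BIT,
) -> Image2D:
    """Read a 16-bit grayscale image into the float pipeline representation."""
    arr = np.asarray(iio.imread(Path(path))).astype(np.float64)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=-1)
    return Image2D(arr, pixel_size=pixel_size, intensity_scale=intensity_scale)


def save_image_npz(path, image: Image2D) -> None:
    np.savez(
        Path(path),
        pixels=image.pixels,
        pixel_size=image.pixel_size,
        intensity_scale=image.intensity_scale,
        meta=np.frombuffer(json.dumps(image.meta).encode(), dtype=np.uint8),
    )


def load_image_npz(path) -> Image2D:
    with np.load(Path(path)) as z:
        return Image2D(
            z["pixels"],
            pixel_size=float(z["pixel_size"]),
            intensity_scale=float(z["intensity_scale"]),
            meta=json.loads(bytes(z["meta"]).decode()) if "meta" in z else {},
        )


def read_image_any(path, **kwargs) -> Image2D:
    """Dispatch on suffix: ``.npz`` float container, else 16-bit grayscale."""
    p = Path(path)
    if p.suffix == ".npz":
        return load_image_npz(p)
    return read_image_u16(p, **kwargs)
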