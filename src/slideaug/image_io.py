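"""Reading and writing slide preview images and their annotation masks.

The canonical in-memory model used throughout the package:

* an RGB preview image is a ``(H, W, 3)`` ``uint8`` array (top-left origin,
  ``x`` = column, ``y`` = row, 0-based);
* a binary mask is a ``(H, W)`` ``uint8`` array with values in ``{0, 255}``,
  foreground (region of interest) white;
* an annotated preview is stored on disk as a two-page TIFF — page 1 the
  native RGB preview, page 2 the binary mask.

Annotation TIFFs are written as baseline multi-page TIFF, 8-bit,
uncompressed by default (optional deflate); the container layout is fixed,
the encoding is a compatible choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import FormatError

FOREGROUND = 255
BACKGROUND = 0

#: Binarization threshold for nominally black/white hand-drawn masks; guards
#: against antialiased label edges.
MASK_THRESHOLD = 127


def binarize(mask: np.ndarray) -> np.ndarray:
    """Normalize a mask to ``uint8`` values in ``{0, 255}``.

    Boolean and {0, 1}-valued masks map foreground to 255 directly; any
    other grayscale mask is thresholded at the midpoint (> 127 -> 255).
    Idempotent.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise FormatError(f"mask must be 2-D, got shape {m.shape}")
    if m.dtype == bool:
        return m.astype(np.uint8) * np.uint8(FOREGROUND)
    if m.size > 0 and m.max() <= 1:
        return (m > 0).astype(np.uint8) * np.uint8(FOREGROUND)
    return np.where(m > MASK_THRESHOLD, FOREGROUND, BACKGROUND).astype(np.uint8)


def as_rgb(image: np.ndarray) -> np.ndarray:
    """Coerce an image array to ``(H, W, 3)`` ``uint8``.

    Grayscale inputs are promoted by channel replication; an alpha channel
    is dropped.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"cannot interpret shape {np.asarray(image).shape} as RGB")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) and arr.size and arr.max() <= 1.0:
            arr = arr * 255.0
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


def _as_single_channel(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"cannot interpret shape {np.asarray(mask).shape} as a mask")
    return arr


@dataclass
class PreviewSample:
    """An RGB slide preview with an optional binary annotation mask.

    ``tissue_mask`` holds whichever region-of-interest layer the sample was
    annotated with — the tissue outline for preview annotations, or the
    artifact region for labeled artifact source images.
    """

    image: np.ndarray
    tissue_mask: np.ndarray | None = None
    identifier: str = field(default="")

    def __post_init__(self) -> None:
        self.image = as_rgb(self.image)
        if self.tissue_mask is not None:
            self.tissue_mask = binarize(_as_single_channel(self.tissue_mask))
            if self.tissue_mask.shape != self.image.shape[:2]:
                raise FormatError(
                    f"mask shape {self.tissue_mask.shape} does not match "
                    f"image shape {self.image.shape[:2]}"
                )

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def copy(self) -> "PreviewSample":
        return PreviewSample(
            image=self.image.copy(),
            tissue_mask=None if self.tissue_mask is None else self.tissue_mask.copy(),
            identifier=self.identifier,
        )


def read_multilayer_tif(path: str | Path) -> PreviewSample:
    """Read a two-page annotation TIFF (page 1 image, page 2 mask)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if n_pages < 2:
            raise FormatError(
                f"{path} has {n_pages} page(s); a multilayer annotation TIFF "
                "needs at least 2 (image + mask)"
            )
        image = tif.pages[0].asarray()
        mask = tif.pages[1].asarray()
    image = as_rgb(image)
    mask = _as_single_channel(mask)
    if mask.shape != image.shape[:2]:
        raise FormatError(
            f"page dimensions differ: image {image.shape[:2]} vs mask {mask.shape}"
        )
    return PreviewSample(image=image, tissue_mask=mask, identifier=path.stem)


def write_multilayer_tif(
    sample: PreviewSample, path: str | Path, *, compress: bool = False
) -> None:
    """Write a sample as a two-page TIFF; requires an annotation mask."""
    if sample.tissue_mask is None:
        raise ValueError("sample has no mask; a multilayer TIFF needs both pages")
    compression = "deflate" if compress else None
    with tifffile.TiffWriter(Path(path)) as writer:
        writer.write(sample.image, photometric="rgb", compression=compression)
        writer.write(
            sample.tissue_mask, photometric="minisblack", compression=compression
        )


def read_image_mask_pair(
    image_path: str | Path, mask_path: str | Path
) -> PreviewSample:
    """Read a plain image/mask file pair (PNG or single-page TIFF)."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    image = as_rgb(iio.imread(image_path))
    mask = _as_single_channel(iio.imread(mask_path))
    if mask.shape != image.shape[:2]:
        raise FormatError(
            f"dimension mismatch: image {image.shape[:2]} ({image_path.name}) "
            f"vs mask {mask.shape} ({mask_path.name})"
        )
    return PreviewSample(image=image, tissue_mask=mask, identifier=image_path.stem)


def read_image(path: str | Path) -> np.ndarray:
    """Read a plain RGB image file."""
    return as_rgb(iio.imread(Path(path)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a plain mask file, binarized."""
    return binarize(_as_single_channel(iio.imread(Path(path))))


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), as_rgb(image))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), binarize(mask))
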