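"""Artifact extraction and the reusable overlay bank.

Artifact instances (felt-pen markings, air bubbles, dirt speckles, brand
marks) are cut out of labeled source images whose mask paints the artifact
region white.  Each instance is stored in *canonical white-background form*:
every pixel outside the artifact mask is 255 on all channels, which makes
the subtractive blend an identity there — no conditional masking is needed
at composition time.

Bank directory layout::

    <dir>/manifest.json
    <dir>/<category>/<id>.png        # canonical patch
    <dir>/<category>/<id>.mask.png   # binary artifact mask
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import image_io
from .exceptions import FormatError
from .image_io import PreviewSample, as_rgb, binarize

CATEGORIES = ("felt_pen", "bubble", "dirt", "brand_mark")

#: Bounding-box margin around each component, so that later 3x3 blurs
#: (scratch transform) never touch crop borders.
CROP_MARGIN = 2

#: Components smaller than this are treated as labeling specks and dropped.
DEFAULT_MIN_AREA = 9


def canonicalize(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Whiten every pixel outside the mask (white-background form)."""
    out = as_rgb(patch).copy()
    out[binarize(mask) == 0] = 255
    return out


@dataclass
class ArtifactOverlay:
    """A cropped artifact patch with its binary mask and category tag.

    Invariants (enforced at construction): patch and mask share dimensions,
    the mask has at least one foreground pixel, and the patch is canonical
    (255 outside the mask).
    """

    patch: np.ndarray
    mask: np.ndarray
    category: str
    source_id: str = ""
    overlay_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        self.mask = binarize(np.asarray(self.mask))
        self.patch = as_rgb(self.patch)
        if self.patch.shape[:2] != self.mask.shape:
            raise ValueError(
                f"patch shape {self.patch.shape[:2]} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise ValueError("artifact mask has no foreground pixel")
        self.patch = canonicalize(self.patch, self.mask)
        if not self.overlay_id:
            self.overlay_id = self.source_id or "overlay"

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def area(self) -> int:
        """Foreground pixel count of the artifact mask."""
        return int(np.count_nonzero(self.mask))

    def copy(self) -> "ArtifactOverlay":
        return ArtifactOverlay(
            patch=self.patch.copy(),
            mask=self.mask.copy(),
            category=self.category,
            source_id=self.source_id,
            overlay_id=self.overlay_id,
        )


class ArtifactBank:
    """An in-memory collection of overlays, retrievable by category or id."""

    def __init__(self, overlays: list[ArtifactOverlay] | None = None) -> None:
        self.overlays: list[ArtifactOverlay] = list(overlays or [])

    def __len__(self) -> int:
        return len(self.overlays)

    def __iter__(self):
        return iter(self.overlays)

    def add(self, overlay: ArtifactOverlay) -> None:
        self.overlays.append(overlay)

    @property
    def categories_present(self) -> set[str]:
        return {o.category for o in self.overlays}

    def by_category(self, category: str) -> list[ArtifactOverlay]:
        return [o for o in self.overlays if o.category == category]

    def get(self, overlay_id: str) -> ArtifactOverlay:
        for o in self.overlays:
            if o.overlay_id == overlay_id:
                return o
        raise KeyError(overlay_id)


# 8-connectivity: thin diagonal felt-pen strokes stay in one piece.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def extract_artifacts(
    source: PreviewSample,
    category: str,
    min_area: int = DEFAULT_MIN_AREA,
    *,
    split_components: bool = True,
) -> list[ArtifactOverlay]:
    """Extract artifact overlays from a labeled source image.

    One overlay per 8-connected foreground component of the source mask with
    area >= ``min_area``, cropped to the component bounding box plus a
    2-pixel margin (clipped at the image border); pixels inside the crop but
    outside the component are whitened.  Overlays are ordered by component
    top-left corner, row-major.

    With ``split_components=False`` the whole mask is extracted as a single
    overlay (one crop around the union of all components).
    """
    if source.tissue_mask is None:
        raise ValueError("source sample has no artifact mask")
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    mask = source.tissue_mask > 0
    if not mask.any():
        return []

    if not split_components:
        if int(mask.sum()) < min_area:
            return []
        regions = [mask]
    else:
        labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
        regions = [labels == i for i in range(1, n + 1)]
        regions = [r for r in regions if int(r.sum()) >= min_area]

    h, w = mask.shape
    items: list[tuple[tuple[int, int], ArtifactOverlay]] = []
    for region in regions:
        rows, cols = np.nonzero(region)
        r0, r1 = int(rows.min()), int(rows.max())
        c0, c1 = int(cols.min()), int(cols.max())
        r0m, r1m = max(0, r0 - CROP_MARGIN), min(h, r1 + CROP_MARGIN + 1)
        c0m, c1m = max(0, c0 - CROP_MARGIN), min(w, c1 + CROP_MARGIN + 1)
        comp_mask = region[r0m:r1m, c0m:c1m]
        patch = canonicalize(source.image[r0m:r1m, c0m:c1m], comp_mask)
        overlay = ArtifactOverlay(
            patch=patch,
            mask=comp_mask,
            category=category,
            source_id=source.identifier,
        )
        items.append(((r0, c0), overlay))

    items.sort(key=lambda t: t[0])
    overlays = []
    for i, (_, overlay) in enumerate(items):
        overlay.overlay_id = f"{source.identifier or category}_{i:03d}"
        overlays.append(overlay)
    return overlays


def save_bank(bank: ArtifactBank, directory: str | Path) -> None:
    """Write a bank as per-overlay PNG pairs plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for overlay in bank:
        cat_dir = directory / overlay.category
        cat_dir.mkdir(exist_ok=True)
        image_io.write_image(overlay.patch, cat_dir / f"{overlay.overlay_id}.png")
        image_io.write_mask(overlay.mask, cat_dir / f"{overlay.overlay_id}.mask.png")
        entries.append(
            {
                "id": overlay.overlay_id,
                "category": overlay.category,
                "source_id": overlay.source_id,
                "width": overlay.width,
                "height": overlay.height,
            }
        )
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def load_bank(directory: str | Path) -> ArtifactBank:
    """Load a bank written by :func:`save_bank`."""
    directory = Path(directory)
    manifest = directory / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    try:
        entries = json.loads(manifest.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt bank manifest {manifest}: {exc}") from exc
    if not isinstance(entries, list):
        raise FormatError(f"corrupt bank manifest {manifest}: expected a list")

    bank = ArtifactBank()
    for entry in entries:
        try:
            oid, category = entry["id"], entry["category"]
            source_id = entry.get("source_id", "")
        except (TypeError, KeyError) as exc:
            raise FormatError(f"corrupt manifest entry {entry!r}: {exc}") from exc
        patch_path = directory / category / f"{oid}.png"
        mask_path = directory / category / f"{oid}.mask.png"
        for p in (patch_path, mask_path):
            if not p.exists():
                raise FormatError(f"manifest references missing file {p}")
        bank.add(
            ArtifactOverlay(
                patch=image_io.read_image(patch_path),
                mask=image_io.read_mask(mask_path),
                category=category,
                source_id=source_id,
                overlay_id=oid,
            )
        )
    return bank
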