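"""Placing transformed overlays onto preview images.

Brightfield microscopy images multiply transmitted light, so the correct
way to add an artifact to a preview is subtractive: the negative of the
artifact overlay (its *strength*) is subtracted from the preview,

    I_out(x, y, c) = max(0, I_in(x, y, c) + I_over(x~, y~, c) - 255),

where ``I_over`` is the canonical white-background overlay patch.  Outside
the artifact mask the patch is 255 and the blend is an identity; inside,
the darker of preview and overlay dominates, which preserves the visual
appearance of both tissue and artifact.

Placement handles all four size cases: an overlay narrower/shorter than the
preview gets a uniform random offset on that axis; a wider/taller overlay
sits at offset 0 and a uniform random crop window of the overlay is used.
The ground-truth tissue mask passes through augmentation unchanged — the
detector is trained to find tissue despite artifacts, so artifacts are
background for the segmentation label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bank import ArtifactBank, ArtifactOverlay
from .config import AugmentationConfig
from .exceptions import ConfigurationError, ParameterError
from .image_io import PreviewSample
from .transforms import TransformParams, apply_chain, sample_params


def blend_pixel(i_in: int, i_over: int) -> int:
    """Subtractive blend of one channel value pair (both in [0, 255])."""
    return max(0, int(i_in) + int(i_over) - 255)


@dataclass(frozen=True)
class Placement:
    """Offsets (and crop-window starts) of one overlay on one preview.

    On each axis independently: if the overlay fits, ``x0``/``y0`` is the
    offset and the crop start is 0; if it exceeds the preview, the offset is
    0 and ``crop_x``/``crop_y`` selects which overlay window is used.
    """

    x0: int = 0
    y0: int = 0
    crop_x: int = 0
    crop_y: int = 0

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0,
                "crop_x": self.crop_x, "crop_y": self.crop_y}

    @classmethod
    def from_dict(cls, data: dict) -> "Placement":
        return cls(**data)


def _validate_axis(offset: int, crop: int, overlay_dim: int, preview_dim: int,
                   axis: str) -> None:
    if overlay_dim <= preview_dim:
        if crop != 0 or not 0 <= offset <= preview_dim - overlay_dim:
            raise ParameterError(
                f"invalid {axis} placement: offset {offset}, crop {crop} for "
                f"overlay {overlay_dim} in preview {preview_dim}"
            )
    else:
        if offset != 0 or not 0 <= crop <= overlay_dim - preview_dim:
            raise ParameterError(
                f"invalid {axis} placement: offset {offset}, crop {crop} for "
                f"overlay {overlay_dim} in preview {preview_dim}"
            )


def sample_placement(
    preview_dims: tuple[int, int],
    overlay_dims: tuple[int, int],
    rng: np.random.Generator,
) -> Placement:
    """Draw a uniform placement; dims are (height, width).

    Every size combination admits a valid placement, so this never fails.
    """
    ph, pw = preview_dims
    oh, ow = overlay_dims
    if min(ph, pw, oh, ow) < 1:
        raise ParameterError("all dimensions must be >= 1")
    if ow <= pw:
        x0, crop_x = int(rng.integers(0, pw - ow + 1)), 0
    else:
        x0, crop_x = 0, int(rng.integers(0, ow - pw + 1))
    if oh <= ph:
        y0, crop_y = int(rng.integers(0, ph - oh + 1)), 0
    else:
        y0, crop_y = 0, int(rng.integers(0, oh - ph + 1))
    return Placement(x0=x0, y0=y0, crop_x=crop_x, crop_y=crop_y)


def compose(
    preview: PreviewSample,
    overlay: ArtifactOverlay,
    placement: Placement,
) -> tuple[PreviewSample, np.ndarray]:
    """Blend one overlay onto a preview at the given placement.

    Returns the augmented sample (tissue mask unchanged) and the artifact
    footprint — the overlay mask positioned in preview coordinates.  Pixels
    outside the footprint are bit-identical to the input.
    """
    ph, pw = preview.height, preview.width
    oh, ow = overlay.height, overlay.width
    _validate_axis(placement.x0, placement.crop_x, ow, pw, "x")
    _validate_axis(placement.y0, placement.crop_y, oh, ph, "y")

    eff_w, eff_h = min(ow, pw), min(oh, ph)
    src = (slice(placement.crop_y, placement.crop_y + eff_h),
           slice(placement.crop_x, placement.crop_x + eff_w))
    dst = (slice(placement.y0, placement.y0 + eff_h),
           slice(placement.x0, placement.x0 + eff_w))

    out = preview.copy()
    window = out.image[dst].astype(np.int16)
    patch = overlay.patch[src].astype(np.int16)
    out.image[dst] = np.maximum(window + patch - 255, 0).astype(np.uint8)

    footprint = np.zeros((ph, pw), dtype=np.uint8)
    footprint[dst] = overlay.mask[src]
    return out, footprint


@dataclass
class AugmentationRecord:
    """Provenance of one placed overlay; sufficient for bit-exact replay."""

    overlay_id: str
    source_id: str
    category: str
    params: TransformParams
    placement: Placement
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "overlay_id": self.overlay_id,
            "source_id": self.source_id,
            "category": self.category,
            "params": self.params.to_dict(),
            "placement": self.placement.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AugmentationRecord":
        return cls(
            overlay_id=data["overlay_id"],
            source_id=data.get("source_id", ""),
            category=data["category"],
            params=TransformParams.from_dict(data["params"]),
            placement=Placement.from_dict(data["placement"]),
            seed=data.get("seed"),
        )


def augment_sample(
    preview: PreviewSample,
    bank: ArtifactBank,
    config: AugmentationConfig,
    rng: np.random.Generator,
    sample_type: str | None = None,
    seed: int | None = None,
) -> tuple[PreviewSample, list[AugmentationRecord], list[np.ndarray]]:
    """Place ``k`` random transformed overlays on one preview.

    ``k`` is drawn uniformly from the configured overlay-count bounds; for
    each overlay a category is drawn by configured weight (respecting the
    sample type's exclusions), an overlay of that category uniformly, then
    transform parameters and a placement.  Overlays blend sequentially, so
    later overlays compose over earlier results.  Returns the augmented
    sample, one provenance record per overlay, and the matching footprints.
    """
    lo, hi = config.overlay_count
    k = int(rng.integers(lo, hi + 1))
    allowed = [
        c for c in config.allowed_categories(sample_type)
        if bank.by_category(c)
    ]
    if k > 0 and not allowed:
        raise ConfigurationError(
            "no overlays available: bank categories "
            f"{sorted(bank.categories_present)} after exclusions for "
            f"sample type {sample_type!r}"
        )

    weights = np.array([config.category_weights[c] for c in allowed], dtype=float)
    out = preview.copy()
    records: list[AugmentationRecord] = []
    footprints: list[np.ndarray] = []
    for _ in range(k):
        category = str(rng.choice(allowed, p=weights / weights.sum()))
        candidates = bank.by_category(category)
        overlay = candidates[int(rng.integers(0, len(candidates)))]
        params = sample_params(config, category, rng)
        transformed = apply_chain(overlay, params)
        placement = sample_placement(
            (out.height, out.width),
            (transformed.height, transformed.width),
            rng,
        )
        out, footprint = compose(out, transformed, placement)
        records.append(
            AugmentationRecord(
                overlay_id=overlay.overlay_id,
                source_id=overlay.source_id,
                category=category,
                params=params,
                placement=placement,
                seed=seed,
            )
        )
        footprints.append(footprint)
    return out, records, footprints


def replay_records(
    preview: PreviewSample,
    bank: ArtifactBank,
    records: list[AugmentationRecord],
) -> PreviewSample:
    """Re-run a recorded augmentation; bit-exact given the same bank."""
    out = preview.copy()
    for record in records:
        overlay = apply_chain(bank.get(record.overlay_id), record.params)
        out, _ = compose(out, overlay, record.placement)
    return out
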