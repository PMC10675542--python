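"""The seven overlay transformations.

Geometric transforms (scaling, rotation, mirroring) apply to every artifact
category; content transforms (hue replacement, scratches, Perlin fading,
intensity scaling) are specific to felt-pen markings.  Content transforms
operate in *strength* space: the strength of a canonical white-background
patch is ``255 - intensity`` inside the artifact mask and 0 outside — it is
the quantity the compositing step subtracts from the preview image, so
attenuating strength makes the placed artifact fainter.  Scratch, Perlin
fading and intensity scaling only ever reduce strength, and no content
transform touches a pixel outside the artifact mask.

All randomness comes from explicit ``numpy.random.Generator`` arguments or
from sub-seeds stored in :class:`TransformParams`, so a parameter set fully
determines the transform chain.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

from .bank import ArtifactOverlay, canonicalize
from .config import MIRROR_AXES, AugmentationConfig, CategoryTransformConfig
from .exceptions import ParameterError
from .noise import normalized_perlin

_MAX_SUBSEED = 2**31 - 1


@dataclass(frozen=True)
class TransformParams:
    """One fully-determined draw of the transform chain.

    Identity values (``scale_factor=1``, ``rotation_angle=0``,
    ``mirror_axis='none'``, ``hue_value=None``, ``scratch_count=0``,
    ``perlin_weight=0``, ``intensity_factor=1``) leave the overlay
    untouched.  ``scratch_seed`` and ``perlin_seed`` pin the scratch-line
    geometry and the noise field, so replaying the same parameters is
    bit-exact.
    """

    scale_factor: float = 1.0
    rotation_angle: int = 0
    mirror_axis: str = "none"
    hue_value: int | None = None
    scratch_count: int = 0
    scratch_factor: float = 0.0
    perlin_weight: float = 0.0
    perlin_octaves: float = 4.0
    perlin_threshold: float | None = None
    perlin_normalize: bool = True
    intensity_factor: float = 1.0
    scratch_seed: int = 0
    perlin_seed: int = 0

    def is_identity(self) -> bool:
        return (
            self.scale_factor == 1.0
            and self.rotation_angle == 0
            and self.mirror_axis == "none"
            and self.hue_value is None
            and self.scratch_count == 0
            and self.perlin_weight == 0.0
            and self.intensity_factor == 1.0
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TransformParams":
        return cls(**data)


# ---------------------------------------------------------------------------
# strength-space helpers


def strength_field(overlay: ArtifactOverlay) -> np.ndarray:
    """Per-pixel artifact strength: ``255 - patch`` inside the mask, 0 outside."""
    s = 255 - overlay.patch.astype(np.int32)
    s[overlay.mask == 0] = 0
    return s


def _from_strength(strength: np.ndarray, overlay: ArtifactOverlay) -> ArtifactOverlay:
    patch = (255 - np.clip(strength, 0, 255)).astype(np.uint8)
    patch[overlay.mask == 0] = 255
    return replace_patch(overlay, patch)


def replace_patch(
    overlay: ArtifactOverlay,
    patch: np.ndarray,
    mask: np.ndarray | None = None,
) -> ArtifactOverlay:
    return ArtifactOverlay(
        patch=patch,
        mask=overlay.mask if mask is None else mask,
        category=overlay.category,
        source_id=overlay.source_id,
        overlay_id=overlay.overlay_id,
    )


def _ensure_nonempty(mask: np.ndarray, original: ArtifactOverlay) -> np.ndarray:
    # Nearest-neighbour resampling can drop a 1-2 px artifact entirely;
    # keep the invariant (>= 1 foreground pixel) by marking the centre.
    if not mask.any():
        mask = mask.copy()
        mask[mask.shape[0] // 2, mask.shape[1] // 2] = 255
    return mask


# ---------------------------------------------------------------------------
# geometric transforms


def scale_overlay(overlay: ArtifactOverlay, factor: float) -> ArtifactOverlay:
    """Uniform dilation by ``factor``; new dims = floor(dim * factor + 0.5)."""
    if factor <= 0:
        raise ParameterError(f"scale factor must be positive, got {factor}")
    h, w = overlay.mask.shape
    h2 = max(1, int(np.floor(h * factor + 0.5)))
    w2 = max(1, int(np.floor(w * factor + 0.5)))
    if (h2, w2) == (h, w):
        return overlay.copy()
    patch = sktransform.resize(
        overlay.patch.astype(float),
        (h2, w2),
        order=1,
        preserve_range=True,
        anti_aliasing=factor < 1.0,
    )
    mask = sktransform.resize(
        overlay.mask,
        (h2, w2),
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    ).astype(np.uint8)
    mask = _ensure_nonempty(mask, overlay)
    patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
    return replace_patch(overlay, canonicalize(patch, mask), mask)


def rotate_overlay(overlay: ArtifactOverlay, angle: int) -> ArtifactOverlay:
    """Rotate counter-clockwise about the patch centre, expanding the canvas.

    Multiples of 90 degrees are exact index permutations; other angles use
    bilinear resampling for the patch and nearest-neighbour for the mask.
    Newly exposed canvas lies outside the rotated mask and is whitened in
    the canonical patch, so the fill value never reaches the output.
    """
    angle = int(angle)
    if not 0 <= angle <= 359:
        raise ParameterError(f"rotation angle must be in [0, 359], got {angle}")
    if angle == 0:
        return overlay.copy()
    if angle % 90 == 0:
        k = angle // 90
        return replace_patch(
            overlay, np.rot90(overlay.patch, k).copy(), np.rot90(overlay.mask, k).copy()
        )
    patch = sktransform.rotate(
        overlay.patch.astype(float),
        angle,
        resize=True,
        order=1,
        preserve_range=True,
        cval=255.0,
    )
    mask = sktransform.rotate(
        overlay.mask,
        angle,
        resize=True,
        order=0,
        preserve_range=True,
        cval=0,
    ).astype(np.uint8)
    mask = _ensure_nonempty(mask, overlay)
    patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
    return replace_patch(overlay, canonicalize(patch, mask), mask)


def mirror_overlay(overlay: ArtifactOverlay, axis: str) -> ArtifactOverlay:
    """Flip patch and mask identically; ``horizontal`` flips left-right."""
    if axis not in MIRROR_AXES:
        raise ParameterError(f"mirror axis must be one of {MIRROR_AXES}, got {axis!r}")
    patch, mask = overlay.patch, overlay.mask
    if axis in ("horizontal", "both"):
        patch, mask = patch[:, ::-1], mask[:, ::-1]
    if axis in ("vertical", "both"):
        patch, mask = patch[::-1], mask[::-1]
    return replace_patch(overlay, patch.copy(), mask.copy())


# ---------------------------------------------------------------------------
# content transforms (felt pen)


def hue_set(overlay: ArtifactOverlay, hue: int) -> ArtifactOverlay:
    """Replace the HSV hue of all masked pixels, keeping saturation and value.

    ``hue`` is in half-degree units [0, 180] (180 wraps to 0); saturation
    and value survive the RGB/HSV round trip to within one 8-bit level.
    """
    hue = int(hue)
    if not 0 <= hue <= 180:
        raise ParameterError(f"hue must be in [0, 180], got {hue}")
    hsv = rgb2hsv(overlay.patch.astype(float) / 255.0)
    hsv[:, :, 0] = (hue % 180) / 180.0
    rgb = np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    patch = overlay.patch.copy()
    fg = overlay.mask > 0
    patch[fg] = rgb[fg]
    return replace_patch(overlay, patch)


def add_scratches(
    overlay: ArtifactOverlay,
    count: int,
    rng: np.random.Generator,
    factors: float | list[float] | None = None,
    factor_range: tuple[float, float] = (0.0, 0.2),
) -> ArtifactOverlay:
    """Scratch the overlay with one-pixel lines between random image edges.

    Each line carries an attenuation factor ``f`` (drawn uniformly from
    ``factor_range`` unless ``factors`` is given); a weight map holding
    ``f`` on line pixels is blurred with a 3x3 mean kernel, and the strength
    field is multiplied by the blurred factor where the (blur-widened) lines
    intersect the artifact mask.  Pixels outside the mask, and masked pixels
    away from every line, are untouched.
    """
    if count < 0:
        raise ParameterError(f"scratch count must be >= 0, got {count}")
    if count == 0:
        return overlay.copy()
    h, w = overlay.mask.shape
    if isinstance(factors, (int, float)):
        factors = [float(factors)] * count
    weights = np.zeros((h, w), dtype=float)
    indicator = np.zeros((h, w), dtype=float)
    for i in range(count):
        r0, c0, r1, c1 = _edge_endpoints(h, w, rng)
        if factors is None:
            f = float(rng.uniform(*factor_range))
        else:
            f = float(factors[i])
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"scratch factor must be in [0, 1], got {f}")
        rr, cc = skdraw.line(r0, c0, r1, c1)
        weights[rr, cc] = f
        indicator[rr, cc] = 1.0
    blurred = ndimage.uniform_filter(weights, size=3, mode="constant")
    spread = ndimage.uniform_filter(indicator, size=3, mode="constant")
    region = (spread > 1e-12) & (overlay.mask > 0)
    s = strength_field(overlay).astype(float)
    s[region] = np.rint(s[region] * np.clip(blurred[region], 0.0, 1.0)[:, None])
    return _from_strength(s.astype(np.int32), overlay)


def _edge_endpoints(
    h: int, w: int, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    """Two random points on two distinct, randomly chosen image edges."""
    edges = rng.choice(4, size=2, replace=False)  # 0 top, 1 bottom, 2 left, 3 right
    pts = []
    for edge in edges:
        if edge == 0:
            pts.append((0, int(rng.integers(0, w))))
        elif edge == 1:
            pts.append((h - 1, int(rng.integers(0, w))))
        elif edge == 2:
            pts.append((int(rng.integers(0, h)), 0))
        else:
            pts.append((int(rng.integers(0, h)), w - 1))
    (r0, c0), (r1, c1) = pts
    return r0, c0, r1, c1


def perlin_fade(
    overlay: ArtifactOverlay,
    weight: float,
    octaves: float = 4.0,
    threshold: float | None = None,
    normalize: bool = True,
    rng: np.random.Generator | None = None,
) -> ArtifactOverlay:
    """Fade random regions of the overlay with a Perlin-noise weighting.

    The strength field is multiplied by ``1 - weight * noise`` inside the
    mask, with the noise field in [0, 1]; fading can only lighten the
    artifact, never darken it.
    """
    if not 0.0 <= weight <= 1.0:
        raise ParameterError(f"perlin weight must be in [0, 1], got {weight}")
    if weight == 0.0:
        return overlay.copy()
    noise = normalized_perlin(
        overlay.mask.shape, cells=octaves, rng=rng,
        threshold=threshold, normalize=normalize,
    )
    s = strength_field(overlay).astype(float)
    fg = overlay.mask > 0
    s[fg] = np.rint(s[fg] * (1.0 - weight * noise[fg])[:, None])
    return _from_strength(s.astype(np.int32), overlay)


def intensity_scale(overlay: ArtifactOverlay, factor: float) -> ArtifactOverlay:
    """Scale artifact strength by ``factor``: patch' = 255 - factor*(255-patch)."""
    if not 0.0 < factor <= 1.0:
        raise ParameterError(f"intensity factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return overlay.copy()
    s = strength_field(overlay).astype(float)
    fg = overlay.mask > 0
    s[fg] = np.rint(s[fg] * factor)
    return _from_strength(s.astype(np.int32), overlay)


# ---------------------------------------------------------------------------
# parameter sampling and the chain


def sample_params(
    config: AugmentationConfig,
    category: str,
    rng: np.random.Generator,
) -> TransformParams:
    """Draw one parameter set for ``category`` from the configured ranges.

    Disabled transforms yield identity values.  Content transforms are
    forced to identity for every category except felt pen.
    """
    cat_cfg: CategoryTransformConfig = config.categories.get(
        category, CategoryTransformConfig()
    )

    scale = float(rng.uniform(*cat_cfg.scale)) if cat_cfg.scale else 1.0
    if cat_cfg.rotation:
        lo, hi = cat_cfg.rotation
        angle = int(rng.integers(lo, hi + 1))
    else:
        angle = 0
    mirror = str(rng.choice(MIRROR_AXES)) if cat_cfg.mirror else "none"

    hue_value: int | None = None
    scratch_count, scratch_factor = 0, 0.0
    perlin_weight, intensity = 0.0, 1.0
    scratch_seed = perlin_seed = 0
    if category == "felt_pen":
        if cat_cfg.hue is not None:
            hue_value = int(rng.integers(cat_cfg.hue[0], cat_cfg.hue[1] + 1))
        if cat_cfg.scratch_count is not None:
            lo, hi = cat_cfg.scratch_count
            scratch_count = int(rng.integers(lo, hi + 1))
            scratch_factor = float(rng.uniform(*cat_cfg.scratch_factor))
            scratch_seed = int(rng.integers(0, _MAX_SUBSEED))
        if cat_cfg.perlin_weight is not None:
            perlin_weight = float(rng.uniform(*cat_cfg.perlin_weight))
            perlin_seed = int(rng.integers(0, _MAX_SUBSEED))
        if cat_cfg.intensity_u is not None:
            u = float(rng.uniform(*cat_cfg.intensity_u))
            intensity = float(np.sqrt(u))

    return TransformParams(
        scale_factor=scale,
        rotation_angle=angle,
        mirror_axis=mirror,
        hue_value=hue_value,
        scratch_count=scratch_count,
        scratch_factor=scratch_factor,
        perlin_weight=perlin_weight,
        perlin_octaves=cat_cfg.perlin_octaves,
        perlin_threshold=cat_cfg.perlin_threshold,
        perlin_normalize=cat_cfg.perlin_normalize,
        intensity_factor=intensity,
        scratch_seed=scratch_seed,
        perlin_seed=perlin_seed,
    )


def apply_chain(overlay: ArtifactOverlay, params: TransformParams) -> ArtifactOverlay:
    """Apply a parameter set in fixed order: scale, rotate, mirror, hue,
    scratch, Perlin fade, intensity.

    The fixed order makes a chain reproducible from its parameters alone;
    the transformations themselves are mutually independent.
    """
    if overlay.category != "felt_pen" and not (
        params.hue_value is None
        and params.scratch_count == 0
        and params.perlin_weight == 0.0
        and params.intensity_factor == 1.0
    ):
        raise ParameterError(
            f"content-transform parameters are invalid for category "
            f"{overlay.category!r}"
        )
    out = overlay
    if params.scale_factor != 1.0:
        out = scale_overlay(out, params.scale_factor)
    if params.rotation_angle != 0:
        out = rotate_overlay(out, params.rotation_angle)
    if params.mirror_axis != "none":
        out = mirror_overlay(out, params.mirror_axis)
    if params.hue_value is not None:
        out = hue_set(out, params.hue_value)
    if params.scratch_count > 0:
        out = add_scratches(
            out,
            params.scratch_count,
            np.random.default_rng(params.scratch_seed),
            factors=params.scratch_factor,
        )
    if params.perlin_weight > 0.0:
        out = perlin_fade(
            out,
            params.perlin_weight,
            octaves=params.perlin_octaves,
            threshold=params.perlin_threshold,
            normalize=params.perlin_normalize,
            rng=np.random.default_rng(params.perlin_seed),
        )
    if params.intensity_factor != 1.0:
        out = intensity_scale(out, params.intensity_factor)
    if out is overlay:
        out = overlay.copy()
    return out
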