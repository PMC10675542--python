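"""Synthetic slide previews and artifact overlays.

Real scanner preview images (landscape glass slides: a bright near-white
field, darker stained tissue blobs, a label area at one end) and labeled
artifact sources are proprietary; this module generates structurally
similar stand-ins so every other module is testable with no external data.
The generators aim for the *structure* the method relies on — tissue darker
than background, artifacts with consistent masks in canonical
white-background form — not for photorealistic histology.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw
from skimage.color import hsv2rgb

from . import image_io
from .bank import CATEGORIES, ArtifactBank, ArtifactOverlay
from .exceptions import ParameterError
from .image_io import PreviewSample
from .noise import normalized_perlin

# stain-like interior colors (RGB base, jitter sigma)
_STAIN_COLORS = {
    "eosin": np.array([212, 132, 166], dtype=float),      # pink
    "hematoxylin": np.array([138, 102, 172], dtype=float),  # purple-blue
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic clean preview.

    Defaults mirror the working resolution of the augmentation pipeline:
    a 512 x 1024 landscape canvas (rows x columns) with a label area on the
    left and 1-4 irregular tissue blobs on the slide field.
    """

    height: int = 512
    width: int = 1024
    blob_count: tuple[int, int] = (1, 4)
    blob_radius: tuple[int, int] = (40, 110)
    background_brightness: tuple[int, int] = (228, 248)
    label_fraction: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ParameterError("canvas must be at least 32x32")
        lo, hi = self.background_brightness
        if not (0 <= lo <= hi <= 255):
            raise ParameterError("background brightness range outside [0, 255]")
        if not 0.0 <= self.label_fraction < 0.9:
            raise ParameterError("label_fraction must be in [0, 0.9)")
        usable_w = int(self.width * (1 - self.label_fraction))
        if 2 * self.blob_radius[1] >= min(self.height, usable_w):
            raise ParameterError(
                f"blob radius up to {self.blob_radius[1]} does not fit the "
                f"{self.height}x{usable_w} slide field"
            )


def _blob_support(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """An irregular blob: ellipse with a smooth random radial perturbation."""
    aspect = rng.uniform(0.6, 1.0)
    theta = np.linspace(0.0, 2.0 * np.pi, 180, endpoint=False)
    # low-order random-Fourier boundary wobble, smooth and closed
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        wobble += rng.uniform(0.0, 0.12) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = radius * (1.0 + wobble)
    rows = center[0] + r * aspect * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    support = np.zeros(shape, dtype=bool)
    support[rr, cc] = True
    return support


def generate_clean_preview(spec: FixtureSpec) -> PreviewSample:
    """A clean slide preview: textured bright field, label area, tissue blobs.

    The tissue mask is exactly the union of painted blob supports; the label
    area is excluded from the mask.  Tissue is darker than the background on
    average, as on real stained slides.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    base = float(rng.integers(*spec.background_brightness))
    texture = normalized_perlin((h, w), cells=6.0, rng=rng) * 10.0 - 5.0
    image = np.empty((h, w, 3), dtype=float)
    for c in range(3):
        image[:, :, c] = base + texture + rng.uniform(-3.0, 3.0)

    label_w = int(round(w * spec.label_fraction))
    if label_w > 0:
        label_shade = float(rng.integers(170, 210))
        image[:, :label_w, :] = label_shade
        image[:, label_w - 2 : label_w, :] = 120.0  # label edge

    stain = str(rng.choice(sorted(_STAIN_COLORS)))
    color = _STAIN_COLORS[stain]
    n_blobs = int(rng.integers(spec.blob_count[0], spec.blob_count[1] + 1))
    support = np.zeros((h, w), dtype=bool)
    r_max = spec.blob_radius[1]
    for _ in range(n_blobs):
        radius = float(rng.integers(spec.blob_radius[0], spec.blob_radius[1] + 1))
        cy = float(rng.uniform(r_max, h - r_max))
        cx = float(rng.uniform(label_w + r_max, w - r_max))
        support |= _blob_support((h, w), (cy, cx), radius, rng)

    if support.any():
        jitter = rng.normal(0.0, 9.0, size=(int(support.sum()), 3))
        image[support] = color[None, :] + jitter

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    mask = support.astype(np.uint8) * 255
    return PreviewSample(image=image, tissue_mask=mask,
                         identifier=f"synthetic_{spec.seed:06d}")


def generate_synthetic_artifact(
    category: str,
    dims: tuple[int, int] = (96, 96),
    seed: int = 0,
) -> ArtifactOverlay:
    """One synthetic artifact overlay of the given category.

    felt_pen: thick curved saturated strokes; bubble: a bright disk with a
    darker rim (mask = full disk); dirt: scattered small dark speckles;
    brand_mark: dark glyph-like rectangles.  Returned in canonical
    white-background form.
    """
    if category not in CATEGORIES:
        raise ParameterError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        )
    h, w = int(dims[0]), int(dims[1])
    if h < 8 or w < 8:
        raise ParameterError("artifact canvas must be at least 8x8")
    rng = np.random.default_rng(seed)
    patch = np.full((h, w, 3), 255, dtype=float)
    mask = np.zeros((h, w), dtype=bool)

    if category == "felt_pen":
        _paint_felt_pen(patch, mask, rng)
    elif category == "bubble":
        _paint_bubble(patch, mask, rng)
    elif category == "dirt":
        _paint_dirt(patch, mask, rng)
    else:
        _paint_brand_mark(patch, mask, rng)

    return ArtifactOverlay(
        patch=np.clip(np.rint(patch), 0, 255).astype(np.uint8),
        mask=mask.astype(np.uint8) * 255,
        category=category,
        source_id=f"synthetic_{category}_{seed:06d}",
    )


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: int) -> None:
    rr, cc = skdraw.disk((r, c), radius, shape=mask.shape)
    mask[rr, cc] = True


def _paint_felt_pen(patch: np.ndarray, mask: np.ndarray,
                    rng: np.random.Generator) -> None:
    h, w = mask.shape
    n_strokes = int(rng.integers(1, 3))
    hue = rng.uniform(0.0, 1.0)
    sat = rng.uniform(0.55, 0.9)
    val = rng.uniform(0.45, 0.8)
    color = hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0] * 255.0
    thickness = max(2, int(min(h, w) * 0.06))
    for _ in range(n_strokes):
        # quadratic Bezier between random border-margin points
        pts = rng.uniform([4, 4], [h - 5, w - 5], size=(3, 2))
        t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t**2 * pts[2])
        for r, c in curve:
            _stamp_disk(mask, r, c, thickness)
    jitter = rng.normal(0.0, 6.0, size=(int(mask.sum()), 3))
    patch[mask] = color[None, :] + jitter


def _paint_bubble(patch: np.ndarray, mask: np.ndarray,
                  rng: np.random.Generator) -> None:
    h, w = mask.shape
    radius = int(min(h, w) // 2 - 3)
    cy, cx = h / 2.0, w / 2.0
    rim = max(2, radius // 8)
    rr, cc = skdraw.disk((cy, cx), radius, shape=mask.shape)
    mask[rr, cc] = True
    interior = np.zeros_like(mask)
    rr, cc = skdraw.disk((cy, cx), radius - rim, shape=mask.shape)
    interior[rr, cc] = True
    rim_shade = float(rng.integers(95, 150))
    inner_shade = float(rng.integers(232, 250))
    patch[mask & ~interior] = rim_shade
    patch[interior] = inner_shade + rng.normal(0.0, 2.0, size=(int(interior.sum()), 3))


def _paint_dirt(patch: np.ndarray, mask: np.ndarray,
                rng: np.random.Generator) -> None:
    h, w = mask.shape
    n_speckles = int(rng.integers(10, 40))
    for _ in range(n_speckles):
        r = rng.uniform(2, h - 3)
        c = rng.uniform(2, w - 3)
        _stamp_disk(mask, r, c, int(rng.integers(1, 4)))
    shade = rng.uniform(40.0, 120.0)
    brownish = np.array([shade * 1.15, shade * 0.95, shade * 0.8])
    patch[mask] = brownish[None, :] + rng.normal(0.0, 10.0, size=(int(mask.sum()), 3))


def _paint_brand_mark(patch: np.ndarray, mask: np.ndarray,
                      rng: np.random.Generator) -> None:
    h, w = mask.shape
    n_bars = int(rng.integers(2, 6))
    shade = float(rng.integers(30, 80))
    for _ in range(n_bars):
        bh = int(rng.integers(max(2, h // 12), max(3, h // 4)))
        bw = int(rng.integers(max(2, w // 12), max(3, w // 3)))
        r0 = int(rng.integers(2, max(3, h - bh - 2)))
        c0 = int(rng.integers(2, max(3, w - bw - 2)))
        mask[r0 : r0 + bh, c0 : c0 + bw] = True
    patch[mask] = shade + rng.normal(0.0, 4.0, size=(int(mask.sum()), 3))


@dataclass
class BankSpec:
    """How many synthetic overlays to generate per category, and their size."""

    per_category: dict[str, int] = field(
        default_factory=lambda: {c: 3 for c in CATEGORIES}
    )
    dims: tuple[int, int] = (96, 96)


def generate_bank(bank_spec: BankSpec, seed: int = 0) -> ArtifactBank:
    """A synthetic artifact bank with deterministic per-overlay seeds."""
    bank = ArtifactBank()
    for category in CATEGORIES:
        for i in range(bank_spec.per_category.get(category, 0)):
            bank.add(
                generate_synthetic_artifact(
                    category, dims=bank_spec.dims, seed=seed * 1000 + i
                )
            )
    return bank


def generate_dataset(
    n: int,
    spec: FixtureSpec,
    bank_spec: BankSpec,
    out_dir: str | Path,
    seed: int = 0,
) -> tuple[list[Path], Path]:
    """Write ``n`` clean annotated previews plus a synthetic bank.

    Layout: ``<out_dir>/previews/<id>.tif`` (two-page annotation TIFFs),
    ``<out_dir>/bank/``, and ``<out_dir>/manifest.json`` recording the
    per-sample seeds.  Returns the preview paths and the bank directory.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    previews_dir = out_dir / "previews"
    previews_dir.mkdir(parents=True, exist_ok=True)

    from .bank import save_bank  # local import to avoid cycle at module load

    entries = []
    paths = []
    for i in range(n):
        sample_seed = seed * 10_000 + i
        sample_spec = FixtureSpec(
            height=spec.height,
            width=spec.width,
            blob_count=spec.blob_count,
            blob_radius=spec.blob_radius,
            background_brightness=spec.background_brightness,
            label_fraction=spec.label_fraction,
            seed=sample_seed,
        )
        sample = generate_clean_preview(sample_spec)
        path = previews_dir / f"{sample.identifier}.tif"
        image_io.write_multilayer_tif(sample, path)
        paths.append(path)
        entries.append({"id": sample.identifier, "seed": sample_seed,
                        "file": f"previews/{path.name}"})

    bank_dir = out_dir / "bank"
    save_bank(generate_bank(bank_spec, seed=seed), bank_dir)
    (out_dir / "manifest.json").write_text(
        json.dumps({"seed": seed, "samples": entries}, indent=2, sort_keys=True) + "\n"
    )
    return paths, bank_dir
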