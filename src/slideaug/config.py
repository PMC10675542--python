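"""Augmentation configuration: per-category transform ranges and run options.

Defaults reproduce the method's published sampling ranges, so a bare
``AugmentationConfig()`` runs the canonical augmentation: scale factor
uniform in [0.75, 1.25], integer rotation in [0, 359], mirroring over
{horizontal, vertical, both, none}; felt-pen content transforms draw a hue
in [0, 180] (half-degree HSV units), 1-10 scratch lines with attenuation
factor in [0, 0.2], a Perlin fade weight in [0, 1], and an intensity factor
sqrt(u) with u uniform in [0.3, 0.7].

Content transforms (hue, scratch, Perlin fade, intensity scaling) apply to
felt-pen overlays only; other categories are transformed geometrically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .bank import CATEGORIES
from .exceptions import ConfigurationError

#: Felt-pen hue range, OpenCV-style half-degree HSV units.
HUE_RANGE = (0, 180)
SCALE_RANGE = (0.75, 1.25)
ROTATION_RANGE = (0, 359)
SCRATCH_COUNT_RANGE = (1, 10)
SCRATCH_FACTOR_RANGE = (0.0, 0.2)
PERLIN_WEIGHT_RANGE = (0.0, 1.0)
INTENSITY_U_RANGE = (0.3, 0.7)

MIRROR_AXES = ("horizontal", "vertical", "both", "none")


@dataclass
class CategoryTransformConfig:
    """Enable flags and sampling ranges for one artifact category.

    A range set to ``None`` disables that transform (identity parameters are
    drawn).  Content-transform ranges are ignored for non-felt-pen
    categories regardless of their value here.
    """

    scale: tuple[float, float] | None = SCALE_RANGE
    rotation: tuple[int, int] | None = ROTATION_RANGE
    mirror: bool = True
    hue: tuple[int, int] | None = None
    scratch_count: tuple[int, int] | None = None
    scratch_factor: tuple[float, float] = SCRATCH_FACTOR_RANGE
    perlin_weight: tuple[float, float] | None = None
    perlin_octaves: float = 4.0
    perlin_threshold: float | None = None
    perlin_normalize: bool = True
    intensity_u: tuple[float, float] | None = None

    def validate(self) -> None:
        def _check(name: str, rng, lo, hi) -> None:
            if rng is None:
                return
            a, b = rng
            if not (lo <= a <= b <= hi):
                raise ConfigurationError(
                    f"{name} range {rng} outside legal domain [{lo}, {hi}]"
                )

        _check("scale", self.scale, 1e-6, 100.0)
        _check("rotation", self.rotation, 0, 359)
        _check("hue", self.hue, 0, 180)
        _check("scratch_count", self.scratch_count, 0, 10_000)
        _check("scratch_factor", self.scratch_factor, 0.0, 0.2)
        _check("perlin_weight", self.perlin_weight, 0.0, 1.0)
        _check("intensity_u", self.intensity_u, 0.0, 1.0)


def _default_categories() -> dict[str, CategoryTransformConfig]:
    cats = {c: CategoryTransformConfig() for c in CATEGORIES}
    cats["felt_pen"] = CategoryTransformConfig(
        hue=HUE_RANGE,
        scratch_count=SCRATCH_COUNT_RANGE,
        scratch_factor=SCRATCH_FACTOR_RANGE,
        perlin_weight=PERLIN_WEIGHT_RANGE,
        intensity_u=INTENSITY_U_RANGE,
    )
    return cats


@dataclass
class AugmentationConfig:
    """Full configuration of an augmentation run."""

    categories: dict[str, CategoryTransformConfig] = field(
        default_factory=_default_categories
    )
    #: inclusive bounds of the per-sample overlay count (uniform draw)
    overlay_count: tuple[int, int] = (1, 3)
    #: relative sampling weight per category; 0 removes a category
    category_weights: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CATEGORIES}
    )
    #: sample-type name -> categories never placed on that sample type
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    #: sample id -> sample-type name (used with ``exclusions``)
    sample_types: dict[str, str] = field(default_factory=dict)
    #: augmented copies written per input sample
    copies_per_sample: int = 1
    seed: int = 0
    #: (height, width) target for dataset preparation
    output_dims: tuple[int, int] = (512, 1024)

    def validate(self) -> None:
        for name, cat in self.categories.items():
            if name not in CATEGORIES:
                raise ConfigurationError(f"unknown category {name!r}")
            cat.validate()
        lo, hi = self.overlay_count
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid overlay_count bounds {self.overlay_count}")
        for name, wgt in self.category_weights.items():
            if name not in CATEGORIES:
                raise ConfigurationError(f"unknown category {name!r} in weights")
            if wgt < 0:
                raise ConfigurationError(f"negative weight for {name}")
        for sample_type, excluded in self.exclusions.items():
            for cat in excluded:
                if cat not in CATEGORIES:
                    raise ConfigurationError(
                        f"exclusion for {sample_type!r} names unknown category {cat!r}"
                    )

    def allowed_categories(self, sample_type: str | None = None) -> list[str]:
        """Categories with positive weight, minus the sample type's exclusions."""
        excluded = set(self.exclusions.get(sample_type, [])) if sample_type else set()
        return [
            c
            for c in CATEGORIES
            if self.category_weights.get(c, 0.0) > 0 and c not in excluded
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["categories"] = {k: asdict(v) for k, v in self.categories.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "AugmentationConfig":
        data = dict(data)
        cats = {}
        for name, sub in (data.pop("categories", None) or {}).items():
            sub = dict(sub)
            for key in ("scale", "rotation", "hue", "scratch_count",
                        "scratch_factor", "perlin_weight", "intensity_u"):
                if key in sub and sub[key] is not None:
                    sub[key] = tuple(sub[key])
            cats[name] = CategoryTransformConfig(**sub)
        cfg = cls(**{**data, "categories": cats or _default_categories()})
        if "overlay_count" in data:
            cfg.overlay_count = tuple(data["overlay_count"])
        if "output_dims" in data:
            cfg.output_dims = tuple(data["output_dims"])
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AugmentationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
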