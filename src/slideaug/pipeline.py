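"""Batch orchestration: dataset preparation and end-to-end augmentation runs.

Seeding is hierarchical: a master seed plus the sample identifier (and copy
index) are hashed into an independent per-sample stream, so results do not
depend on processing order and serial/parallel runs agree bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from . import image_io
from .bank import load_bank
from .compose import augment_sample
from .config import AugmentationConfig
from .exceptions import ConfigurationError
from .image_io import PreviewSample, binarize

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, *parts: object) -> int:
    """A stable 31-bit sub-seed from a master seed and arbitrary labels."""
    digest = hashlib.sha256(
        ":".join([str(master_seed), *map(str, parts)]).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class DatasetSplit:
    """A train/validation partition of sample identifiers."""

    train: list[str]
    validation: list[str]
    ratio: float = 0.8
    test: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"train": self.train, "validation": self.validation,
                "ratio": self.ratio, "test": self.test}


def split_ids(ids: list[str], ratio: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Shuffle and split ids; train size = floor(n * ratio), rest validation."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train = int(np.floor(len(ids) * ratio))
    return DatasetSplit(train=shuffled[:n_train], validation=shuffled[n_train:],
                        ratio=ratio)


def resize_sample(sample: PreviewSample, dims: tuple[int, int]) -> PreviewSample:
    """Resize to (height, width): bilinear image, nearest-then-binarized mask."""
    h, w = dims
    image = sktransform.resize(
        sample.image.astype(float), (h, w), order=1,
        preserve_range=True, anti_aliasing=True,
    )
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    mask = None
    if sample.tissue_mask is not None:
        mask = binarize(
            sktransform.resize(
                sample.tissue_mask, (h, w), order=0,
                preserve_range=True, anti_aliasing=False,
            ).astype(np.uint8)
        )
    return PreviewSample(image=image, tissue_mask=mask, identifier=sample.identifier)


def _list_annotation_tifs(input_dir: Path) -> list[Path]:
    paths = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in (".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no annotation TIFFs found in {input_dir}")
    return paths


def prepare_dataset(
    input_dir: str | Path,
    output_dir: str | Path,
    dims: tuple[int, int] = (512, 1024),
    ratio: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Resize every annotated preview to fixed dims and split 80:20.

    Reads all two-page TIFFs in ``input_dir``, writes the resized samples to
    ``output_dir`` along with ``split.json``, and returns the split.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    for path in _list_annotation_tifs(input_dir):
        sample = resize_sample(image_io.read_multilayer_tif(path), dims)
        image_io.write_multilayer_tif(sample, output_dir / f"{sample.identifier}.tif")
        ids.append(sample.identifier)
    split = split_ids(ids, ratio=ratio, seed=seed)
    (output_dir / "split.json").write_text(
        json.dumps(split.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    logger.info("prepared %d samples: %d train / %d validation",
                len(ids), len(split.train), len(split.validation))
    return split


def _config_hash(config: AugmentationConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_augmentation(
    input_dir: str | Path,
    bank_dir: str | Path,
    config: AugmentationConfig,
    output_dir: str | Path,
) -> dict:
    """Augment every annotated preview in ``input_dir``.

    For each input sample the original is co-emitted together with
    ``config.copies_per_sample`` augmented copies — each an annotation TIFF
    with the *unchanged* tissue mask, plus the union artifact footprint
    (PNG) and a JSON-lines provenance file.  Consistency between the config
    and the bank is checked before anything is written.  Returns the run
    log (also written as ``run.json``).
    """
    input_dir, bank_dir = Path(input_dir), Path(bank_dir)
    output_dir = Path(output_dir)
    config.validate()
    bank = load_bank(bank_dir)

    present = bank.categories_present
    requested = {
        c for c in config.category_weights
        if config.category_weights[c] > 0
    }
    missing = requested - present
    if missing and not (requested & present):
        raise ConfigurationError(
            f"config requests categories {sorted(requested)} but the bank "
            f"only contains {sorted(present)}"
        )
    if missing:
        logger.warning("bank lacks requested categories %s; skipping them",
                       sorted(missing))

    paths = _list_annotation_tifs(input_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    n_written = 0
    for path in paths:
        sample = image_io.read_multilayer_tif(path)
        image_io.write_multilayer_tif(sample, output_dir / f"{sample.identifier}.tif")
        n_written += 1
        sample_type = config.sample_types.get(sample.identifier)
        for copy_idx in range(config.copies_per_sample):
            sub_seed = derive_seed(config.seed, sample.identifier, copy_idx)
            rng = np.random.default_rng(sub_seed)
            augmented, records, footprints = augment_sample(
                sample, bank, config, rng,
                sample_type=sample_type, seed=sub_seed,
            )
            stem = f"{sample.identifier}_aug{copy_idx}"
            augmented.identifier = stem
            image_io.write_multilayer_tif(augmented, output_dir / f"{stem}.tif")
            union = np.zeros((sample.height, sample.width), dtype=np.uint8)
            for fp in footprints:
                union = np.maximum(union, fp)
            image_io.write_mask(union, output_dir / f"{stem}.footprint.png")
            with open(output_dir / f"{stem}.records.jsonl", "w") as fh:
                for record in records:
                    fh.write(json.dumps(record.to_dict(), sort_keys=True) + "\n")
            n_written += 1

    run_log = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "inputs": len(paths),
        "copies_per_sample": config.copies_per_sample,
        "samples_written": n_written,
        "bank_categories": sorted(present),
    }
    (output_dir / "run.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    return run_log
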