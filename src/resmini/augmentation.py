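"""Dataset-doubling augmentation: random offset plus horizontal flip.

Each original slice yields exactly one augmented variant (so 155 originals
become 310 records): the image is translated by a random integer offset of
at most ``max_offset_fraction`` of each dimension, then flipped about the
vertical midline.  Vacated pixels take the background fill value — brain
slices sit on a dark background, so the default fill is 0.  Labels are
copied; augmented records point back to their source via ``source_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .slice_io import ImageRecord, Manifest, Provenance, load_slice_png, save_slice_png


@dataclass(frozen=True)
class AugmentPolicy:
    max_offset_fraction: float = 0.1
    flip: bool = True
    copies_per_image: int = 1
    fill_value: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.max_offset_fraction < 0.5:
            raise ValueError("max_offset_fraction must be in [0, 0.5)")
        if self.copies_per_image < 1:
            raise ValueError("copies_per_image must be >= 1")


def offset_image(image: np.ndarray, dx: int, dy: int,
                 fill_value: float = 0.0) -> np.ndarray:
    """Translate by ``dx`` columns and ``dy`` rows, filling vacated pixels.

    Positive ``dx`` moves content right, positive ``dy`` moves it down.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"offset ({dx}, {dy}) out of bounds for {h}x{w} image")
    out = np.full_like(img, fill_value)
    src_r = slice(max(0, -dy), h - max(0, dy))
    src_c = slice(max(0, -dx), w - max(0, dx))
    dst_r = slice(max(0, dy), h - max(0, -dy))
    dst_c = slice(max(0, dx), w - max(0, -dx))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def horizontal_flip(image: np.ndarray) -> np.ndarray:
    """Mirror about the vertical midline (columns reversed)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    return img[:, ::-1].copy()


def augment_image(image: np.ndarray, dx: int, dy: int,
                  policy: AugmentPolicy) -> np.ndarray:
    """One augmented variant: offset, then (optionally) flip."""
    out = offset_image(image, dx, dy, policy.fill_value)
    if policy.flip:
        out = horizontal_flip(out)
    return out


def draw_offsets(policy: AugmentPolicy, height: int, width: int,
                 rng: np.random.Generator) -> tuple[int, int]:
    """Integer offsets uniform on [-m*dim, +m*dim] for each dimension."""
    mx = int(policy.max_offset_fraction * width)
    my = int(policy.max_offset_fraction * height)
    return int(rng.integers(-mx, mx + 1)), int(rng.integers(-my, my + 1))


def augment_dataset(records: list[ImageRecord], policy: AugmentPolicy,
                    images: Mapping[str, np.ndarray] | None = None,
                    ) -> tuple[list[ImageRecord], dict[str, np.ndarray]]:
    """Originals plus ``copies_per_image`` augmented variants per original.

    Returns the combined record list and, when pixel arrays were supplied
    (mapping ``image_id -> 2D array``), the augmented arrays keyed by their
    new ids.  Deterministic given ``policy.seed``.
    """
    for r in records:
        if r.provenance is not Provenance.ORIGINAL:
            raise ValueError(
                f"record {r.image_id!r} is not original; augmenting an "
                "augmented image would compound transforms")
    rng = np.random.default_rng(policy.seed)
    out_records = list(records)
    out_images: dict[str, np.ndarray] = {}
    for r in records:
        for copy in range(policy.copies_per_image):
            suffix = "aug" if policy.copies_per_image == 1 else f"aug{copy}"
            new_id = f"{r.image_id}_{suffix}"
            if images is not None:
                img = images[r.image_id]
                dx, dy = draw_offsets(policy, img.shape[0], img.shape[1], rng)
                out_images[new_id] = augment_image(img, dx, dy, policy)
            new_path = str(Path(r.path).with_name(f"{new_id}.png")) if r.path else ""
            out_records.append(replace(
                r, image_id=new_id, path=new_path,
                provenance=Provenance.AUGMENTED, source_id=r.image_id))
    return out_records, out_images


def augment_manifest_files(manifest: Manifest, policy: AugmentPolicy,
                           image_root: str | Path = ".",
                           out_dir: str | Path | None = None) -> Manifest:
    """File-level augmentation: read each original PNG, write its variant.

    Augmented PNGs land next to their sources unless ``out_dir`` is given.
    """
    root = Path(image_root)
    images = {}
    for r in manifest.records:
        p = Path(r.path)
        images[r.image_id] = load_slice_png(p if p.is_absolute() else root / p)
    records, aug_images = augment_dataset(manifest.records, policy, images)
    final_records = []
    for r in records:
        if r.provenance is Provenance.AUGMENTED:
            if out_dir is not None:
                r = replace(r, path=str(Path(out_dir) / Path(r.path).name))
            p = Path(r.path)
            dest = p if p.is_absolute() else root / p
            dest.parent.mkdir(parents=True, exist_ok=True)
            save_slice_png(aug_images[r.image_id], dest)
        final_records.append(r)
    return Manifest(class_names=manifest.class_names, records=final_records,
                    image_height=manifest.image_height,
                    image_width=manifest.image_width)
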