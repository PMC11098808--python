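"""Slice extraction, intensity normalization, PNG export and manifests.

The classification pipeline works on the 2D axial *middle* slice of each
brain volume: the plane at index ``floor(D/2)`` (0-based) along the axial
axis.  Functional (4D) series are reduced to their first time frame before
slicing.  Slices are min-max normalized to [0, 1] and stored as 8-bit
grayscale PNG; labels live only in a manifest CSV, never in file paths.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

MANIFEST_COLUMNS = ("image_id", "path", "class_name", "provenance",
                    "source_id", "split")


class Provenance(str, Enum):
    ORIGINAL = "original"
    AUGMENTED = "augmented"


class Split(str, Enum):
    UNASSIGNED = "unassigned"
    TRAIN = "train"
    VAL = "val"
    TEST = "test"


@dataclass(frozen=True)
class ImageRecord:
    """One labeled slice image with provenance and split assignment."""

    image_id: str
    path: str
    label: int
    class_name: str
    provenance: Provenance = Provenance.ORIGINAL
    source_id: str = ""
    split: Split = Split.UNASSIGNED

    def __post_init__(self):
        if not self.source_id:
            object.__setattr__(self, "source_id", self.image_id)


@dataclass
class Manifest:
    """An ordered class vocabulary plus the records of one dataset."""

    class_names: list[str]
    records: list[ImageRecord] = field(default_factory=list)
    image_height: int = 95
    image_width: int = 79

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image_id in manifest")
        for r in self.records:
            if r.class_name not in self.class_names:
                raise ValueError(f"unknown class_name {r.class_name!r}")
            if not (0 <= r.label < len(self.class_names)):
                raise ValueError(f"label {r.label} out of range")
            if self.class_names[r.label] != r.class_name:
                raise ValueError(
                    f"label {r.label} inconsistent with class {r.class_name!r}")

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for r in self.records:
            counts[r.class_name] += 1
        return counts


def extract_middle_axial_slice(volume: np.ndarray, axial_axis: int = 2) -> np.ndarray:
    """The 2D plane at index ``floor(D/2)`` along ``axial_axis``.

    4D input (an fMRI series, time last) is reduced to its first frame
    before slicing.  Output axes are the two non-axial spatial axes, in
    their original order.
    """
    vol = np.asarray(volume)
    if vol.ndim == 4:
        vol = vol[..., 0]
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D or 4D volume, got {volume.ndim} axes")
    if not -3 <= axial_axis < 3:
        raise ValueError(f"axial_axis {axial_axis} invalid for a 3D volume")
    depth = vol.shape[axial_axis]
    if depth == 0:
        raise ValueError("degenerate axial axis of length 0")
    return np.take(vol, depth // 2, axis=axial_axis)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Per-image min-max rescale to [0, 1]; a constant image maps to zeros."""
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN or Inf pixels")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def save_slice_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def load_slice_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to a float image in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def load_nifti_volume(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)


def save_nifti_volume(volume: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4)),
             str(path))


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Serialize to CSV; class order and image size ride in a comment header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# class_names: {','.join(manifest.class_names)}; "
                 f"image_size: {manifest.image_height}x{manifest.image_width}\n")
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in manifest.records:
            writer.writerow([r.image_id, r.path, r.class_name,
                             r.provenance.value, r.source_id, r.split.value])


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing manifest header line")
        meta = header.lstrip("# ").strip()
        class_part, size_part = (p.strip() for p in meta.split(";"))
        class_names = class_part.split(":", 1)[1].strip().split(",")
        h, w = (int(v) for v in size_part.split(":", 1)[1].strip().split("x"))
        reader = csv.DictReader(fh)
        records = []
        for row in reader:
            cls = row["class_name"]
            if cls not in class_names:
                raise ValueError(f"unknown class_name {cls!r} in {path}")
            records.append(ImageRecord(
                image_id=row["image_id"], path=row["path"],
                label=class_names.index(cls), class_name=cls,
                provenance=Provenance(row["provenance"]),
                source_id=row["source_id"], split=Split(row["split"])))
    return Manifest(class_names=class_names, records=records,
                    image_height=h, image_width=w)


def load_arrays(manifest: Manifest, image_root: str | Path = ".",
                split: Split | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stack manifest images into a (N, 1, H, W) float array plus labels.

    ``split=None`` loads every record; otherwise only records assigned to
    that split.  Paths are resolved relative to ``image_root`` unless
    absolute.
    """
    root = Path(image_root)
    recs = [r for r in manifest.records if split is None or r.split is split]
    if not recs:
        raise ValueError(f"no records for split {split}")
    images = []
    for r in recs:
        p = Path(r.path)
        img = load_slice_png(p if p.is_absolute() else root / p)
        images.append(img[None, :, :])
    return np.stack(images).astype(np.float32), np.array(
        [r.label for r in recs], dtype=np.int64)


def prepare_slices(volume_paths: Sequence[str | Path], class_names: list[str],
                   labels: Sequence[int], out_dir: str | Path,
                   axial_axis: int = 2) -> Manifest:
    """Slice each volume, normalize, export PNGs and build a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    height = width = None
    for path, label in zip(volume_paths, labels):
        vol = load_nifti_volume(path)
        sl = normalize_intensity(extract_middle_axial_slice(vol, axial_axis))
        image_id = Path(path).name.split(".")[0]
        png = out / f"{image_id}.png"
        save_slice_png(sl, png)
        height, width = sl.shape
        records.append(ImageRecord(image_id=image_id, path=str(png),
                                   label=int(label),
                                   class_name=class_names[int(label)]))
    return Manifest(class_names=class_names, records=records,
                    image_height=height or 0, image_width=width or 0)
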