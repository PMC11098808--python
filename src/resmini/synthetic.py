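"""Class-separable brain-slice phantoms for exercising the whole pipeline.

A phantom is an elliptical "brain" on a dark background with a brighter
cortical ring and a dark central ventricle, plus additive Gaussian noise.
Class identity is carried by morphology — brain size, ring thickness,
ventricle radius, tissue intensity — echoing, qualitatively, the atrophy
and ventricle enlargement that distinguish age and dementia classes in
real MRI.  A global ``separation`` factor scales every class's morphology
toward (0) or away from (>1) the across-class mean, so separability can be
dialed from "identical classes" to "trivially separable" without touching
the individual morphologies.

The defaults mirror the study conditions: 95x79 single-channel images and
per-class original counts 65 / 57 / 33 (ages 3-5, ages 7-12, adults),
totalling 155.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .slice_io import (ImageRecord, Manifest, normalize_intensity,
                       save_slice_png)

_NUMERIC_FIELDS = ("brain_axis_y", "brain_axis_x", "cortical_ring_thickness",
                   "ventricle_radius", "mean_intensity")


@dataclass(frozen=True)
class ClassMorphology:
    """Geometry of one phantom class.

    ``brain_axis_y``/``brain_axis_x`` are ellipse semi-axes as fractions of
    the image dimensions; ring thickness and ventricle radius are in pixels;
    ``mean_intensity`` is the brain-tissue level in [0, 1].
    """

    name: str
    brain_axis_y: float = 0.42
    brain_axis_x: float = 0.40
    cortical_ring_thickness: float = 4.0
    ventricle_radius: float = 6.0
    mean_intensity: float = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    image_height: int = 95
    image_width: int = 79
    classes: tuple[ClassMorphology, ...] = ()
    samples_per_class: tuple[int, ...] = ()
    noise_sd: float = 0.05
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.classes and not self.samples_per_class:
            object.__setattr__(self, "samples_per_class",
                               (1,) * len(self.classes))
        if len(self.classes) != len(self.samples_per_class):
            raise ValueError("classes and samples_per_class length mismatch")
        if any(n < 1 for n in self.samples_per_class):
            raise ValueError("samples_per_class must be >= 1")
        if self.noise_sd < 0 or self.separation < 0:
            raise ValueError("noise_sd and separation must be >= 0")


def default_phantom_spec(samples_per_class: Sequence[int] = (65, 57, 33),
                         noise_sd: float = 0.05, separation: float = 1.0,
                         seed: int = 0) -> PhantomSpec:
    """Three age-class phantoms at the study's image size and composition.

    Children get a proportionally larger brain with thicker cortex and a
    small ventricle; adults the reverse — a caricature of neurodevelopment
    sufficient for a classifier to separate.
    """
    classes = (
        ClassMorphology("ages_3_5", 0.46, 0.44, 6.0, 3.0, 0.52),
        ClassMorphology("ages_7_12", 0.43, 0.41, 4.5, 6.0, 0.60),
        ClassMorphology("adults", 0.40, 0.38, 3.0, 9.0, 0.68),
    )
    return PhantomSpec(classes=classes,
                       samples_per_class=tuple(samples_per_class),
                       noise_sd=noise_sd, separation=separation, seed=seed)


def _effective_morphology(morph: ClassMorphology,
                          spec: PhantomSpec) -> ClassMorphology:
    """Interpolate class geometry toward/away from the across-class mean."""
    if not spec.classes:
        return morph
    values = {}
    for fname in _NUMERIC_FIELDS:
        ref = float(np.mean([getattr(c, fname) for c in spec.classes]))
        values[fname] = ref + spec.separation * (getattr(morph, fname) - ref)
    return ClassMorphology(name=morph.name, **values)


def phantom_image(morph: ClassMorphology, spec: PhantomSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Render one noisy phantom slice in [0, 1] for a class morphology."""
    eff = _effective_morphology(morph, spec)
    h, w = spec.image_height, spec.image_width
    ay = max(eff.brain_axis_y * h, 1.0)
    ax = max(eff.brain_axis_x * w, 1.0)
    if eff.ventricle_radius >= min(ay, ax):
        raise ValueError("ventricle does not fit inside the brain ellipse")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    img = np.zeros((h, w), dtype=np.float64)
    img[rho <= 1.0] = eff.mean_intensity
    ring_rho = eff.cortical_ring_thickness / ((ay + ax) / 2.0)
    ring = (rho <= 1.0) & (rho >= 1.0 - ring_rho)
    img[ring] = min(1.0, eff.mean_intensity + 0.3)
    r_px = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    img[r_px <= eff.ventricle_radius] = 0.25 * eff.mean_intensity
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def phantom_volume(morph: ClassMorphology, depth: int, spec: PhantomSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """A (H, W, depth) stack whose middle plane carries the full morphology.

    Outer planes are the same design attenuated linearly with distance from
    the middle, so the middle axial slice is the brightest and, at zero
    noise, exactly equals the designed phantom.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    design_spec = PhantomSpec(
        image_height=spec.image_height, image_width=spec.image_width,
        classes=spec.classes, samples_per_class=spec.samples_per_class,
        noise_sd=0.0, separation=spec.separation, seed=spec.seed)
    design = phantom_image(morph, design_spec, rng)
    mid = depth // 2
    vol = np.empty((spec.image_height, spec.image_width, depth))
    half = max(mid, depth - 1 - mid, 1)
    for k in range(depth):
        atten = 1.0 - 0.6 * abs(k - mid) / half
        plane = design * atten
        if spec.noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
        vol[:, :, k] = np.clip(plane, 0.0, 1.0)
    return vol


def generate_phantom_dataset(spec: PhantomSpec, out_dir: str | Path,
                             ) -> Manifest:
    """Write per-class phantom PNGs plus a manifest; deterministic by seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records = []
    for label, (morph, n) in enumerate(zip(spec.classes,
                                           spec.samples_per_class)):
        for i in range(n):
            img = phantom_image(morph, spec, rng)
            image_id = f"{morph.name}_{i:03d}"
            path = out / f"{image_id}.png"
            save_slice_png(img, path)
            records.append(ImageRecord(image_id=image_id, path=str(path),
                                       label=label, class_name=morph.name))
    return Manifest(class_names=[c.name for c in spec.classes],
                    records=records, image_height=spec.image_height,
                    image_width=spec.image_width)


def phantom_arrays(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """In-memory phantom dataset: (N, 1, H, W) images and label vector."""
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for label, (morph, n) in enumerate(zip(spec.classes,
                                           spec.samples_per_class)):
        for _ in range(n):
            images.append(phantom_image(morph, spec, rng)[None, :, :])
            labels.append(label)
    return (np.stack(images).astype(np.float32),
            np.array(labels, dtype=np.int64))
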