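"""Image plumbing: augmentation, synthetic blood smears, noise, VOC I/O.

The augmentation operators (rotation, shear, reflection, translation,
rescaling) enlarge a labeled image set while preserving labels and class
proportions — the standard recipe for small annotated medical image
collections.

The synthetic smear generator emulates the morphological cue that
separates the two classes in peripheral-blood microscopy: leukemic
blasts show a *large, irregular* dark nucleus with scanty cytoplasm,
whereas normal lymphocytes show a *smaller, rounder* nucleus.  Images
are grayscale, with light circular distractors standing in for red
blood cells and additive Gaussian pixel noise.  Class separability is
built in by construction (the blast nucleus-radius interval sits
strictly above the lymphocyte interval), so classifiers trained on
these images are attacking a learnable problem.

Ground truth for real smear collections is read from Pascal-VOC XML
(1-based, inclusive pixel boxes).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "LabeledImage",
    "AugmentationConfig",
    "SyntheticSmearConfig",
    "VocObject",
    "rotate",
    "shear",
    "reflect",
    "translate",
    "rescale",
    "augment_dataset",
    "salt_pepper",
    "generate_synthetic_dataset",
    "resize_to",
    "dataset_arrays",
    "read_voc_annotations",
    "write_voc_annotations",
    "load_image_directory",
    "save_image_directory",
]

CLASS_NAMES = ("normal", "leukemic")


@dataclass(frozen=True)
class LabeledImage:
    """A [0,1]-valued image with its class label and provenance."""

    pixels: np.ndarray
    label: str
    provenance: str = "original"  # original | augmented | synthetic

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class AugmentationConfig:
    """Operator parameter ranges for random augmentation.

    Rotation and shear ranges follow the usual smear-augmentation
    recipe (±50°, shear factor ±0.1); translation (±10% of the image
    per axis) and scale ([0.9, 1.1]) are mild defaults.
    """

    rotation_deg: tuple = (-50.0, 50.0)
    shear: tuple = (-0.1, 0.1)
    reflect_x: float = 0.5
    reflect_y: float = 0.5
    translate_frac: tuple = (-0.1, 0.1)
    scale: tuple = (0.9, 1.1)
    target_count: int = 500


@dataclass(frozen=True)
class SyntheticSmearConfig:
    """Generative knobs of the two-class synthetic smear.

    Radii are fractions of the image side; the blast interval must sit
    strictly above the lymphocyte interval so the classes are separable
    by nucleus area.
    """

    image_size: int = 32
    blast_nucleus_radius: tuple = (0.28, 0.40)
    lymph_nucleus_radius: tuple = (0.12, 0.18)
    irregularity: float = 0.35
    n_red_cells: tuple = (3, 7)
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not self.lymph_nucleus_radius[1] < self.blast_nucleus_radius[0]:
            raise ValueError(
                "blast nucleus radius interval must sit strictly above the "
                "lymphocyte interval (class separability by construction)"
            )


# ---------------------------------------------------------------------------
# geometric augmentation operators
# ---------------------------------------------------------------------------

def _border_fill(px: np.ndarray) -> float:
    border = np.concatenate([px[0].ravel(), px[-1].ravel(),
                             px[:, 0].ravel(), px[:, -1].ravel()])
    return float(np.median(border))


def _warp_about_center(img: LabeledImage, matrix: np.ndarray) -> LabeledImage:
    px = img.pixels
    h, w = px.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shift = sktransform.AffineTransform(translation=-center)
    unshift = sktransform.AffineTransform(translation=center)
    tf = shift + sktransform.AffineTransform(matrix=matrix) + unshift
    out = sktransform.warp(px, tf.inverse, order=1, mode="constant",
                           cval=_border_fill(px), preserve_range=True)
    return replace(img, pixels=np.clip(out, 0.0, 1.0), provenance="augmented")


def rotate(img: LabeledImage, angle_deg: float) -> LabeledImage:
    """Rotate about the image center; out-of-frame pixels get the border fill."""
    a = np.deg2rad(angle_deg)
    m = np.array([[np.cos(a), -np.sin(a), 0.0],
                  [np.sin(a), np.cos(a), 0.0],
                  [0.0, 0.0, 1.0]])
    return _warp_about_center(img, m)


def shear(img: LabeledImage, sx: float, sy: float) -> LabeledImage:
    """Shear by factors ``sx`` (along x) and ``sy`` (along y) about the center."""
    m = np.array([[1.0, sx, 0.0],
                  [sy, 1.0, 0.0],
                  [0.0, 0.0, 1.0]])
    return _warp_about_center(img, m)


def reflect(img: LabeledImage, axis: str) -> LabeledImage:
    """Mirror along ``"x"`` (left-right) or ``"y"`` (up-down); exact involution."""
    if axis == "x":
        out = img.pixels[:, ::-1].copy()
    elif axis == "y":
        out = img.pixels[::-1].copy()
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return replace(img, pixels=out, provenance="augmented")


def translate(img: LabeledImage, dx: float, dy: float) -> LabeledImage:
    """Shift by (dx, dy) pixels; vacated pixels get the border fill."""
    m = np.array([[1.0, 0.0, dx],
                  [0.0, 1.0, dy],
                  [0.0, 0.0, 1.0]])
    return _warp_about_center(img, m)


def rescale(img: LabeledImage, factor: float) -> LabeledImage:
    """Zoom about the center by ``factor``, keeping the output shape."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    m = np.array([[factor, 0.0, 0.0],
                  [0.0, factor, 0.0],
                  [0.0, 0.0, 1.0]])
    return _warp_about_center(img, m)


def augment_dataset(images: list, config: AugmentationConfig,
                    rng: np.random.Generator) -> list:
    """Grow a labeled set to ``config.target_count`` by random compositions.

    Originals are retained unchanged; each added image applies rotation,
    shear, optional reflections, translation and rescaling (parameters
    drawn from the config intervals) to a random source image of the
    class being topped up.  Per-class counts of the output stay within
    ±1 image of the source proportions.
    """
    if not images:
        raise ValueError("input image list must be non-empty")
    n_in, target = len(images), config.target_count
    if target < n_in:
        raise ValueError(f"target_count {target} below input size {n_in}")

    labels = sorted({im.label for im in images})
    by_label = {lab: [im for im in images if im.label == lab] for lab in labels}
    # allocate added images to preserve class proportions (largest remainder)
    n_add = target - n_in
    quota = {lab: n_add * len(by_label[lab]) / n_in for lab in labels}
    counts = {lab: int(np.floor(quota[lab])) for lab in labels}
    rest = sorted(labels, key=lambda lab: quota[lab] - counts[lab], reverse=True)
    for lab in rest[: n_add - sum(counts.values())]:
        counts[lab] += 1

    out = list(images)
    for lab in labels:
        pool = by_label[lab]
        for _ in range(counts[lab]):
            src = pool[rng.integers(len(pool))]
            h, w = src.pixels.shape[:2]
            im = rotate(src, rng.uniform(*config.rotation_deg))
            im = shear(im, rng.uniform(*config.shear), rng.uniform(*config.shear))
            if rng.random() < config.reflect_x:
                im = reflect(im, "x")
            if rng.random() < config.reflect_y:
                im = reflect(im, "y")
            im = translate(im, rng.uniform(*config.translate_frac) * w,
                           rng.uniform(*config.translate_frac) * h)
            im = rescale(im, rng.uniform(*config.scale))
            out.append(im)
    return out


def salt_pepper(img: LabeledImage, density: float,
                rng: np.random.Generator) -> LabeledImage:
    """Impulse noise: exactly ``round(density · #pixels)`` pixels forced to 0 or 1."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    px = img.pixels.copy()
    h, w = px.shape[:2]
    n = int(round(density * h * w))
    if n:
        flat = rng.choice(h * w, size=n, replace=False)
        vals = rng.integers(0, 2, size=n).astype(float)
        ys, xs = np.unravel_index(flat, (h, w))
        px[ys, xs] = vals if px.ndim == 2 else vals[:, None]
    return replace(img, pixels=px)


# ---------------------------------------------------------------------------
# synthetic blood-smear generator
# ---------------------------------------------------------------------------

def _draw_disc(px, cy, cx, radius, value, softness=1.0):
    h, w = px.shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    mask = np.clip((radius - d) / softness + 0.5, 0.0, 1.0)
    px[:] = px * (1 - mask) + value * mask


def _draw_nucleus(px, cy, cx, radius, irregularity, rng, value=0.2):
    """Dark nucleus with a radially perturbed boundary (random harmonics)."""
    h, w = px.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    d = np.sqrt(dy**2 + dx**2)
    theta = np.arctan2(dy, dx)
    r_theta = np.full_like(d, float(radius))
    if irregularity > 0:
        for harmonic in (2, 3, 5):
            amp = irregularity * radius * rng.uniform(0.2, 0.5) / len((2, 3, 5))
            phase = rng.uniform(0, 2 * np.pi)
            r_theta = r_theta + amp * np.sin(harmonic * theta + phase)
    mask = np.clip((r_theta - d) + 0.5, 0.0, 1.0)
    px[:] = px * (1 - mask) + value * mask


def generate_synthetic_dataset(config: SyntheticSmearConfig,
                               n_per_class: int) -> list:
    """Balanced two-class synthetic smear set, deterministic per seed.

    Leukemic images carry one large irregular dark nucleus, normal
    images one small round one, both over a light background scattered
    with faint disc distractors (red-cell analogues) plus Gaussian
    noise.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    out = []
    for label in CLASS_NAMES:
        leukemic = label == "leukemic"
        lo, hi = (config.blast_nucleus_radius if leukemic
                  else config.lymph_nucleus_radius)
        for _ in range(n_per_class):
            px = np.full((size, size), 0.88)
            # red-cell analogues: faint light discs
            for _ in range(rng.integers(config.n_red_cells[0],
                                        config.n_red_cells[1] + 1)):
                _draw_disc(px, rng.uniform(0, size), rng.uniform(0, size),
                           rng.uniform(0.08, 0.16) * size, rng.uniform(0.68, 0.78),
                           softness=1.5)
            cy = size / 2 + rng.uniform(-0.08, 0.08) * size
            cx = size / 2 + rng.uniform(-0.08, 0.08) * size
            radius = rng.uniform(lo, hi) * size
            irr = config.irregularity if leukemic else 0.05
            _draw_nucleus(px, cy, cx, radius, irr, rng,
                          value=rng.uniform(0.15, 0.3))
            px += rng.normal(0.0, config.noise_sigma, px.shape)
            out.append(LabeledImage(np.clip(px, 0.0, 1.0), label, "synthetic"))
    # interleave classes so truncations stay balanced
    interleaved = [im for pair in zip(out[:n_per_class], out[n_per_class:])
                   for im in pair]
    return interleaved


# ---------------------------------------------------------------------------
# conversion helpers
# ---------------------------------------------------------------------------

def resize_to(img: LabeledImage, height: int, width: int) -> LabeledImage:
    """Bilinear resize (with luminance conversion for RGB inputs)."""
    px = img.pixels
    if px.ndim == 3:
        px = px @ np.array([0.2126, 0.7152, 0.0722])
    out = sktransform.resize(px, (height, width), order=1, mode="reflect",
                             anti_aliasing=True, preserve_range=True)
    return replace(img, pixels=np.clip(out, 0.0, 1.0))


def dataset_arrays(images: list, height: int, width: int,
                   classes: tuple = CLASS_NAMES):
    """Stack a labeled set into (X, y) arrays for the network."""
    X = np.stack([resize_to(im, height, width).pixels for im in images])
    y = np.array([classes.index(im.label) for im in images])
    return X, y


# ---------------------------------------------------------------------------
# Pascal-VOC annotation I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VocObject:
    """One annotated cell: 1-based inclusive pixel box plus class label."""

    label: str
    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self):
        if self.xmin >= self.xmax or self.ymin >= self.ymax:
            raise ValueError(
                f"invalid box ({self.xmin},{self.ymin},{self.xmax},{self.ymax})"
            )

    def to_zero_based(self) -> tuple:
        """(xmin, ymin, xmax, ymax) as 0-based half-open coordinates."""
        return (self.xmin - 1, self.ymin - 1, self.xmax, self.ymax)


def read_voc_annotations(xml_path) -> list:
    """Parse a Pascal-VOC XML file into a list of :class:`VocObject`."""
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML {xml_path.name}: {exc}") from exc
    out = []
    for obj in root.iter("object"):
        label = obj.findtext("name")
        box = obj.find("bndbox")
        if label is None or box is None:
            raise ValueError(f"{xml_path.name}: object missing name or bndbox")
        coords = {}
        for tag in ("xmin", "ymin", "xmax", "ymax"):
            text = box.findtext(tag)
            if text is None:
                raise ValueError(f"{xml_path.name}: bndbox missing {tag}")
            coords[tag] = int(round(float(text)))
        out.append(VocObject(label=label, **coords))
    return out


def write_voc_annotations(xml_path, objects: list, image_filename: str = "",
                          image_shape: tuple | None = None) -> None:
    """Write objects back out as minimal Pascal-VOC XML."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = image_filename
    if image_shape is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "height").text = str(image_shape[0])
        ET.SubElement(size, "width").text = str(image_shape[1])
        depth = image_shape[2] if len(image_shape) > 2 else 1
        ET.SubElement(size, "depth").text = str(depth)
    for obj in objects:
        node = ET.SubElement(root, "object")
        ET.SubElement(node, "name").text = obj.label
        box = ET.SubElement(node, "bndbox")
        for tag in ("xmin", "ymin", "xmax", "ymax"):
            ET.SubElement(box, tag).text = str(getattr(obj, tag))
    ET.ElementTree(root).write(xml_path, encoding="unicode")


# ---------------------------------------------------------------------------
# dataset directory I/O  (<root>/<class>/<image>.jpg|png)
# ---------------------------------------------------------------------------

def load_image_directory(root) -> list:
    """Read a ``<root>/<class>/<image>`` tree into labeled images."""
    import imageio.v3 as iio

    root = Path(root)
    out = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in (".jpg", ".jpeg", ".png"):
                continue
            px = np.asarray(iio.imread(path), dtype=float)
            if px.max() > 1.0:
                px = px / 255.0
            out.append(LabeledImage(np.clip(px, 0, 1), class_dir.name))
    if not out:
        raise ValueError(f"no images found under {root}")
    return out


def save_image_directory(images: list, root) -> None:
    import imageio.v3 as iio

    root = Path(root)
    counters: dict = {}
    for im in images:
        d = root / im.label
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(im.label, 0)
        counters[im.label] = i + 1
        iio.imwrite(d / f"{im.label}_{i:04d}.png",
                    (im.pixels * 255).astype(np.uint8))
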