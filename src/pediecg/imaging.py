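"""Beat-frame rasterization and image-dataset construction.

One beat frame becomes a square grayscale raster: a black anti-aliased
polyline of the voltage trace on a white background, min–max normalized
per beat with 5 % vertical padding. Dataset construction follows the
training recipe: 3×3-grid crop augmentation (nine two-thirds-size crops
plus the original → ten images), exact-count salt-and-pepper noise on a
fixed share of the training split, class balancing by downsampling, and
a stratified, optionally record-grouped train/val/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from skimage.draw import line_aa

from .segmentation import BeatFrame
from .synthetic import TRAINABLE_CLASSES, BeatClass

_VALID_SPLITS = ("train", "val", "test", "unassigned")


@dataclass
class BeatImage:
    """Square 8-bit grayscale raster of one beat."""

    pixels: np.ndarray
    label: BeatClass | None = None
    source_record: str = ""
    source_peak_index: int = -1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if self.side < 32:
            raise ValueError("side must be >= 32")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class AugmentPolicy:
    """Augmentation knobs (defaults are the training recipe's values)."""

    crop_fraction: float = 2.0 / 3.0
    crops_per_image: int = 9
    pepper_fraction: float = 0.02
    noised_share: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.crop_fraction < 1):
            raise ValueError("crop_fraction must be in (0, 1)")
        if not (0 <= self.pepper_fraction < 1):
            raise ValueError("pepper_fraction must be in [0, 1)")
        if not (0 <= self.noised_share <= 1):
            raise ValueError("noised_share must be in [0, 1]")


@dataclass
class LabeledDataset:
    """Labeled beat images with a per-image split tag."""

    images: list[BeatImage]
    split_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split_tags:
            self.split_tags = ["unassigned"] * len(self.images)
        if len(self.split_tags) != len(self.images):
            raise ValueError("split_tags must align with images")
        for tag in self.split_tags:
            if tag not in _VALID_SPLITS:
                raise ValueError(f"unknown split tag {tag!r}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> list[BeatImage]:
        return [im for im, tag in zip(self.images, self.split_tags) if tag == split]

    def class_counts(self) -> dict[BeatClass, int]:
        counts: dict[BeatClass, int] = {}
        for im in self.images:
            if im.label is not None:
                counts[im.label] = counts.get(im.label, 0) + 1
        return counts


def render_beat_image(frame: BeatFrame, side: int = 128) -> BeatImage:
    """Rasterize a beat frame to a ``side`` × ``side`` grayscale image.

    White background, black one-pixel anti-aliased polyline; time maps
    linearly to x over the full width, voltage to y using the frame's
    own min–max range with 5 % padding (so rendering is invariant to
    positive amplitude scaling). A constant frame renders as a single
    horizontal line at mid-height. No axes, ticks, or text.
    """
    if side < 32:
        raise ValueError("side must be >= 32")
    v = np.asarray(frame.samples, dtype=float)
    if len(v) == 0:
        raise ValueError("frame is empty")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        norm = (v - vmin) / (vmax - vmin)
    else:
        norm = np.full_like(v, 0.5)
    pad = 0.05
    ys = (side - 1) * (pad + (1.0 - 2.0 * pad) * (1.0 - norm))
    xs = np.linspace(0.0, side - 1, len(v))
    rows = np.rint(ys).astype(int)
    cols = np.rint(xs).astype(int)

    canvas = np.full((side, side), 255.0)
    if len(v) == 1:
        canvas[rows[0], cols[0]] = 0.0
    for i in range(len(v) - 1):
        rr, cc, val = line_aa(rows[i], cols[i], rows[i + 1], cols[i + 1])
        canvas[rr, cc] = np.minimum(canvas[rr, cc], 255.0 * (1.0 - val))
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return BeatImage(
        pixels=pixels,
        label=None,
        source_record=frame.parent_id,
        source_peak_index=frame.r_peak_index_global,
    )


def crop_augment(image: BeatImage, policy: AugmentPolicy | None = None) -> list[BeatImage]:
    """The original plus nine two-thirds-size crops, rescaled back up.

    Crops form a 3×3 grid: windows of side round(crop_fraction × side)
    anchored at (0, ½, 1) of the free margin in each axis, each resized
    to the original side by bilinear interpolation. Labels and source
    provenance are inherited, so with the default policy one labeled
    beat yields ten similar labeled images.
    """
    policy = policy or AugmentPolicy()
    side = image.side
    crop_side = int(round(policy.crop_fraction * side))
    if crop_side < 16:
        raise ValueError("crop side < 16; image too small for this crop_fraction")
    margin = side - crop_side
    anchors = sorted({0, int(round(margin / 2)), margin})
    out = [replace(image, pixels=image.pixels.copy())]
    n_grid = len(anchors) ** 2
    count = 0
    for top in anchors:
        for left in anchors:
            if count >= policy.crops_per_image:
                break
            window = image.pixels[top : top + crop_side, left : left + crop_side]
            resized = Image.fromarray(window).resize((side, side), Image.BILINEAR)
            out.append(replace(image, pixels=np.asarray(resized, dtype=np.uint8)))
            count += 1
    # if more crops requested than the 3×3 grid provides, tile again
    while count < policy.crops_per_image:
        out.append(replace(image, pixels=out[1 + count % n_grid].pixels.copy()))
        count += 1
    return out


def salt_and_pepper(image: BeatImage, pepper_fraction: float = 0.02, seed: int = 0) -> BeatImage:
    """Blacken exactly round(pepper_fraction × side²) random pixels.

    "Colored black" pepper noise with an exact count (not i.i.d.
    Bernoulli): distinct pixels are drawn uniformly under ``seed``
    from those not already black and set to 0, so exactly the stated
    number of pixels changes; all other pixels are untouched and no
    pixel value ever increases.
    """
    if not (0 <= pepper_fraction < 1):
        raise ValueError("pepper_fraction must be in [0, 1)")
    side = image.side
    n_pepper = int(round(pepper_fraction * side * side))
    pixels = image.pixels.copy()
    if n_pepper > 0:
        rng = np.random.default_rng(seed)
        candidates = np.flatnonzero(pixels.reshape(-1) != 0)
        n_pepper = min(n_pepper, len(candidates))
        flat = rng.choice(candidates, size=n_pepper, replace=False)
        pixels.reshape(-1)[flat] = 0
    return replace(image, pixels=pixels)


def apply_noise_policy(dataset: LabeledDataset, policy: AugmentPolicy | None = None) -> LabeledDataset:
    """Salt-and-pepper exactly round(noised_share × n_train) training images.

    Models generalized best with pepper noise on 70 % of the training
    images; validation and test images are never touched.
    """
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(policy.seed)
    train_idx = [i for i, tag in enumerate(dataset.split_tags) if tag == "train"]
    n_noise = int(round(policy.noised_share * len(train_idx)))
    chosen = set(
        rng.choice(len(train_idx), size=n_noise, replace=False).tolist()
    ) if n_noise else set()
    pixel_seeds = rng.integers(0, 2**31 - 1, size=len(train_idx))
    images = list(dataset.images)
    for k, i in enumerate(train_idx):
        if k in chosen:
            images[i] = salt_and_pepper(
                images[i], policy.pepper_fraction, int(pixel_seeds[k])
            )
    return LabeledDataset(images=images, split_tags=list(dataset.split_tags))


def balance_classes(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Downsample every trainable class to the minimum class count.

    Balanced training data is obtained by selecting the same number of
    images for all classes — subset selection under ``seed``, never
    duplication. Raises if a trainable class is absent.
    """
    by_class: dict[BeatClass, list[int]] = {c: [] for c in TRAINABLE_CLASSES}
    for i, im in enumerate(dataset.images):
        if im.label in by_class:
            by_class[im.label].append(i)
    for cls, idx in by_class.items():
        if not idx:
            raise ValueError(f"trainable class {cls.value} has no images")
    n_min = min(len(idx) for idx in by_class.values())
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in TRAINABLE_CLASSES:
        idx = np.asarray(by_class[cls])
        keep.extend(idx[rng.choice(len(idx), size=n_min, replace=False)].tolist())
    order = rng.permutation(len(keep))
    keep = [keep[i] for i in order]
    return LabeledDataset(
        images=[dataset.images[i] for i in keep],
        split_tags=[dataset.split_tags[i] for i in keep],
    )


def split_dataset(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    group_by_record: bool = True,
) -> LabeledDataset:
    """Assign train/val/test tags, stratified by class.

    With ``group_by_record`` (the default) all beats of one source
    record land in the same split, preventing beat-level leakage of a
    record between train and test.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    tags = ["unassigned"] * n

    if group_by_record:
        groups: dict[str, list[int]] = {}
        for i, im in enumerate(dataset.images):
            groups.setdefault(im.source_record or f"#{i}", []).append(i)
        keys = sorted(groups)
        order = rng.permutation(len(keys))
        targets = [f * n for f in fractions]
        filled = [0.0, 0.0, 0.0]
        for k in order:
            idx = groups[keys[k]]
            # place the group where the deficit (relative to target) is largest
            deficits = [targets[j] - filled[j] for j in range(3)]
            j = int(np.argmax(deficits))
            for i in idx:
                tags[i] = _VALID_SPLITS[j]
            filled[j] += len(idx)
        return LabeledDataset(images=list(dataset.images), split_tags=tags)

    by_class: dict[BeatClass | None, list[int]] = {}
    for i, im in enumerate(dataset.images):
        by_class.setdefault(im.label, []).append(i)
    for idx in by_class.values():
        arr = np.asarray(idx)[rng.permutation(len(idx))]
        n_c = len(arr)
        n_train = int(round(fractions[0] * n_c))
        n_val = int(round(fractions[1] * n_c))
        n_val = min(n_val, n_c - n_train)
        for i in arr[:n_train]:
            tags[i] = "train"
        for i in arr[n_train : n_train + n_val]:
            tags[i] = "val"
        for i in arr[n_train + n_val :]:
            tags[i] = "test"
    return LabeledDataset(images=list(dataset.images), split_tags=tags)


def save_png(image: BeatImage, path) -> None:
    Image.fromarray(image.pixels, mode="L").save(path)


def load_png(path, label: BeatClass | None = None) -> BeatImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    return BeatImage(pixels=arr, label=label)
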