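"""Programmatic beat-image datasets for classifier training.

Builds labeled single-beat images straight from the synthetic
templates: each beat gets its own jittered amplitude, QRS width, RR
context, and additive noise, then passes through the real framing and
rendering path, so a classifier trained here sees exactly the image
statistics the pipeline produces at inference time.
"""

from __future__ import annotations

import numpy as np

from .imaging import BeatImage, LabeledDataset, render_beat_image, split_dataset
from .segmentation import BeatFrame
from .synthetic import (
    DEFAULT_QRS_AMPLITUDE_UV,
    DEFAULT_QRS_WIDTH_MS,
    TRAINABLE_CLASSES,
    BeatClass,
    beat_template,
)


def synthetic_beat_frame(
    cls: BeatClass,
    rng: np.random.Generator,
    noise_sd_uv: float = 5.0,
    sampling_rate_hz: float = 512.0,
    record_id: str = "",
) -> BeatFrame:
    """One jittered beat of class ``cls`` wrapped in a plausible frame."""
    amp = DEFAULT_QRS_AMPLITUDE_UV * rng.uniform(0.75, 1.25)
    width = DEFAULT_QRS_WIDTH_MS[cls] * rng.uniform(0.9, 1.1)
    tpl = beat_template(cls, sampling_rate_hz, amp, width)
    half = len(tpl) // 2
    rr_prev = rng.uniform(500.0, 900.0)
    rr_next = rng.uniform(500.0, 900.0)
    n_left = int(rr_prev / 2000.0 * sampling_rate_hz)
    n_right = int(rr_next / 2000.0 * sampling_rate_hz)
    window = np.zeros(n_left + n_right + 1)
    lo = n_left - half
    for i, v in enumerate(tpl):
        j = lo + i
        if 0 <= j < len(window):
            window[j] += v
    window += rng.normal(0.0, noise_sd_uv, len(window))
    window += np.linspace(0, rng.uniform(-30, 30), len(window))  # mild drift
    return BeatFrame(
        samples=window,
        r_peak_index_global=n_left,
        r_peak_index_local=n_left,
        rr_prev_ms=rr_prev,
        rr_next_ms=rr_next,
        parent_id=record_id,
    )


def make_beat_image_dataset(
    n_per_class: int = 200,
    side: int = 128,
    noise_sd_uv: float = 5.0,
    seed: int = 0,
    classes: tuple[BeatClass, ...] = TRAINABLE_CLASSES,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> LabeledDataset:
    """Balanced labeled beat images with a stratified split.

    One image per synthetic record id, so record grouping cannot leak
    beats between splits.
    """
    rng = np.random.default_rng(seed)
    images: list[BeatImage] = []
    for cls in classes:
        for i in range(n_per_class):
            frame = synthetic_beat_frame(
                cls, rng, noise_sd_uv, record_id=f"synthbeat-{cls.value}-{i:04d}"
            )
            image = render_beat_image(frame, side)
            image.label = cls
            images.append(image)
    dataset = LabeledDataset(images=images)
    return split_dataset(dataset, fractions, seed=seed + 1, group_by_record=False)


def permute_labels(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Shuffle train+val labels (test untouched): a leakage control.

    A pipeline with no label leakage must fall to chance accuracy on
    the intact test split when trained on permuted labels.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    idx = [i for i, tag in enumerate(dataset.split_tags) if tag in ("train", "val")]
    labels = [dataset.images[i].label for i in idx]
    perm = rng.permutation(len(idx))
    images = list(dataset.images)
    for k, i in enumerate(idx):
        images[i] = replace(images[i], label=labels[perm[k]])
    return LabeledDataset(images=images, split_tags=list(dataset.split_tags))
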