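import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pediecg.imaging import (
    AugmentPolicy,
    BeatImage,
    LabeledDataset,
    apply_noise_policy,
    balance_classes,
    crop_augment,
    render_beat_image,
    salt_and_pepper,
    split_dataset,
)
from pediecg.segmentation import BeatFrame
from pediecg.synthetic import BeatClass, beat_template


def _frame(samples, parent="rec"):
    samples = np.asarray(samples, dtype=float)
    return BeatFrame(samples, 0, len(samples) // 2, None, None, parent)


def _beat_frame(cls="N", scale=1.0):
    return _frame(scale * beat_template(cls))


def _labeled(n_per_class, side=64, seed=0):
    rng = np.random.default_rng(seed)
    images, tags = [], []
    for cls, n in n_per_class.items():
        for i in range(n):
            px = rng.integers(0, 256, (side, side), dtype=np.uint8)
            images.append(
                BeatImage(px, label=BeatClass(cls), source_record=f"{cls}{i % 5}")
            )
            tags.append("unassigned")
    return LabeledDataset(images, tags)


class TestRender:
    @pytest.mark.parametrize("side", [128, 299])
    def test_output_is_square_of_requested_side(self, side):
        image = render_beat_image(_beat_frame(), side)
        assert image.pixels.shape == (side, side)

    def test_rendering_is_deterministic(self):
        a = render_beat_image(_beat_frame(), 128)
        b = render_beat_image(_beat_frame(), 128)
        assert np.array_equal(a.pixels, b.pixels)

    def test_constant_frame_renders_midline(self):
        image = render_beat_image(_frame(np.full(100, 7.0)), 128)
        dark_rows = np.where((image.pixels < 255).any(axis=1))[0]
        assert len(dark_rows) == 1
        assert abs(dark_rows[0] - 64) <= 1
        assert (image.pixels[dark_rows[0]] == 0).all()

    def test_scale_covariance(self):
        base = render_beat_image(_beat_frame("N"), 128)
        for scale in (0.25, 3.0, 1000.0):
            scaled = render_beat_image(_beat_frame("N", scale), 128)
            assert np.array_equal(base.pixels, scaled.pixels)

    def test_small_side_rejected(self):
        with pytest.raises(ValueError):
            render_beat_image(_beat_frame(), 16)


class TestCropAugment:
    def test_ten_images_out(self):
        image = render_beat_image(_beat_frame(), 128)
        image.label = BeatClass.N
        out = crop_augment(image)
        assert len(out) == 10
        assert all(o.side == 128 for o in out)
        assert all(o.label == BeatClass.N for o in out)

    def test_uniform_white_stays_white(self):
        image = BeatImage(np.full((96, 96), 255, dtype=np.uint8))
        for out in crop_augment(image):
            assert (out.pixels == 255).all()

    def test_crops_differ_from_original(self):
        image = render_beat_image(_beat_frame(), 128)
        out = crop_augment(image)
        assert np.array_equal(out[0].pixels, image.pixels)
        assert any(not np.array_equal(o.pixels, image.pixels) for o in out[1:])

    def test_too_small_for_crop_rejected(self):
        image = BeatImage(np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError, match="crop"):
            crop_augment(image, AugmentPolicy(crop_fraction=0.4))


class TestSaltAndPepper:
    def test_zero_fraction_is_identity(self):
        image = render_beat_image(_beat_frame(), 128)
        out = salt_and_pepper(image, 0.0, seed=1)
        assert np.array_equal(out.pixels, image.pixels)

    def test_exact_pepper_count_and_darkening_only(self):
        image = BeatImage(np.full((128, 128), 200, dtype=np.uint8))
        out = salt_and_pepper(image, 0.02, seed=5)
        changed = out.pixels != image.pixels
        assert changed.sum() == round(0.02 * 128 * 128) == 328
        assert (out.pixels[changed] == 0).all()
        assert (out.pixels <= image.pixels).all()

    def test_same_seed_same_noise(self):
        image = render_beat_image(_beat_frame(), 128)
        a = salt_and_pepper(image, 0.05, seed=9)
        b = salt_and_pepper(image, 0.05, seed=9)
        assert np.array_equal(a.pixels, b.pixels)


class TestNoisePolicy:
    def _split_dataset(self):
        ds = _labeled({"N": 40, "R": 40, "P": 40, "V": 40})
        return split_dataset(ds, seed=2, group_by_record=False)

    def test_zero_share_unchanged(self):
        ds = self._split_dataset()
        out = apply_noise_policy(ds, AugmentPolicy(noised_share=0.0))
        assert all(
            np.array_equal(a.pixels, b.pixels) for a, b in zip(ds.images, out.images)
        )

    def test_exact_noised_count_train_only(self):
        ds = self._split_dataset()
        policy = AugmentPolicy(noised_share=0.70, seed=4)
        out = apply_noise_policy(ds, policy)
        n_train = sum(tag == "train" for tag in ds.split_tags)
        noised = sum(
            not np.array_equal(a.pixels, b.pixels)
            for a, b, tag in zip(ds.images, out.images, ds.split_tags)
            if tag == "train"
        )
        assert noised == round(0.70 * n_train)
        for a, b, tag in zip(ds.images, out.images, ds.split_tags):
            if tag != "train":
                assert np.array_equal(a.pixels, b.pixels)


class TestBalance:
    def test_downsamples_to_minimum(self):
        ds = _labeled({"N": 100, "R": 40, "P": 40, "V": 40})
        out = balance_classes(ds, seed=0)
        counts = out.class_counts()
        assert all(v == 40 for v in counts.values())
        assert len(out) == 160

    def test_balanced_input_preserved_up_to_order(self):
        ds = _labeled({"N": 10, "R": 10, "P": 10, "V": 10})
        out = balance_classes(ds, seed=0)
        assert len(out) == 40

    def test_missing_class_named(self):
        ds = _labeled({"N": 10, "R": 10, "P": 10})
        with pytest.raises(ValueError, match="V"):
            balance_classes(ds, seed=0)

    def test_deterministic(self):
        ds = _labeled({"N": 50, "R": 20, "P": 20, "V": 20})
        a = balance_classes(ds, seed=3)
        b = balance_classes(ds, seed=3)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a.images, b.images))


class TestSplit:
    def test_split_sizes_stratified(self):
        ds = _labeled({"N": 25, "R": 25, "P": 25, "V": 25})
        out = split_dataset(ds, (0.70, 0.15, 0.15), seed=1, group_by_record=False)
        sizes = {s: len(out.subset(s)) for s in ("train", "val", "test")}
        assert abs(sizes["train"] - 70) <= 4
        assert abs(sizes["val"] - 15) <= 4
        assert abs(sizes["test"] - 15) <= 4
        assert sum(sizes.values()) == 100

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = _labeled({"N": 30, "R": 30, "P": 30, "V": 30})
        out = split_dataset(ds, seed=5, group_by_record=False)
        assert "unassigned" not in out.split_tags

    def test_grouped_split_keeps_records_together(self):
        ds = _labeled({"N": 40, "R": 40, "P": 40, "V": 40})
        out = split_dataset(ds, seed=5, group_by_record=True)
        record_split: dict[str, str] = {}
        for image, tag in zip(out.images, out.split_tags):
            assert record_split.setdefault(image.source_record, tag) == tag

    def test_bad_fractions_rejected(self):
        ds = _labeled({"N": 4})
        with pytest.raises(ValueError, match="sum"):
            split_dataset(ds, (0.5, 0.3, 0.3))

    def test_same_seed_same_assignment(self):
        ds = _labeled({"N": 20, "R": 20, "P": 20, "V": 20})
        a = split_dataset(ds, seed=8, group_by_record=False)
        b = split_dataset(ds, seed=8, group_by_record=False)
        assert a.split_tags == b.split_tags


@settings(max_examples=15, deadline=None, derandomize=True)
@given(fraction=st.floats(0.0, 0.2), seed=st.integers(0, 1000))
def test_pepper_never_brightens(fraction, seed):
    rng = np.random.default_rng(seed)
    image = BeatImage(rng.integers(0, 256, (64, 64), dtype=np.uint8))
    out = salt_and_pepper(image, fraction, seed)
    assert (out.pixels <= image.pixels).all()
    assert (out.pixels != image.pixels).sum() <= round(fraction * 64 * 64)
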