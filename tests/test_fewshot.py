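"""Few-shot split construction: stride rule, remapping, leakage guards."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maefew.fewshot import (
    FewShotSpec,
    build_classification_split,
    build_segmentation_split,
    remap_volume_to_slices,
    split_manifest,
    stride_sample,
)
from maefew.phantom import PhantomSpec, PhantomVolume, generate_cohort


class TestStrideSample:
    @pytest.mark.parametrize(
        "k,expected", [(4, 56), (5, 44), (6, 37), (7, 32), (8, 28), (9, 24),
                       (10, 22)]
    )
    def test_counts_on_224_axis(self, k, expected):
        assert len(stride_sample(224, k)) == expected

    def test_indices_are_one_based_multiples(self):
        assert stride_sample(10, 3) == [2, 5, 8]
        assert stride_sample(10, 1) == list(range(10))

    def test_stride5_doubles_stride10(self):
        assert len(stride_sample(224, 5)) == 2 * len(stride_sample(224, 10))

    def test_oversized_stride_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert stride_sample(5, 9) == []

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 1024), st.integers(1, 1024))
    def test_count_is_floor_n_over_k(self, n, k):
        if k <= n:
            assert len(stride_sample(n, k)) == n // k

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            stride_sample(0, 1)
        with pytest.raises(ValueError):
            stride_sample(5, 0)


def _toy_volume(n_axial=5, empty=(0, 4), size=8, seq="T1", vid="v0"):
    labels = np.zeros((size, size, n_axial), dtype=np.int64)
    for i in range(n_axial):
        if i not in empty:
            labels[2:6, 2:6, i] = 1
    return PhantomVolume(
        image=np.random.default_rng(0).random((size, size, n_axial)),
        brain_mask=(labels > 0).astype(np.uint8),
        labels=labels,
        voxel_size_mm=(1, 1, 1),
        sequence=seq,
        volume_id=vid,
    )


class TestRemap:
    def test_empty_mask_slices_dropped(self):
        vol = _toy_volume(n_axial=5, empty=(1, 3))
        out = remap_volume_to_slices(vol, axes=("axial",), min_foreground=1)
        assert len(out) == 3
        assert [s.provenance[2] for s in out] == [0, 2, 4]

    def test_axial_only_keeps_all_nonempty(self):
        vol = _toy_volume(n_axial=8, empty=(), size=8)
        out = remap_volume_to_slices(vol, axes=("axial",), min_foreground=1)
        assert len(out) == 8

    def test_triaxial_additivity(self):
        labels = np.ones((8, 8, 8), dtype=np.int64)
        vol = PhantomVolume(
            image=np.random.default_rng(1).random((8, 8, 8)),
            brain_mask=np.ones((8, 8, 8), dtype=np.uint8),
            labels=labels, voxel_size_mm=(1, 1, 1), sequence="T1",
        )
        n1 = len(remap_volume_to_slices(vol, axes=("axial",)))
        n3 = len(remap_volume_to_slices(vol))
        assert n1 == 8 and n3 == 24

    def test_stride_applied_per_axis(self):
        vol = _toy_volume(n_axial=224, empty=(), size=4)
        out = remap_volume_to_slices(vol, axes=("axial",), stride_k=7)
        assert len(out) == 32

    def test_provenance_and_alpha_recorded(self):
        vol = _toy_volume()
        s = remap_volume_to_slices(vol, axes=("axial",))[0]
        assert s.provenance == ("v0", "axial", 1)
        assert s.alpha == pytest.approx(16 / 64)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(PhantomSpec(seed=17), 4)


class TestClassificationSplit:
    def test_train_count_and_determinism(self, small_cohort):
        a = build_classification_split(small_cohort, 10, seed=3)
        b = build_classification_split(small_cohort, 10, seed=3)
        assert len(a.train) == 10 * len(a.class_names)
        assert split_manifest(a).equals(split_manifest(b))

    def test_no_volume_level_leakage(self, small_cohort):
        split = build_classification_split(small_cohort, 10, seed=3)
        train_ids = {(s.sequence, s.provenance[0]) for s in split.train}
        test_ids = {(s.sequence, s.provenance[0]) for s in split.test}
        assert train_ids and test_ids
        assert not train_ids & test_ids

    def test_overdraw_names_the_sequence(self, small_cohort):
        with pytest.raises(ValueError, match="FLAIR"):
            build_classification_split(small_cohort, 10_000, seed=0)

    def test_seed_changes_selection_not_counts(self, small_cohort):
        a = build_classification_split(small_cohort, 10, seed=3)
        b = build_classification_split(small_cohort, 10, seed=4)
        assert len(a.train) == len(b.train)
        assert not split_manifest(a).equals(split_manifest(b))


class TestSegmentationSplit:
    def test_skullstrip_stride7_on_224_axis(self):
        vols = [_toy_volume(n_axial=224, empty=(), size=4, vid=f"v{i}")
                for i in range(2)]
        spec = FewShotSpec(task="skull_strip", stride_k=7, axes=("axial",),
                           seed=0, image_size=None)
        split = build_segmentation_split(vols, spec)
        assert len(split.train) == 32  # Table-2 style count for one subject

    def test_anatomy_overdraw_errors(self, small_cohort):
        spec = FewShotSpec(task="anatomy", n_volumes=99, seed=0,
                           image_size=None)
        with pytest.raises(ValueError):
            build_segmentation_split(small_cohort["T1"], spec)

    def test_manifest_rows_match_recount(self, small_cohort):
        spec = FewShotSpec(task="anatomy", n_volumes=2, seed=1,
                           image_size=None)
        split = build_segmentation_split(small_cohort["T1"], spec)
        manifest = split_manifest(split)
        expected = sum(
            len(remap_volume_to_slices(v))
            for v in small_cohort["T1"]
        )
        assert len(manifest) == expected
        assert (manifest["split"] == "train").sum() == len(split.train)

    def test_volume_level_disjointness(self, small_cohort):
        spec = FewShotSpec(task="anatomy", n_volumes=2, seed=1,
                           image_size=None)
        split = build_segmentation_split(small_cohort["T1"], spec)
        tr = {s.provenance[0] for s in split.train}
        te = {s.provenance[0] for s in split.test}
        assert not tr & te


def test_fewshot_spec_validation():
    with pytest.raises(ValueError):
        FewShotSpec(stride_k=0)
    with pytest.raises(ValueError):
        FewShotSpec(min_foreground=-1)
    with pytest.raises(ValueError):
        FewShotSpec(axes=("diagonal",))
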