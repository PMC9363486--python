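"""Splits, CRISPR pair encoding/filtering, synthetic generators and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsanomaly import (
    GRNATargetPair,
    SplitSpec,
    build_diverse_inlier_split,
    build_diverse_outlier_split,
    decode_pair,
    encode_pair,
    filter_pairs,
    generate_synthetic_images,
    generate_synthetic_pairs,
    mismatch_count,
    read_image_dataset,
    read_pairs_tsv,
    train_test_split_stratified,
    write_image_dataset,
    write_pairs_tsv,
)


@pytest.fixture(scope="module")
def toy_dataset():
    rng = np.random.default_rng(3)
    labels = np.repeat(np.arange(4), 250)  # 4 classes x 250
    images = rng.random((1000, 1, 12, 12))
    return images, labels


class TestDiverseOutlier:
    def test_counts_and_labels(self, toy_dataset):
        images, labels = toy_dataset
        # 250 focal examples at 1% -> round(2.5) = 2 anomalies
        split = build_diverse_outlier_split(images, labels, 0, 0.01, seed=1)
        assert (split.labels == 0).sum() == 250
        assert (split.labels == 1).sum() == 2
        assert np.all(labels[split.indices[split.labels == 0]] == 0)
        assert np.all(labels[split.indices[split.labels == 1]] != 0)

    def test_thousand_focal_one_percent_gives_ten(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.zeros(1000, int), np.ones(500, int)])
        images = rng.random((1500, 1, 4, 4))
        split = build_diverse_outlier_split(images, labels, 0, 0.01, seed=0)
        assert (split.labels == 1).sum() == 10

    def test_zero_anomalies_rejected(self, toy_dataset):
        images, labels = toy_dataset
        with pytest.raises(ValueError):
            build_diverse_outlier_split(images, labels, 0, 0.001, seed=1)

    def test_same_seed_identical(self, toy_dataset):
        images, labels = toy_dataset
        a = build_diverse_outlier_split(images, labels, 2, 0.1, seed=5)
        b = build_diverse_outlier_split(images, labels, 2, 0.1, seed=5)
        assert np.array_equal(a.indices, b.indices)
        assert np.array_equal(a.labels, b.labels)


class TestDiverseInlier:
    def test_focal_class_fully_anomalous(self, toy_dataset):
        images, labels = toy_dataset
        split = build_diverse_inlier_split(images, labels, 1, 0.5, seed=2)
        anom = split.indices[split.labels == 1]
        assert set(anom) == set(np.flatnonzero(labels == 1))
        assert np.all(labels[split.indices[split.labels == 0]] != 1)

    def test_normal_pool_size_capped_by_availability(self, toy_dataset):
        images, labels = toy_dataset
        # round(250 / 0.1) = 2500 > 750 available -> capped
        split = build_diverse_inlier_split(images, labels, 1, 0.1, seed=2)
        assert (split.labels == 0).sum() == 750

    def test_labels_complement_outlier_construction(self, toy_dataset):
        """Same membership roles, opposite labels, across the two setups."""
        images, labels = toy_dataset
        out_s = build_diverse_outlier_split(images, labels, 3, 0.1, seed=7)
        in_s = build_diverse_inlier_split(images, labels, 3, 0.5, seed=7)
        focal = set(np.flatnonzero(labels == 3))
        assert set(out_s.indices[out_s.labels == 0]) == focal
        assert set(in_s.indices[in_s.labels == 1]) == focal

    def test_same_seed_identical(self, toy_dataset):
        images, labels = toy_dataset
        a = build_diverse_inlier_split(images, labels, 0, 0.2, seed=5)
        b = build_diverse_inlier_split(images, labels, 0, 0.2, seed=5)
        assert np.array_equal(a.indices, b.indices)


@given(setup=st.sampled_from(["diverse_outlier", "diverse_inlier"]),
       focal=st.integers(0, 3),
       fraction=st.sampled_from([0.1, 0.05, 0.5]),
       seed=st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_split_label_composition_invariants(setup, focal, fraction, seed):
    """Both labels present; focal class takes the setup's designated label."""
    labels = np.repeat(np.arange(4), 60)
    images = np.zeros((240, 1, 4, 4))
    builder = (build_diverse_outlier_split if setup == "diverse_outlier"
               else build_diverse_inlier_split)
    split = builder(images, labels, focal, fraction, seed=seed)
    assert {0, 1} == set(np.unique(split.labels))
    focal_label = 0 if setup == "diverse_outlier" else 1
    focal_members = split.indices[split.labels == focal_label]
    assert set(np.flatnonzero(labels == focal)) == set(focal_members)


def test_split_manifest_roundtrip(toy_dataset):
    images, labels = toy_dataset
    split = build_diverse_outlier_split(images, labels, 0, 0.1, seed=3)
    clone = SplitSpec.from_manifest(split.to_manifest())
    assert (clone.setup, clone.focal_class, clone.anomaly_fraction, clone.seed) == (
        split.setup, split.focal_class, split.anomaly_fraction, split.seed)
    assert np.array_equal(clone.indices, split.indices)
    assert np.array_equal(clone.labels, split.labels)


def test_stratified_split_keeps_both_classes():
    y = np.array([0] * 90 + [1] * 10)
    tr, te = train_test_split_stratified(y, 0.3, seed=0)
    assert sorted(np.concatenate([tr, te])) == list(range(100))
    assert set(y[te]) == {0, 1} and set(y[tr]) == {0, 1}
    assert (y[te] == 1).sum() == 3


# ------------------------------------------------------------- CRISPR pairs
class TestPairEncoding:
    def test_homopolymer_pair(self):
        p = GRNATargetPair("A" * 23, "A" * 23, 0)
        enc = encode_pair(p)
        assert enc.shape == (2, 4, 23)
        assert np.all(enc[:, 0, :] == 1)
        assert np.all(enc[:, 1:, :] == 0)

    def test_column_sums_one_for_random_pairs(self):
        for p in generate_synthetic_pairs(5, 5, seed=1):
            enc = encode_pair(p)
            assert enc.shape == (2, 4, 23)
            assert np.all(enc.sum(axis=1) == 1)

    def test_encode_decode_roundtrip(self):
        for p in generate_synthetic_pairs(10, 10, seed=2):
            q = decode_pair(encode_pair(p), label=p.label)
            assert (q.target, q.grna, q.label) == (p.target, p.grna, p.label)

    def test_wrong_length_rejected_with_position(self):
        with pytest.raises(ValueError, match="23"):
            GRNATargetPair("A" * 22, "A" * 23, 0)

    def test_invalid_character_reports_position(self):
        with pytest.raises(ValueError, match="position 5"):
            GRNATargetPair("ACGTA" + "N" + "A" * 17, "A" * 23, 0)

    def test_mismatch_count(self):
        assert mismatch_count("AAAA", "AAAA") == 0
        assert mismatch_count("AAAA", "ATAT") == 2


class TestFilterPairs:
    def _pair_with_mismatches(self, k):
        target = "A" * 23
        grna = "C" * k + "A" * (23 - k)
        return GRNATargetPair(target, grna, 1)

    def test_boundary_at_six(self):
        kept = filter_pairs([self._pair_with_mismatches(k) for k in (0, 6, 7)])
        assert [p.mismatches for p in kept] == [0, 6]

    def test_idempotent_and_order_preserving(self):
        pairs = [self._pair_with_mismatches(k) for k in (3, 1, 7, 6, 2)]
        once = filter_pairs(pairs)
        assert filter_pairs(once) == once
        assert [p.mismatches for p in once] == [3, 1, 6, 2]


# ------------------------------------------------------ synthetic fixtures
class TestSyntheticImages:
    def test_reproducible_under_seed(self):
        a = generate_synthetic_images(2, 20, 16, seed=4)
        b = generate_synthetic_images(2, 20, 16, seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_value_range_and_shape(self):
        images, labels = generate_synthetic_images(3, 10, 20, seed=1)
        assert images.shape == (30, 1, 20, 20)
        assert images.min() >= 0 and images.max() <= 1
        assert set(labels) == {0, 1, 2}

    def test_pixel_mean_classifier_beats_chance(self):
        """The two classes are visibly different: a nearest-class-mean rule
        on raw pixels beats random guessing."""
        images, labels = generate_synthetic_images(2, 200, 16, seed=8)
        flat = images.reshape(len(images), -1)
        half = len(flat) // 2
        mu0 = flat[:half][labels[:half] == 0].mean(axis=0)
        mu1 = flat[:half][labels[:half] == 1].mean(axis=0)
        pred = (np.linalg.norm(flat[half:] - mu1, axis=1)
                < np.linalg.norm(flat[half:] - mu0, axis=1)).astype(int)
        assert (pred == labels[half:]).mean() > 0.8

    def test_noiseless_images_differ_only_by_jitter(self):
        images, labels = generate_synthetic_images(1, 30, 16, seed=2, noise=0.0,
                                                   jitter=0)
        # same class, no jitter, no noise: only the intensity gain varies,
        # so supports (nonzero pixel sets) are identical
        support = images[0, 0] > 0
        for img in images[:, 0]:
            assert np.array_equal(img > 0, support)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_images(2, 5, 8, seed=0)


class TestSyntheticPairs:
    def test_lengths_alphabet_and_filter_survival(self):
        pairs = generate_synthetic_pairs(30, 10, seed=5)
        assert len(pairs) == 40
        for p in pairs:
            assert len(p.target) == len(p.grna) == 23
            assert set(p.target) <= set("ACGT")
            assert 1 <= p.mismatches <= 6
        assert filter_pairs(pairs) == pairs

    def test_reproducible_under_seed(self):
        a = generate_synthetic_pairs(10, 5, seed=6)
        b = generate_synthetic_pairs(10, 5, seed=6)
        assert a == b

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            generate_synthetic_pairs(0, 5, seed=1)


# ------------------------------------------------------------------ file IO
class TestIO:
    def test_npz_roundtrip(self, tmp_path):
        images, labels = generate_synthetic_images(2, 5, 16, seed=9)
        path = tmp_path / "data.npz"
        write_image_dataset(path, images, labels)
        ri, rl = read_image_dataset(path)
        assert np.array_equal(ri, images) and np.array_equal(rl, labels)

    def test_png_roundtrip_quantized(self, tmp_path):
        images, labels = generate_synthetic_images(2, 4, 16, seed=9)
        write_image_dataset(tmp_path / "imgs", images, labels, fmt="png")
        ri, rl = read_image_dataset(tmp_path / "imgs")
        assert ri.shape == images.shape
        assert np.sort(rl).tolist() == np.sort(labels).tolist()
        # 8-bit quantization bound
        order = np.argsort(labels, kind="stable")
        assert np.abs(np.sort(ri.ravel()) - np.sort(images.ravel())).max() <= 1 / 255

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError):
            read_image_dataset(tmp_path / "empty")

    def test_pairs_tsv_roundtrip(self, tmp_path):
        pairs = generate_synthetic_pairs(8, 4, seed=3)
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv(path, pairs)
        assert read_pairs_tsv(path) == pairs

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("target\tgrna\tlabel\n" + "A" * 22 + "\t" + "A" * 23 + "\t0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_pairs_tsv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("target\tlabel\nAAA\t0\n")
        with pytest.raises(ValueError, match="grna"):
            read_pairs_tsv(path)
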