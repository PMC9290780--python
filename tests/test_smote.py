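import numpy as np
import pytest
from PIL import Image

from helpers import brute_force_knn
from srasnet.manifest import DatasetManifest, ManifestRecord
from srasnet.smote import (MinoritySet, SmoteConfig, balance_dataset,
                           k_nearest_minority, sampling_magnification,
                           smote_oversample, synthesize)


class TestKNearest:
    def test_nearest_on_a_line(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        ms = MinoritySet(pts, class_id=0, K=1)
        assert k_nearest_minority(ms, 0) == [1]

    def test_exhaustion_returns_both_others(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        ms = MinoritySet(pts, class_id=0, K=2)
        assert sorted(k_nearest_minority(ms, 0)) == [1, 2]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 8))
        ms = MinoritySet(pts, class_id=23, K=5)
        for i in range(50):
            assert k_nearest_minority(ms, i) == brute_force_knn(pts, i, 5)

    def test_matches_oracle_on_200_samples(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(200, 4))
        ms = MinoritySet(pts, class_id=0, K=7)
        for i in range(0, 200, 13):
            assert k_nearest_minority(ms, i) == brute_force_knn(pts, i, 7)

    def test_ties_broken_by_lower_index(self):
        pts = np.array([[0.0], [2.0], [-2.0], [2.0]])
        ms = MinoritySet(pts, class_id=0, K=2)
        # indices 1, 2, 3 all at distance 2 from index 0
        assert k_nearest_minority(ms, 0) == [1, 2]

    def test_k_too_large_rejected(self):
        ms = MinoritySet(np.zeros((3, 2)), class_id=0, K=3)
        with pytest.raises(ValueError):
            k_nearest_minority(ms, 0)


class TestMagnification:
    @pytest.mark.parametrize("maj,mino,expected", [
        (100, 100, 0),
        (100, 25, 3),
        (238, 45, 4),   # the reference-set majority/Y-chromosome ratio
        (238, 193, 0),  # (238-193)/193 = 0.23 rounds to 0
        (50, 100, 0),
    ])
    def test_values(self, maj, mino, expected):
        assert sampling_magnification(maj, mino) == expected

    def test_zero_minority_rejected(self):
        with pytest.raises(ValueError):
            sampling_magnification(10, 0)


class TestOversample:
    def test_interpolation_endpoints(self):
        x = np.array([1.0, 2.0])
        nb = np.array([3.0, 6.0])
        assert np.array_equal(synthesize(x, nb, 0.0), x)
        assert np.array_equal(synthesize(x, nb, 1.0), nb)

    def test_synthetic_points_collinear_and_between(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2)) * 5
        ms = MinoritySet(pts, class_id=0, K=1)
        synth = smote_oversample(ms, SmoteConfig(K=1, rng_seed=3), eta=1)
        assert len(synth) == 10
        for i, s in enumerate(synth):
            nb = pts[brute_force_knn(pts, i, 1)[0]]
            v1, v2 = s - pts[i], nb - pts[i]
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            assert abs(cross) < 1e-9
            t = np.dot(v1, v2) / np.dot(v2, v2)
            assert -1e-12 <= t <= 1 + 1e-12

    def test_convex_hull_componentwise(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(size=(12, 6))
        ms = MinoritySet(pts, class_id=23, K=3)
        synth = smote_oversample(ms, SmoteConfig(K=3, rng_seed=1), eta=2)
        lo, hi = pts.min(axis=0) - 1e-12, pts.max(axis=0) + 1e-12
        assert ((synth >= lo) & (synth <= hi)).all()

    def test_deterministic_and_seed_sensitive(self):
        pts = np.arange(20, dtype=float).reshape(10, 2)
        ms = MinoritySet(pts, class_id=0, K=2)
        a = smote_oversample(ms, SmoteConfig(K=2, rng_seed=4), eta=2)
        b = smote_oversample(ms, SmoteConfig(K=2, rng_seed=4), eta=2)
        c = smote_oversample(ms, SmoteConfig(K=2, rng_seed=5), eta=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_eta_above_k_falls_back_with_warning(self, caplog):
        pts = np.arange(8, dtype=float).reshape(4, 2)
        ms = MinoritySet(pts, class_id=0, K=1)
        with caplog.at_level("WARNING", logger="srasnet.smote"):
            synth = smote_oversample(ms, SmoteConfig(K=1, rng_seed=0), eta=3)
        assert len(synth) == 12
        assert any("replacement" in r.message for r in caplog.records)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            MinoritySet(np.zeros((1, 4)), class_id=0)


def _write_image_set(tmp_path, counts, size=12):
    """Tiny standardized image set with the given per-class train counts
    plus 2 test images per class."""
    rng = np.random.default_rng(0)
    records = []
    for cls, n in counts.items():
        for k in range(n):
            img = rng.integers(0, 255, (size, size)).astype(np.uint8)
            p = tmp_path / f"c{cls}_{k}.png"
            Image.fromarray(img, mode="L").save(p)
            records.append(ManifestRecord(str(p), cls, "train"))
        for k in range(2):
            img = rng.integers(0, 255, (size, size)).astype(np.uint8)
            p = tmp_path / f"c{cls}_test{k}.png"
            Image.fromarray(img, mode="L").save(p)
            records.append(ManifestRecord(str(p), cls, "test"))
    return DatasetManifest(records)


class TestBalance:
    def test_counts_match_majority_exactly(self, tmp_path):
        manifest = _write_image_set(
            tmp_path, {5: 40, 7: 40, 0: 8, 23: 20})
        out = balance_dataset(manifest, SmoteConfig(K=3, rng_seed=1),
                              tmp_path / "bal")
        counts = out.class_counts("train")
        assert counts[0] == 40 and counts[23] == 40
        assert counts[5] == 40 and counts[7] == 40

    def test_majority_and_test_split_untouched(self, tmp_path):
        manifest = _write_image_set(tmp_path, {5: 30, 0: 6, 23: 10})
        out = balance_dataset(manifest, SmoteConfig(K=3, rng_seed=1),
                              tmp_path / "bal")
        assert out.class_counts("test") == manifest.class_counts("test")
        before = {r.path for r in manifest.records if r.label == 5}
        after = {r.path for r in out.records if r.label == 5}
        assert before == after

    def test_already_balanced_returned_unchanged(self, tmp_path):
        manifest = _write_image_set(tmp_path, {5: 10, 0: 10, 23: 10})
        out = balance_dataset(manifest, SmoteConfig(K=3, rng_seed=1),
                              tmp_path / "bal")
        assert out == manifest

    def test_synthetic_images_marked_and_in_range(self, tmp_path):
        manifest = _write_image_set(tmp_path, {5: 20, 0: 4, 23: 6})
        out = balance_dataset(manifest, SmoteConfig(K=3, rng_seed=1),
                              tmp_path / "bal")
        new = [r for r in out.records if r not in manifest.records]
        assert new and all("_smote_" in r.path for r in new)
        for r in new:
            img = np.asarray(Image.open(r.path))
            assert img.shape == (12, 12)
            assert r.split == "train"

    def test_minority_with_one_sample_rejected(self, tmp_path):
        manifest = _write_image_set(tmp_path, {5: 10, 0: 1, 23: 5})
        with pytest.raises(ValueError):
            balance_dataset(manifest, SmoteConfig(K=3, rng_seed=1),
                            tmp_path / "bal")
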