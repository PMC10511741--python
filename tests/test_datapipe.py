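"""Split arithmetic and the three augmentation transforms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermonet import datapipe as dp
from thermonet import synthgen as sg


def _manifest(n_per_class, images_per_subject=1):
    rows = []
    sid = 0
    for label in ("normal", "RA"):
        for _ in range(n_per_class // images_per_subject):
            for i in range(images_per_subject):
                rows.append(
                    {"path": f"{label}_{sid}_{i}.png", "label": label,
                     "subject_id": sid, "hand": "left", "view": "dorsal",
                     "split": "unassigned"}
                )
            sid += 1
    return pd.DataFrame(rows, columns=sg.MANIFEST_COLUMNS)


class TestSplits:
    def test_study_arithmetic_600_to_480_120(self):
        m = _manifest(300, images_per_subject=6)
        train, test = dp.split_train_test(m, dp.SplitConfig(seed=4))
        assert (len(train), len(test)) == (480, 120)
        assert train["label"].value_counts().to_dict() == {"normal": 240, "RA": 240}
        assert test["label"].value_counts().to_dict() == {"normal": 60, "RA": 60}
        # subject grouping: no subject straddles the split
        assert not set(train["subject_id"]) & set(test["subject_id"])

    def test_augmented_70_30_is_1008_432(self):
        m = _manifest(720, images_per_subject=18)
        train, val = dp.split_train_val(m, dp.SplitConfig(seed=0))
        assert (len(train), len(val)) == (1008, 432)
        assert train["label"].value_counts().to_dict() == {"normal": 504, "RA": 504}

    def test_empty_manifest_splits_to_empty(self):
        m = _manifest(0)
        train, test = dp.split_train_test(m)
        assert len(train) == 0 and len(test) == 0

    @pytest.mark.parametrize("fraction,expected", [(0.2, (8, 2)), (0.3, (7, 3))])
    def test_ten_record_rounding_verified_exhaustively(self, fraction, expected):
        """5/5 labels: enumerate every stratified assignment consistent with
        per-class counts off the exact fraction by < 1 and check membership."""
        labels = np.array([0] * 5 + [1] * 5)
        large, small = dp.split_indices(labels, fraction, seed=3)
        assert (len(large), len(small)) == expected
        per_class = [np.isin(small, np.flatnonzero(labels == c)).sum() for c in (0, 1)]
        # admissible per-class small-side counts: |k - 5*fraction| < 1
        admissible = [
            (a, b)
            for a, b in itertools.product(range(6), repeat=2)
            if a + b == len(small)
            and abs(a - 5 * fraction) < 1
            and abs(b - 5 * fraction) < 1
        ]
        assert tuple(per_class) in admissible

    @given(
        n0=st.integers(0, 40), n1=st.integers(0, 40),
        frac=st.sampled_from([0.2, 0.25, 0.3]), seed=st.integers(0, 5),
    )
    def test_partition_property(self, n0, n1, frac, seed):
        """Train and test always partition the input, stratified within < 1."""
        labels = np.array([0] * n0 + [1] * n1)
        large, small = dp.split_indices(labels, frac, seed=seed)
        assert len(large) + len(small) == n0 + n1
        assert len(np.intersect1d(large, small)) == 0
        for c, n_c in ((0, n0), (1, n1)):
            got = np.isin(small, np.flatnonzero(labels == c)).sum()
            assert abs(got - n_c * frac) < 1

    def test_fraction_bounds_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            dp.SplitConfig(test_fraction=1.2).validate()

    def test_determinism(self):
        m = _manifest(30, images_per_subject=3)
        a = dp.split_train_test(m, dp.SplitConfig(seed=7))
        b = dp.split_train_test(m, dp.SplitConfig(seed=7))
        assert a[0]["path"].tolist() == b[0]["path"].tolist()


class TestElasticDeform:
    def test_zero_alpha_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16, 3))
        out = dp.elastic_deform(img, elastic_sigma=2, elastic_alpha=0, seed=1)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_constant_field_unchanged(self):
        img = np.full((20, 20, 3), 0.37)
        out = dp.elastic_deform(img, 2, 6, seed=2)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_matches_dense_resampling_matrix_oracle(self):
        """Rebuild the warp as an explicit (HW x HW) bilinear resampling
        matrix from the same displacement field; outputs must agree and every
        row must sum to 1 (bilinear weights are a partition of unity).  Total
        intensity of a smooth blob is conserved within a few percent — the
        pointwise Jacobian of the smoothed field fluctuates, so exact
        conservation holds only for constant images."""
        h = w = 24
        sigma, alpha, seed = 2.0, 4.0, 5
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        dy = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
        dx = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
        M = np.zeros((h * w, h * w))
        for r in range(h):
            for c in range(w):
                sr = min(max(r + dy[r, c], 0), h - 1)
                sc = min(max(c + dx[r, c], 0), w - 1)
                r0, c0 = int(np.floor(sr)), int(np.floor(sc))
                r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
                fr, fc = sr - r0, sc - c0
                for rr, wr in ((r0, 1 - fr), (r1, fr)):
                    for cc, wc in ((c0, 1 - fc), (c1, fc)):
                        M[r * w + c, rr * w + cc] += wr * wc
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

        img = np.zeros((h, w))
        img[h // 2, w // 2] = 1.0
        out = dp.elastic_deform(img, sigma, alpha, seed)
        oracle = (M @ img.ravel()).reshape(h, w)
        np.testing.assert_allclose(out, oracle, atol=1e-10)

        yy, xx = np.mgrid[:h, :w]
        blob = np.exp(-(((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / (2 * 5**2)))
        warped = dp.elastic_deform(blob, sigma, alpha, seed)
        assert abs(warped.sum() / blob.sum() - 1.0) < 0.05

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            dp.elastic_deform(np.zeros((8, 8)), elastic_sigma=0, elastic_alpha=1)


class TestBrightnessZoom:
    def test_brightness_scalar_multiplication_and_clipping(self):
        img = np.full((8, 8, 3), 0.5)
        np.testing.assert_allclose(dp.adjust_brightness(img, 1.0), img)
        np.testing.assert_allclose(dp.adjust_brightness(img, 1.1), 0.55)
        np.testing.assert_allclose(
            dp.adjust_brightness(np.full((8, 8, 3), 0.95), 1.1), 1.0
        )
        with pytest.raises(ValueError):
            dp.adjust_brightness(img, 0.0)

    def test_zoom_identity_and_constant(self):
        img = np.random.default_rng(1).uniform(0, 1, (16, 16, 3))
        np.testing.assert_allclose(dp.scale_zoom(img, 1.0), img)
        const = np.full((17, 17), 0.42)
        for f in (0.9, 1.1):
            np.testing.assert_allclose(dp.scale_zoom(const, f), const, atol=1e-12)
        with pytest.raises(ValueError):
            dp.scale_zoom(img, 2.5)

    def test_zoom_scales_disk_radius(self):
        """Area-count oracle: a centred disk zoomed by 1.1 has its half-max
        radius scaled by 1.1 within one pixel."""
        size, r = 101, 20
        yy, xx = np.mgrid[:size, :size] - size // 2
        img = (np.hypot(yy, xx) <= r).astype(float)
        out = dp.scale_zoom(img, 1.1)
        r_fit = np.sqrt((out > 0.5).sum() / np.pi)
        assert abs(r_fit - 1.1 * r) <= 1.0

    def test_transforms_preserve_shape_and_range(self):
        img = np.random.default_rng(3).uniform(0, 1, (21, 21, 3))
        for out in (
            dp.elastic_deform(img, 2, 8, seed=0),
            dp.adjust_brightness(img, 1.09),
            dp.scale_zoom(img, 0.92),
        ):
            assert out.shape == img.shape
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestAugmentation:
    def test_triples_cardinality_and_inherits_labels(self):
        X = np.random.default_rng(0).uniform(0, 1, (4, 12, 12, 3))
        Xa, src = dp.augment_arrays(X, dp.AugmentConfig(seed=2))
        assert Xa.shape == (12, 12, 12, 3)
        assert src.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_empty_input(self):
        Xa, src = dp.augment_arrays(np.zeros((0, 8, 8, 3)))
        assert len(Xa) == 0 and len(src) == 0

    def test_file_based_augmentation_writes_three_suffixed_pngs(self, tmp_path):
        cfg = sg.GeneratorConfig(1, 24, 0.3, 0.0, seed=1)
        manifest = sg.generate_dataset(cfg, str(tmp_path / "src"))
        aug = dp.augment_training_set(manifest, str(tmp_path / "aug"))
        assert len(aug) == 3 * len(manifest)
        stems = [p.rsplit("_", 1)[-1].replace(".png", "") for p in aug["path"]]
        assert set(stems) == {"el", "br", "sc"}
        assert aug["label"].tolist() == np.repeat(manifest["label"].to_numpy(), 3).tolist()

    def test_augmentation_deterministic_bytes(self, tmp_path):
        cfg = sg.GeneratorConfig(1, 24, 0.3, 0.02, seed=1)
        manifest = sg.generate_dataset(cfg, str(tmp_path / "src"))
        a = dp.augment_training_set(manifest, str(tmp_path / "a"), dp.AugmentConfig(seed=5))
        b = dp.augment_training_set(manifest, str(tmp_path / "b"), dp.AugmentConfig(seed=5))
        for p1, p2 in zip(a["path"], b["path"]):
            with open(p1, "rb") as f1, open(p2, "rb") as f2:
                assert f1.read() == f2.read()
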