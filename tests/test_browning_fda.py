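"""Browning-score tests: FDA eigenstructure, anchoring, limits, classification."""

import numpy as np
import pytest

import bakevision as bv
from bakevision.browning_fda import consensus_class


def two_gaussian_groups(rng, mu1, mu2, n=400, cov=None):
    p = len(mu1)
    cov = np.eye(p) if cov is None else cov
    x1 = rng.multivariate_normal(mu1, cov, size=n)
    x2 = rng.multivariate_normal(mu2, cov, size=n)
    pixels = np.vstack([x1, x2])
    groups = np.array(["a"] * n + ["b"] * n, dtype=object)
    return pixels, groups


class TestConsensus:
    def test_majority(self):
        assert consensus_class(4, 1, 1) == "underbaked"
        assert consensus_class(0, 1, 5) == "overbaked"

    def test_tie_breaks_toward_adequate(self):
        assert consensus_class(3, 3, 0) == "adequately_baked"
        assert consensus_class(3, 0, 3) == "adequately_baked"  # paper saw no such conflict


class TestBuildPixelDataset:
    def test_row_conservation(self, set1_fast, masks1_fast):
        labels = ["underbaked"] * 10 + ["adequately_baked"] * 10 + ["overbaked"] * 10
        pixels, groups = bv.build_pixel_dataset(set1_fast.images, masks1_fast, labels)
        assert pixels.shape[0] == sum(m.sum() for m in masks1_fast)
        assert pixels.shape[0] == len(groups)
        assert set(groups) == set(bv.CLASS_LABELS)

    def test_empty_mask_warns_and_contributes_nothing(self, set1_fast, masks1_fast):
        masks = list(masks1_fast)
        masks[0] = np.zeros_like(masks[0])
        labels = ["underbaked"] * 10 + ["adequately_baked"] * 10 + ["overbaked"] * 10
        with pytest.warns(UserWarning, match="empty mask"):
            pixels, _ = bv.build_pixel_dataset(set1_fast.images, masks, labels)
        assert pixels.shape[0] == sum(m.sum() for m in masks)

    def test_missing_class_rejected(self, set1_fast, masks1_fast):
        labels = ["underbaked"] * 15 + ["adequately_baked"] * 15
        with pytest.raises(ValueError, match="overbaked"):
            bv.build_pixel_dataset(set1_fast.images, masks1_fast, labels)


class TestFitFDA:
    def test_two_class_closed_form_oracle(self):
        """First loading collinear with S_W^-1 (mu1 - mu2), the classic LDA direction."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            p = rng.integers(3, 8)
            A = rng.normal(size=(p, p))
            cov = A @ A.T + p * np.eye(p)
            mu1 = rng.normal(size=p)
            mu2 = mu1 + rng.normal(size=p)
            pixels, groups = two_gaussian_groups(rng, mu1, mu2, n=300, cov=cov)
            model = bv.fit_fda(pixels, groups, ridge=0.0)
            # empirical within-scatter and mean difference define the oracle
            m1 = pixels[groups == "a"].mean(axis=0)
            m2 = pixels[groups == "b"].mean(axis=0)
            direction = np.linalg.solve(model.within_scatter, m1 - m2)
            direction /= np.linalg.norm(direction)
            dot = abs(float(direction @ model.loadings[0]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_identity_covariance_gives_mean_difference(self):
        rng = np.random.default_rng(1)
        mu1, mu2 = np.array([0.0, 0.0]), np.array([3.0, 1.0])
        pixels, groups = two_gaussian_groups(rng, mu1, mu2, n=20000)
        model = bv.fit_fda(pixels, groups, ridge=0.0)
        direction = (mu1 - mu2) / np.linalg.norm(mu1 - mu2)
        assert abs(float(direction @ model.loadings[0])) == pytest.approx(1.0, abs=5e-2)

    def test_identical_means_no_separation(self):
        rng = np.random.default_rng(2)
        mu = np.array([1.0, 2.0, 3.0])
        pixels, groups = two_gaussian_groups(rng, mu, mu, n=500)
        pixels[len(pixels) // 2:] = pixels[: len(pixels) // 2]  # exactly equal groups
        with pytest.raises(ValueError, match="no separation"):
            bv.fit_fda(pixels, groups, ridge=1e-9)

    def test_singular_within_scatter_advises_ridge(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(200, 1))
        pixels = np.hstack([base, base, base])  # rank-1 within-scatter
        groups = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        pixels[groups == "b"] += 1.0
        with pytest.raises(ValueError, match="ridge"):
            bv.fit_fda(pixels, groups, ridge=0.0)

    def test_between_scatter_rank_bounded_by_groups(self, set1_fast, masks1_fast, fda_fast):
        model, _ = fda_fast
        rank = np.linalg.matrix_rank(model.between_scatter, tol=1e-8)
        assert rank <= 2  # n_groups - 1

    def test_duplicating_data_preserves_loadings(self):
        rng = np.random.default_rng(4)
        pixels, groups = two_gaussian_groups(
            rng, np.array([0.0, 0.0, 0.0]), np.array([1.0, 2.0, 0.5]), n=200
        )
        m1 = bv.fit_fda(pixels, groups, ridge=0.0)
        m2 = bv.fit_fda(
            np.vstack([pixels, pixels]), np.concatenate([groups, groups]), ridge=0.0
        )
        assert abs(float(m1.loadings[0] @ m2.loadings[0])) == pytest.approx(1.0, abs=1e-8)

    def test_loading_peak_at_395nm_on_synthetic_set1(self, fda_fast, set1_fast):
        model, _ = fda_fast
        lam = set1_fast.images[0].wavelengths_nm
        assert lam[int(np.argmax(np.abs(model.loadings[0])))] == 395.0


class TestScoring:
    def test_underbaked_class_mean_anchored_to_zero(self, fda_fast):
        model, _ = fda_fast
        assert model.class_mean_scores["underbaked"] == pytest.approx(0.0, abs=1e-12)
        assert max(model.class_mean_scores.values()) == pytest.approx(0.0, abs=1e-12)

    def test_browner_spectrum_scores_lower(self, fda_fast, set1_fast, masks1_fast):
        model, df = fda_fast
        i4 = df.index[df.time_min == 4][0]
        i16 = df.index[df.time_min == 16][0]
        s4 = bv.mean_browning_score(
            bv.score_pixels(set1_fast.images[i4], masks1_fast[i4], model), masks1_fast[i4]
        )
        s16 = bv.mean_browning_score(
            bv.score_pixels(set1_fast.images[i16], masks1_fast[i16], model), masks1_fast[i16]
        )
        assert s16 < s4

    def test_wavelength_grid_mismatch_rejected(self, fda_fast):
        model, _ = fda_fast
        img = bv.SpectralImage(
            cube=np.zeros((4, 4, 3)), wavelengths_nm=[400, 500, 600]
        )
        with pytest.raises(ValueError, match="wavelength"):
            bv.score_pixels(img, np.ones((4, 4), bool), model)

    def test_mean_score_examples(self):
        score = np.array([[0.0, -2.0], [0.0, -2.0]])
        mask = np.ones((2, 2), bool)
        assert bv.mean_browning_score(score, mask) == pytest.approx(-1.0)
        assert bv.mean_browning_score(np.full((3, 3), 0.7), np.ones((3, 3), bool)) == pytest.approx(0.7)
        with pytest.raises(ValueError, match="empty"):
            bv.mean_browning_score(score, np.zeros((2, 2), bool))

    def test_mean_scores_strictly_decrease_with_time_noise_free(self, fda_fast):
        cfg = bv.SimulationConfig(image_size=(64, 64), cookie_radius_px=24, noise_sd=0.0)
        ds = bv.generate_set("set1", cfg, seed=13)
        model, _ = fda_fast
        masks = [bv.segment(img) for img in ds.images]
        scores = [
            bv.mean_browning_score(bv.score_pixels(img, m, model), m)
            for img, m in zip(ds.images, masks)
        ]
        means = ds.records.assign(s=scores).groupby("time_min")["s"].mean().values
        assert (np.diff(means) < 0).all()


class TestLimitsAndClassification:
    def test_limits_are_midpoints(self):
        limits = bv.compute_class_limits({4: -1.0, 6: -3.0, 10: -6.0, 12: -8.0})
        assert limits == (pytest.approx(-2.0), pytest.approx(-7.0))

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="12"):
            bv.compute_class_limits({4: -1.0, 6: -3.0, 10: -6.0})

    def test_limits_ordered_on_synthetic_set1(self, fda_fast):
        model, _ = fda_fast
        assert model.limit_under_adequate > model.limit_adequate_over

    def test_cookie_classification_with_tie_to_browner_class(self):
        limits = (-2.0, -7.0)
        assert bv.classify_cookie(-1.0, limits) == "underbaked"
        assert bv.classify_cookie(-2.0, limits) == "adequately_baked"  # tie rule
        assert bv.classify_cookie(-7.0, limits) == "overbaked"
        assert bv.classify_cookie(-9.0, limits) == "overbaked"

    def test_six_to_ten_minutes_adequately_baked(self, fda_fast):
        _, df = fda_fast
        model, _ = fda_fast
        limits = (model.limit_under_adequate, model.limit_adequate_over)
        for r in df.itertuples():
            if 6 <= r.time_min <= 10:
                assert bv.classify_cookie(r.mean_score, limits) == "adequately_baked"
            elif r.time_min == 4:
                assert bv.classify_cookie(r.mean_score, limits) == "underbaked"
            elif r.time_min >= 12:
                assert bv.classify_cookie(r.mean_score, limits) == "overbaked"


class TestPixelClassification:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            bv.classify_pixels(np.zeros((4, 4)), np.ones((4, 4), bool), (-2.0, -7.0), -1.0)

    def test_uniform_score_above_upper_limit_all_underbaked(self):
        labels = bv.classify_pixels(
            np.zeros((6, 6)), np.ones((6, 6), bool), (-2.0, -7.0), gaussian_sigma=0.0
        )
        assert (labels == 0).all()

    def test_smoothing_removes_single_pixel_islands(self):
        rng = np.random.default_rng(0)
        score = np.full((32, 32), -4.0)  # adequately baked plateau
        mask = np.ones((32, 32), bool)
        isolated = rng.choice(32 * 32, size=20, replace=False)
        score.ravel()[isolated] = -20.0  # overbaked speckles
        raw = bv.classify_pixels(score, mask, (-2.0, -7.0), gaussian_sigma=0.0)
        smoothed = bv.classify_pixels(score, mask, (-2.0, -7.0), gaussian_sigma=1.5)
        assert (raw == 2).sum() == 20
        assert (smoothed == 2).sum() == 0
        assert (smoothed == 1).all()

    def test_background_never_bleeds_into_surface(self):
        # masked smoothing must ignore background zeros entirely
        score = np.full((16, 16), -4.0)
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        labels = bv.classify_pixels(score, mask, (-2.0, -7.0), gaussian_sigma=3.0)
        assert (labels[mask] == 1).all()
        assert (labels[~mask] == -1).all()

    def test_underbaked_areas_only_in_four_minute_cookies(self, fda_fast, set1_fast, masks1_fast):
        model, df = fda_fast
        limits = (model.limit_under_adequate, model.limit_adequate_over)
        for r in df.itertuples():
            lab = bv.classify_pixels(
                bv.score_pixels(set1_fast.images[r.Index], masks1_fast[r.Index], model),
                masks1_fast[r.Index], limits, gaussian_sigma=1.0,
            )
            if r.time_min == 4:
                assert (lab == 0).any()
            else:
                assert not (lab == 0).any()


def test_model_json_roundtrip(tmp_path, fda_fast):
    model, _ = fda_fast
    model.to_json(tmp_path / "fda.json")
    back = bv.FDAModel.from_json(tmp_path / "fda.json")
    assert np.allclose(back.loadings, model.loadings)
    assert back.score_offset == pytest.approx(model.score_offset)
    assert back.limit_under_adequate == pytest.approx(model.limit_under_adequate)
    assert np.array_equal(back.wavelengths_nm, model.wavelengths_nm)
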