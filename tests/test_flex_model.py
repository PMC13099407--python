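import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdvflex.errors import DegenerateInputError, DomainError, ParameterError
from gdvflex.fixtures import synth_flex_dataset
from gdvflex.flex_model import (
    ModelCoefficients,
    RMSFProfile,
    TrainingSet,
    cross_validate,
    fit,
    load_model,
    predict,
    published_model,
    save_model,
    transform_features,
    transform_target,
)


class TestPublishedModel:
    def test_coefficients(self):
        m = published_model()
        assert len(m.betas) == 15
        assert m.intercept == 0.0
        assert m.betas[0] == pytest.approx(-1.91)
        assert m.betas[2] == pytest.approx(2.98)
        assert m.betas[14] == pytest.approx(-1.48)

    def test_serialization_round_trip(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(published_model(), path)
        doc = json.loads(path.read_text())
        assert doc["orbit_order"] == "O0..O14"
        assert doc["transform"]["sd"] == "sample"
        assert load_model(path) == published_model()

    def test_wrong_beta_count_rejected(self):
        with pytest.raises(ParameterError):
            ModelCoefficients(intercept=0.0, betas=(1.0,) * 14)


class TestTransforms:
    def test_constant_column_maps_to_zeros(self):
        gdv = np.tile([3, 0, 7] + [1] * 12, (5, 1))
        assert np.array_equal(transform_features(gdv), np.zeros((5, 15)))

    def test_two_point_standardization(self):
        gdv = np.zeros((2, 15), dtype=int)
        gdv[1, 0] = 2  # any distinct pair standardizes to ±1/sqrt(2)
        feats = transform_features(gdv)
        assert feats[0, 0] == pytest.approx(-np.sqrt(0.5))
        assert feats[1, 0] == pytest.approx(+np.sqrt(0.5))

    def test_matches_direct_formula(self, rng):
        gdv = rng.integers(0, 40, size=(30, 15))
        gdv[:, 4] = 9  # one degenerate column
        feats = transform_features(gdv)
        logs = np.log1p(gdv.astype(float))
        for k in range(15):
            col = logs[:, k]
            if col.std(ddof=1) == 0:
                assert np.array_equal(feats[:, k], np.zeros(30))
            else:
                expected = (col - col.mean()) / col.std(ddof=1)
                assert np.allclose(feats[:, k], expected, atol=1e-12)
        assert np.abs(feats.mean(axis=0)).max() < 1e-9

    def test_single_row_rejected(self):
        with pytest.raises(DegenerateInputError):
            transform_features(np.ones((1, 15)))

    def test_target_two_point(self):
        z = transform_target(RMSFProfile(np.array([1.0, np.e]), kind="raw"))
        assert z == pytest.approx([-np.sqrt(0.5), +np.sqrt(0.5)])

    def test_target_constant_is_zero(self):
        assert np.array_equal(transform_target(np.full(4, 2.5)), np.zeros(4))

    def test_target_formula(self, rng):
        vals = rng.lognormal(0.0, 0.7, size=50)
        logs = np.log(vals)
        expected = (logs - logs.mean()) / logs.std(ddof=1)
        assert np.allclose(transform_target(vals), expected, atol=1e-12)

    def test_target_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            transform_target(np.array([1.0, 0.0, 2.0]))


class TestPredict:
    def test_zero_features_give_intercept(self):
        out = predict(np.zeros((3, 15)), published_model())
        assert np.array_equal(out.values, np.zeros(3))
        assert out.kind == "normalized"

    def test_unit_orbit2_feature(self):
        feats = np.zeros((1, 15))
        feats[0, 2] = 1.0
        assert predict(feats, published_model()).values[0] == pytest.approx(2.98)

    def test_matches_manual_dot_product(self, rng):
        feats = rng.normal(size=(50, 15))
        m = published_model()
        expected = feats @ np.array(m.betas)
        assert np.allclose(predict(feats, m).values, expected, atol=1e-12)

    def test_linearity(self, rng):
        m = published_model()  # intercept 0
        f1, f2 = rng.normal(size=(2, 20, 15))
        combo = predict(2.0 * f1 - 3.0 * f2, m).values
        assert np.allclose(combo, 2.0 * predict(f1, m).values - 3.0 * predict(f2, m).values)

    def test_width_mismatch(self):
        with pytest.raises(ParameterError):
            predict(np.zeros((3, 14)), published_model())


class TestFit:
    def test_noiseless_recovery(self):
        train = synth_flex_dataset(n_proteins=6, noise_sd=0.0, seed=3, n_res=60)
        m = fit(train)
        assert np.allclose(m.beta_array, published_model().beta_array, atol=1e-8)
        assert m.intercept == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations(self):
        train = synth_flex_dataset(n_proteins=4, noise_sd=0.3, seed=9, n_res=50)
        from gdvflex.flex_model import _pooled_design

        x, y = _pooled_design(train.proteins)
        design = np.column_stack([np.ones(len(x)), x])
        expected = np.linalg.solve(design.T @ design, design.T @ y)
        m = fit(train)
        assert np.allclose([m.intercept, *m.betas], expected, atol=1e-8)

    def test_rank_deficient_warns(self):
        train = synth_flex_dataset(n_proteins=2, noise_sd=0.0, seed=1, n_res=40)
        for p in train.proteins:
            p.gdv = p.gdv.copy()
            p.gdv[:, 14] = 0  # no 4-cliques anywhere -> zero-variance column
            p.gdv[:, 13] = 0
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit(train)

    def test_raw_reference_recovered_up_to_positive_scale(self):
        """The log/z target transform rescales each protein's coefficients by
        a positive factor, so raw-reference fits recover the direction."""
        train = synth_flex_dataset(
            n_proteins=6, noise_sd=0.0, seed=3, n_res=60, reference_kind="raw"
        )
        m = fit(train)
        b, bt = m.beta_array, published_model().beta_array
        cosine = b @ bt / (np.linalg.norm(b) * np.linalg.norm(bt))
        # per-protein rescaling perturbs the direction slightly, never the sign
        assert cosine > 0.99


class TestCrossValidate:
    def test_self_consistent_reference_scores_one(self):
        train = synth_flex_dataset(n_proteins=10, noise_sd=0.0, seed=2, n_res=40)
        cv = cross_validate(train, k=10, seed=0)
        assert np.allclose(cv.rhos, 1.0)

    def test_negated_reference_scores_minus_one(self):
        from gdvflex.evaluation import spearman_ca

        train = synth_flex_dataset(n_proteins=10, noise_sd=0.0, seed=2, n_res=40)
        model = fit(train)
        for p in train.proteins:
            pred = predict(transform_features(p.gdv), model)
            rho = spearman_ca(pred.values, -p.reference.values, p.ca_mask)
            assert rho == pytest.approx(-1.0)

    def test_folds_partition_proteins(self):
        train = synth_flex_dataset(n_proteins=17, noise_sd=0.2, seed=4, n_res=40)
        cv = cross_validate(train, k=5, seed=11)
        ids = [pid for fold in cv.folds for pid in fold]
        assert sorted(ids) == sorted(p.protein_id for p in train.proteins)

    def test_noise_monotonicity(self):
        means = []
        for noise in (0.1, 0.5):
            train = synth_flex_dataset(n_proteins=12, noise_sd=noise, seed=6, n_res=50)
            means.append(cross_validate(train, k=4, seed=0).mean_rho)
        assert means[0] > means[1]

    def test_too_few_proteins(self):
        train = synth_flex_dataset(n_proteins=3, noise_sd=0.1, seed=1, n_res=40)
        with pytest.raises(ParameterError):
            cross_validate(train, k=10, seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_prediction_rank_invariance_under_monotone_transform(seed):
    """Spearman-based evaluation cannot distinguish a prediction from any
    strictly increasing transform of it."""
    from scipy.stats import spearmanr

    r = np.random.default_rng(seed)
    pred = r.normal(size=40)
    ref = r.normal(size=40)
    rho = spearmanr(pred, ref).statistic
    rho_t = spearmanr(np.exp(2.0 * pred) + 5.0, ref).statistic
    assert rho == pytest.approx(rho_t, abs=1e-12)
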