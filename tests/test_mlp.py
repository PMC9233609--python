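"""Banded loss, its gradient, and training of the adult-height network."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from staturekit import (BandedMLPRegressor, band_loss, band_loss_gradient,
                        split_train_validation)


class TestBandLoss:
    @pytest.mark.parametrize("y,d,expected", [
        ([170.4], [170.0], 0.0),                 # inside the 0.5 cm band
        ([168.0], [170.0], 2.25),                # (2 - 0.5)^2
        ([169.0, 160.5], [170.0, 160.0], 0.125),  # (0.5^2 + 0)/2
    ])
    def test_hand_values(self, y, d, expected):
        assert band_loss(y, d, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_band_zero_is_mse(self, rng):
        for _ in range(5):
            y = rng.normal(160, 8, size=64)
            d = rng.normal(160, 8, size=64)
            assert band_loss(y, d, 0.0) == pytest.approx(
                np.mean((d - y) ** 2), abs=1e-12)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            band_loss([], [])
        with pytest.raises(ValueError):
            band_loss([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=20))
    def test_nonnegative_and_zero_iff_within_band(self, resid):
        d = np.zeros(len(resid))
        y = np.asarray(resid)
        loss = band_loss(y, d, 0.5)
        assert loss >= 0.0
        assert (loss == 0.0) == bool(np.all(np.abs(y) <= 0.5))


class TestBandLossGradient:
    def test_flat_inside_band(self):
        np.testing.assert_array_equal(
            band_loss_gradient([170.2], [170.0], 0.5), [0.0])

    def test_linear_outside_band(self):
        # residual +2.0, band 0.5, n=1 -> 2 * 1.5 = 3.0
        np.testing.assert_allclose(
            band_loss_gradient([172.0], [170.0], 0.5), [3.0])

    def test_matches_central_finite_differences(self, rng):
        y = rng.normal(160, 5, size=32)
        d = rng.normal(160, 5, size=32)
        # keep sample points away from the (measure-zero) band boundary
        y = np.where(np.abs(np.abs(y - d) - 0.5) < 1e-3, y + 0.01, y)
        grad = band_loss_gradient(y, d, 0.5)
        eps = 1e-6
        for i in range(0, 32, 5):
            e = np.zeros_like(y)
            e[i] = eps
            fd = (band_loss(y + e, d, 0.5) - band_loss(y - e, d, 0.5)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-6)

    def test_continuous_at_band_boundary(self):
        # squared hinge is C^1: gradient tends to 0 approaching the band
        g = band_loss_gradient([170.5 + 1e-9], [170.0], 0.5)
        assert abs(g[0]) < 1e-8


def _toy_batch(rng, n=64):
    X = rng.normal(size=(n, 6))
    w = np.array([1.5, -2.0, 0.5, 1.0, -0.5, 2.0])
    y = 160.0 + X @ w
    return X, y


class TestTraining:
    def test_loss_decreases(self, rng):
        X, y = _toy_batch(rng)
        m = BandedMLPRegressor(iterations=2000, learning_rate=5e-5,
                               random_state=0).fit(X, y)
        assert m.loss_ < m.loss_curve_[0][1]

    def test_deterministic_given_seed(self, rng):
        X, y = _toy_batch(rng)
        kw = dict(iterations=300, random_state=42)
        m1 = BandedMLPRegressor(**kw).fit(X, y)
        m2 = BandedMLPRegressor(**kw).fit(X, y)
        for a, b in zip(m1.coefs_, m2.coefs_):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(m1.intercepts_, m2.intercepts_):
            np.testing.assert_array_equal(a, b)

    def test_band_zero_training_matches_mse_reference(self):
        """With band=0 the whole trajectory equals plain MSE backprop.

        The reference implementation below is an independent, direct
        transcription of full-batch gradient descent on mean squared
        error for a 6-h-1 ReLU network with the same seeded init.
        """
        rng = np.random.default_rng(7)
        X = rng.normal(size=(32, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=32)
        lr, hidden, steps, seed = 1e-3, 10, 100, 3

        model = BandedMLPRegressor(hidden_units=hidden, learning_rate=lr,
                                   iterations=steps, band=0.0,
                                   random_state=seed, standardize=False,
                                   log_every=1).fit(X, y)

        r = np.random.default_rng(seed)
        W1 = r.uniform(-1, 1, size=(6, hidden)) * np.sqrt(6.0 / 6)
        b1 = np.zeros(hidden)
        W2 = r.uniform(-1, 1, size=(hidden, 1)) * np.sqrt(6.0 / hidden)
        b2 = 0.0
        ref_losses = []
        for _ in range(steps):
            Z = X @ W1 + b1
            H = np.maximum(Z, 0)
            pred = (H @ W2).ravel() + b2
            g = 2.0 / len(y) * (pred - y)
            gW2 = H.T @ g[:, None]
            gb2 = g.sum()
            back = (g[:, None] * W2.T) * (Z > 0)
            W1 = W1 - lr * (X.T @ back)
            b1 = b1 - lr * back.sum(axis=0)
            W2 = W2 - lr * gW2
            b2 = b2 - lr * gb2
            pred = (np.maximum(X @ W1 + b1, 0) @ W2).ravel() + b2
            ref_losses.append(np.mean((pred - y) ** 2))

        ours = [loss for it, loss in model.loss_curve_ if it >= 1]
        np.testing.assert_allclose(ours, ref_losses, atol=1e-6)

    def test_overfits_tiny_batch_within_band(self, rng):
        X = rng.normal(size=(4, 6))
        y = np.array([150.0, 160.0, 170.0, 155.0])
        m = BandedMLPRegressor(hidden_units=50, learning_rate=5e-4,
                               iterations=8000, random_state=1).fit(X, y)
        assert np.all(np.abs(m.predict(X) - y) <= 0.5 + 0.2)

    def test_rejects_bad_inputs(self, rng):
        X, y = _toy_batch(rng, n=8)
        with pytest.raises(ValueError, match="non-finite"):
            BandedMLPRegressor(iterations=1).fit(
                np.full_like(X, np.nan), y)
        with pytest.raises(ValueError):
            BandedMLPRegressor(iterations=1).fit(X[:1], y[:1])


class TestPredict:
    def test_zero_weight_model_returns_bias(self):
        m = BandedMLPRegressor.from_dict({
            "params": BandedMLPRegressor().get_params(),
            "W1": np.zeros((6, 100)).tolist(), "b1": np.zeros(100).tolist(),
            "W2": np.zeros((100, 1)).tolist(), "b2": [3.5],
            "feature_means": np.zeros(6).tolist(),
            "feature_scales": np.ones(6).tolist(),
            "target_mean": 0.0, "target_scale": 1.0, "loss": None})
        assert m.predict(np.ones(6)) == pytest.approx(3.5)

    def test_pure_function(self, rng):
        X, y = _toy_batch(rng, n=16)
        m = BandedMLPRegressor(iterations=50, random_state=0).fit(X, y)
        np.testing.assert_array_equal(m.predict(X), m.predict(X))

    def test_feature_permutation_equivalence(self, rng):
        X, y = _toy_batch(rng, n=32)
        m = BandedMLPRegressor(iterations=200, random_state=0).fit(X, y)
        perm = np.array([3, 1, 5, 0, 2, 4])
        m2 = m.permute_features(perm)
        np.testing.assert_allclose(m2.predict(X[:, perm]), m.predict(X),
                                   rtol=1e-12)

    def test_serialization_roundtrip(self, tmp_path, rng):
        X, y = _toy_batch(rng, n=16)
        m = BandedMLPRegressor(iterations=50, random_state=0).fit(X, y)
        m.save(tmp_path / "m.json")
        m2 = BandedMLPRegressor.load(tmp_path / "m.json")
        np.testing.assert_allclose(m2.predict(X), m.predict(X), rtol=1e-15)


class TestSplit:
    def test_three_to_one_sizes(self):
        train, val = split_train_validation(list(range(615)), 0.75, seed=0)
        assert (len(train), len(val)) == (462, 153)
        assert sorted(train + val) == list(range(615))

    def test_reproducible(self):
        recs = list("abcd")
        assert split_train_validation(recs, 0.5, seed=9) == \
            split_train_validation(recs, 0.5, seed=9)

    def test_dataframe_split(self):
        import pandas as pd
        df = pd.DataFrame({"x": range(100)})
        tr, va = split_train_validation(df, 0.75, seed=1)
        assert len(tr) == 75 and len(va) == 25
        assert sorted(list(tr["x"]) + list(va["x"])) == list(range(100))

    def test_rejects_bad_ratio(self):
        with pytest.raises(ValueError):
            split_train_validation([1, 2, 3], 1.5, seed=0)


class TestRecoveryOnSimulatedData:
    def test_heldout_mae_near_information_floor(self, male_curve,
                                                male_bmi_table):
        """Held-out adult-height MAE stays within 2x the floor achieved by
        an analytic predictor that knows the true generative model."""
        import staturekit as sk
        cfg = sk.SimulationConfig(n_subjects=400, sex="M", seed=21)
        subs = sk.simulate_cohort(cfg, male_curve, male_bmi_table)
        df = sk.cohort_frame(subs).sort_values(["subject_id", "age"])
        cur = df.groupby("subject_id").head(1)
        tr, va = split_train_validation(cur, 0.75, seed=2)
        fb = sk.FeatureBuilder(bmi_table=male_bmi_table).fit()
        m = BandedMLPRegressor(iterations=2000, random_state=4).fit(
            fb.transform(tr), tr["adult_height"].to_numpy())
        err = m.predict(fb.transform(va)) - va["adult_height"].to_numpy()

        # analytic oracle: invert the generator's own bone-age/BMI links
        coef = male_curve.coefficients_
        lo, hi = male_curve.age_min_, male_curve.age_max_
        age = va["age"].to_numpy()
        bmi_off = np.array([
            sk.compute_bmi(w, h) - male_bmi_table.standard_bmi(a)
            for w, h, a in zip(va["weight"], va["height"], age)])
        beta_hat = va["bone_age"].to_numpy() - age - cfg.bmi_bone_age_coupling * bmi_off
        gam = va["height"].to_numpy() - np.polyval(
            coef, np.clip(age + beta_hat, lo, hi))
        oracle = np.polyval(coef, np.clip(18 + beta_hat, lo, hi)) + gam
        floor = np.mean(np.abs(oracle - va["adult_height"].to_numpy()))
        assert np.mean(np.abs(err)) <= 2.0 * floor
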