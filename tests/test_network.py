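"""Scaling, forward pass, LM training and serialization of the 4-16-1 net."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import least_squares

import dessound as ds
from dessound.errors import DataFormatError, ValidityRangeError
from dessound.network import _lm_fit, _pack, _residuals_and_jacobian, split_dataset


def identity_scaler() -> ds.ScalerParams:
    """Maps [-1, 1] onto itself for every column: scaling is a no-op."""
    return ds.ScalerParams(
        x_min=-np.ones(4), x_max=np.ones(4), y_min=-1.0, y_max=1.0
    )


def make_model(w_ih, b_h, w_ho, b_o, scaler=None) -> ds.SoundSpeedModel:
    return ds.SoundSpeedModel(
        w_ih=np.asarray(w_ih, dtype=float),
        b_h=np.asarray(b_h, dtype=float),
        w_ho=np.asarray(w_ho, dtype=float),
        b_o=b_o,
        scaler=scaler or identity_scaler(),
    )


class TestScaler:
    def test_endpoints_and_midpoint(self, rng):
        X = rng.uniform(0, 10, size=(30, 4))
        y = rng.uniform(1000, 2000, size=30)
        sc = ds.ScalerParams.fit(X, y)
        assert sc.scale_x(sc.x_min) == pytest.approx(-np.ones(4))
        assert sc.scale_x(sc.x_max) == pytest.approx(np.ones(4))
        assert sc.scale_x((sc.x_min + sc.x_max) / 2) == pytest.approx(np.zeros(4))
        assert sc.scale_y(y.min()) == -1.0 and sc.scale_y(y.max()) == 1.0

    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, seed):
        r = np.random.default_rng(seed)
        X = r.uniform(-5, 5, size=(20, 4)) * r.uniform(0.1, 100, size=4)
        y = r.uniform(1166, 2138, size=20)
        sc = ds.ScalerParams.fit(X, y)
        assert np.allclose(sc.unscale_x(sc.scale_x(X)), X, rtol=0, atol=1e-12 * 100)
        assert np.allclose(sc.unscale_y(sc.scale_y(y)), y, rtol=1e-12)

    def test_constant_column_rejected(self, rng):
        X = rng.uniform(0, 1, size=(10, 4))
        X[:, 2] = 0.88
        with pytest.raises(ValidityRangeError, match="omega"):
            ds.ScalerParams.fit(X, rng.uniform(1, 2, size=10))


class TestTansig:
    def test_closed_form_values(self):
        assert ds.tansig(0.0) == 0.0
        assert ds.tansig(0.5) == pytest.approx(0.4621171572600098, rel=1e-12)
        assert ds.tansig(0.5) == pytest.approx(2 / (1 + math.exp(-1)) - 1, rel=1e-15)

    def test_saturation_and_oddness(self):
        assert ds.tansig(40.0) == pytest.approx(1.0)
        assert ds.tansig(-40.0) == pytest.approx(-1.0)
        z = np.linspace(-3, 3, 13)
        assert np.allclose(ds.tansig(-z), -ds.tansig(z))


class TestForward:
    def test_single_neuron_is_tanh(self):
        model = make_model(w_ih=[[1.0, 0, 0, 0]], b_h=[0.0], w_ho=[1.0], b_o=0.0)
        z = np.linspace(-0.9, 0.9, 7)
        X = np.column_stack([z, *([np.zeros_like(z)] * 3)])
        assert np.allclose(model.forward(X), np.tanh(z), rtol=1e-15)

    def test_zero_output_weights_constant(self, rng):
        model = make_model(
            w_ih=rng.normal(size=(16, 4)), b_h=rng.normal(size=16),
            w_ho=np.zeros(16), b_o=0.25,
        )
        X = rng.uniform(-1, 1, size=(10, 4))
        assert np.allclose(model.forward(X), 0.25)

    def test_independent_forward_pass_oracle(self, rng):
        """Vectorized forward vs a straight-line scalar re-implementation."""
        scaler = ds.ScalerParams(
            x_min=np.array([290.0, 100.0, 0.4, 50.0]),
            x_max=np.array([350.0, 700.0, 1.4, 200.0]),
            y_min=1166.0, y_max=2138.0,
        )
        model = make_model(
            w_ih=rng.normal(size=(16, 4)), b_h=rng.normal(size=16),
            w_ho=rng.normal(size=16), b_o=rng.normal(), scaler=scaler,
        )
        X = np.column_stack([
            rng.uniform(290, 350, 50), rng.uniform(100, 700, 50),
            rng.uniform(0.4, 1.4, 50), rng.uniform(50, 200, 50),
        ])
        got = model.forward(X)
        for row, u in zip(X, got):
            s = [
                -1 + 2 * (row[i] - scaler.x_min[i]) / (scaler.x_max[i] - scaler.x_min[i])
                for i in range(4)
            ]
            acc = model.b_o
            for j in range(16):
                zj = model.b_h[j]
                for i in range(4):
                    zj += model.w_ih[j, i] * s[i]
                nj = 2.0 / (1.0 + math.exp(-2.0 * zj)) - 1.0
                acc += model.w_ho[j] * nj
            ref = 1166.0 + (acc + 1) * (2138.0 - 1166.0) / 2
            assert u == pytest.approx(ref, rel=1e-12)

    def test_oddness_with_zero_biases(self, rng):
        model = make_model(
            w_ih=rng.normal(size=(8, 4)), b_h=np.zeros(8),
            w_ho=rng.normal(size=8), b_o=0.0,
        )
        X = rng.uniform(-1, 1, size=(20, 4))
        assert np.allclose(model.forward(-X), -model.forward(X), atol=1e-12)

    def test_bounded_output_envelope(self, rng):
        model = make_model(
            w_ih=rng.normal(size=(16, 4)) * 3, b_h=rng.normal(size=16),
            w_ho=rng.normal(size=16), b_o=rng.normal(),
        )
        bound = abs(model.b_o) + np.sum(np.abs(model.w_ho))
        X = rng.uniform(-50, 50, size=(200, 4))
        assert np.all(np.abs(model.forward(X)) <= bound + 1e-9)

    def test_shape_mismatch(self):
        model = make_model(np.ones((4, 4)), np.zeros(4), np.ones(4), 0.0)
        with pytest.raises(DataFormatError, match="input columns"):
            model.forward(np.ones((3, 5)))


class TestTraining:
    def test_linear_function_of_temperature(self, rng):
        """An easy target linear in T is fitted essentially exactly."""
        n = 200
        df = pd.DataFrame({
            "T_K": rng.uniform(293, 343, n),
            "Vc_cm3mol": rng.uniform(150, 650, n),
            "omega": rng.uniform(0.5, 1.3, n),
            "MW_gmol": rng.uniform(60, 190, n),
        })
        df["u_ms"] = 2.0 * df["T_K"] + 3.0
        model, report = ds.train(df, ds.TrainingConfig(n_hidden=4, seed=1))
        assert report.train_metrics.ard_percent <= 0.1
        assert report.test_metrics.ard_percent <= 0.1

    def test_insufficient_data(self):
        df = pd.DataFrame(
            {c: [1.0] for c in (*ds.FEATURE_COLUMNS, "u_ms")}
        )
        with pytest.raises(ValidityRangeError, match="insufficient data"):
            ds.train(df)

    def test_loss_history_non_increasing(self, trained_model):
        _, report = trained_model
        hist = np.asarray(report.loss_history)
        assert np.all(np.diff(hist) <= 0)

    def test_split_is_seeded_and_disjoint(self):
        tr1, te1 = split_dataset(415, 300 / 415, seed=42)
        tr2, te2 = split_dataset(415, 300 / 415, seed=42)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
        assert len(tr1) == 300 and len(te1) == 115
        assert len(np.intersect1d(tr1, te1)) == 0
        tr3, _ = split_dataset(415, 300 / 415, seed=43)
        assert not np.array_equal(tr1, tr3)

    def test_lm_matches_scipy_least_squares(self, rng):
        """Dual route: the hand-rolled LM loop vs scipy's LM on one init."""
        n, h = 150, 4
        Xs = rng.uniform(-1, 1, size=(n, 4))
        coeffs = rng.normal(size=4)
        ys = np.tanh(Xs @ coeffs) * 0.8
        n_params = h * 6 + 1
        p0 = rng.uniform(-0.5, 0.5, size=n_params)
        cfg = ds.TrainingConfig(n_hidden=h, max_iterations=300)
        p_ours, hist, _ = _lm_fit(Xs, ys, p0, cfg)
        sol = least_squares(
            lambda p: _residuals_and_jacobian(p, Xs, ys, h, with_jac=False)[0],
            p0,
            jac=lambda p: _residuals_and_jacobian(p, Xs, ys, h)[1],
            method="lm",
            max_nfev=2000,
        )
        loss_scipy = 0.5 * float(sol.fun @ sol.fun)
        assert hist[-1] <= max(10 * loss_scipy, 1e-10)
        assert hist[-1] < 1e-4  # both routes actually fit the surface

    def test_jacobian_matches_finite_differences(self, rng):
        Xs = rng.uniform(-1, 1, size=(10, 4))
        ys = rng.uniform(-1, 1, size=10)
        h = 3
        p = rng.normal(size=h * 6 + 1) * 0.5
        r, J = _residuals_and_jacobian(p, Xs, ys, h)
        eps = 1e-7
        for k in range(p.size):
            dp = np.zeros_like(p)
            dp[k] = eps
            r_hi, _ = _residuals_and_jacobian(p + dp, Xs, ys, h, with_jac=False)
            r_lo, _ = _residuals_and_jacobian(p - dp, Xs, ys, h, with_jac=False)
            assert np.allclose(J[:, k], (r_hi - r_lo) / (2 * eps), atol=1e-6)


class TestNeuronSweep:
    @pytest.fixture(scope="class")
    def small_teacher_data(self):
        df = ds.generate_synthetic(
            ds.SyntheticConfig(n_des=12, noise_sd=0.0, seed=11, teacher="network")
        )
        return df

    def test_capacity_ordering(self, small_teacher_data):
        cfg = ds.TrainingConfig(seed=5, max_iterations=150, n_restarts=2)
        sweep = ds.neuron_sweep(small_teacher_data, [1, 4, 16], cfg)
        t = sweep.table.set_index("n_hidden")["test_ard_percent"]
        assert t[sweep.selected] <= t[1]
        assert sweep.selected in (4, 16)

    def test_single_candidate(self, small_teacher_data):
        cfg = ds.TrainingConfig(seed=5, max_iterations=60)
        sweep = ds.neuron_sweep(small_teacher_data, [16], cfg)
        assert len(sweep.table) == 1 and sweep.selected == 16

    def test_duplicates_deduplicated_with_warning(self, small_teacher_data):
        cfg = ds.TrainingConfig(seed=5, max_iterations=30)
        with pytest.warns(UserWarning, match="duplicate"):
            sweep = ds.neuron_sweep(small_teacher_data, [4, 4], cfg)
        assert len(sweep.table) == 1


class TestSerialization:
    def test_round_trip_forward_equality(self, trained_model, tmp_path, rng):
        model, report = trained_model
        path = tmp_path / "model.json"
        ds.save_model(model, path)
        clone = ds.load_model(path)
        X = np.column_stack([
            rng.uniform(293, 343, 10), rng.uniform(150, 650, 10),
            rng.uniform(0.5, 1.3, 10), rng.uniform(60, 190, 10),
        ])
        assert np.array_equal(model.forward(X), clone.forward(X))

    def test_reloaded_model_reproduces_reported_test_ard(
        self, trained_model, noise_free_dataset, tmp_path
    ):
        model, report = trained_model
        ds.save_model(model, tmp_path / "m.json")
        clone = ds.load_model(tmp_path / "m.json")
        _, idx_test = split_dataset(len(noise_free_dataset), 300 / 415, seed=3)
        sub = noise_free_dataset.iloc[idx_test]
        rep = ds.metrics(sub["u_ms"], clone.predict_frame(sub))
        assert rep.ard_percent == report.test_metrics.ard_percent

    def test_truncated_file_rejected(self, trained_model, tmp_path):
        model, _ = trained_model
        path = tmp_path / "model.json"
        ds.save_model(model, path)
        path.write_text(path.read_text()[: 100])
        with pytest.raises(DataFormatError, match="corrupted"):
            ds.load_model(path)

    def test_missing_field_rejected(self, trained_model, tmp_path):
        model, _ = trained_model
        payload = model.to_dict()
        del payload["w_ho"]
        path = tmp_path / "model.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(DataFormatError, match="w_ho"):
            ds.load_model(path)

    def test_bad_shapes_rejected(self):
        with pytest.raises(DataFormatError, match="w_ih"):
            ds.SoundSpeedModel(
                w_ih=np.ones((16, 3)), b_h=np.zeros(16), w_ho=np.ones(16),
                b_o=0.0, scaler=identity_scaler(),
            )
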