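import numpy as np
import pytest

from barknarx.narx import (
    NarxConfig,
    NarxModel,
    NarxTrainingError,
    _jacobian,
    _sse_and_grad,
    build_regressors,
    compute_fit_metrics,
    init_nguyen_widrow,
    load_model,
    model_from_dict,
    model_to_dict,
    narx_predict,
    pack_params,
    perturb_model,
    save_model,
    train_narx,
    unpack_params,
)
from barknarx.series import ScalerParams, split_series
from barknarx.synthetic import (
    SyntheticProfile,
    default_narx_truth_model,
    generate_dataset,
    noiseless,
)
from barknarx.series import build_series, series_to_frame


def unit_scalers():
    return {name: ScalerParams(name, 0.0, 1.0) for name in ("avg_d", "DTT", "DBT")}


def make_model(W1, b1, w2, b2, delay=1, scalers=None):
    return NarxModel(
        W1=np.asarray(W1, float), b1=np.asarray(b1, float),
        w2=np.asarray(w2, float), b2=float(b2), delay=delay,
        scalers=scalers or unit_scalers(),
    )


class TestInitialization:
    @pytest.mark.parametrize("h", [10, 20])
    def test_nguyen_widrow_norm_law(self, h):
        cfg = NarxConfig(n_hidden=h, delay=1, seed=5)
        model = init_nguyen_widrow(cfg)
        expected = 0.7 * h ** (1.0 / 3.0)
        assert np.allclose(np.linalg.norm(model.W1, axis=1), expected, rtol=1e-12)

    def test_biases_tile_the_range(self):
        model = init_nguyen_widrow(NarxConfig(n_hidden=20, delay=2, seed=5))
        beta = 0.7 * 20 ** (1.0 / 6.0)
        assert model.b1.min() == pytest.approx(-beta)
        assert model.b1.max() == pytest.approx(beta)

    def test_seed_determinism(self):
        a = init_nguyen_widrow(NarxConfig(n_hidden=7, delay=2, seed=11))
        b = init_nguyen_widrow(NarxConfig(n_hidden=7, delay=2, seed=11))
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.w2, b.w2)


def ramp_frame(K=12):
    import pandas as pd

    return pd.DataFrame(
        {
            "k": np.arange(1, K + 1),
            "tree_id": ["t"] * K,
            "avg_d": np.linspace(0.9, 0.1, K),
            "DTT": np.linspace(0.95, 0.05, K),
            "DBT": np.linspace(0.8, 0.2, K),
            "Hb": np.linspace(0.0, 10.0, K),
            "H": 12.0,
        }
    )


class TestForwardPass:
    def test_all_zero_weights_predict_constant(self):
        model = make_model(np.zeros((3, 3)), np.zeros(3), np.zeros(3), b2=0.25)
        pred = narx_predict(model, ramp_frame())
        assert np.isnan(pred[0])  # priming position
        assert np.allclose(pred[1:], 0.25)

    def test_zero_hidden_inputs_yield_half_sigmoid(self):
        # hidden activations sigma(0)=0.5, so output = 0.5 * sum(w2)
        w2 = np.array([0.2, -0.4, 0.6])
        model = make_model(np.zeros((3, 3)), np.zeros(3), w2, b2=0.0)
        pred = narx_predict(model, ramp_frame())
        assert np.allclose(pred[1:], 0.5 * w2.sum())

    def test_inverse_scaling_applied(self):
        scalers = unit_scalers()
        scalers["DBT"] = ScalerParams("DBT", 2.0, 6.0)
        model = make_model(np.zeros((2, 3)), np.zeros(2), np.zeros(2), b2=0.5,
                           scalers=scalers)
        pred = narx_predict(model, ramp_frame())
        assert np.allclose(pred[1:], 4.0)  # 0.5 scaled back into [2, 6]

    def test_open_and_closed_loop_agree_for_exact_model(self):
        truth = default_narx_truth_model("pine", seed=3)
        prof = noiseless(SyntheticProfile(species="pine", truth="narx",
                                          narx_model=truth))
        gen = generate_dataset(prof, 10, seed=1)
        frame = series_to_frame(build_series(gen.dataset))
        open_p = narx_predict(truth, frame, mode="open_loop")
        closed_p = narx_predict(truth, frame, mode="closed_loop")
        assert np.allclose(open_p[1:], closed_p[1:], atol=1e-9)
        assert np.allclose(open_p[1:], frame["DBT"].to_numpy()[1:], atol=1e-9)

    def test_series_shorter_than_delay_rejected(self):
        model = make_model(np.zeros((2, 6)), np.zeros(2), np.zeros(2), 0.0, delay=2)
        with pytest.raises(ValueError, match="too short"):
            narx_predict(model, ramp_frame(K=2))

    def test_regressor_window_width(self):
        frame = ramp_frame()
        X, t, pos = build_regressors(frame, delay=2, scalers=unit_scalers())
        assert X.shape == (10, 6) and pos[0] == 3

    def test_boundary_reset_drops_cross_tree_rows(self):
        frame = ramp_frame()
        frame.loc[6:, "tree_id"] = "u"
        X_all, _, pos_all = build_regressors(frame, 1, unit_scalers())
        X_cut, _, pos_cut = build_regressors(frame, 1, unit_scalers(),
                                             boundary_reset=True)
        assert len(pos_all) - len(pos_cut) == 1
        assert 7 not in pos_cut  # first sample of the second tree


class TestGradients:
    def test_jacobian_matches_central_differences(self):
        # 2(1)-3-1 network, random weights: analytic vs numeric within 1e-5
        rng = np.random.default_rng(0)
        cfg = NarxConfig(n_hidden=3, delay=1, seed=1)
        model = init_nguyen_widrow(cfg, scalers=unit_scalers())
        X = rng.uniform(0, 1, size=(20, 3))
        w = pack_params(model)
        shape = (3, 3)
        _, J = _jacobian(w, X, shape, "logistic")
        eps = 1e-6
        for p in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[p] += eps
            wm[p] -= eps
            from barknarx.narx import _forward_vec

            yp, *_ = _forward_vec(wp, X, shape, "logistic")
            ym, *_ = _forward_vec(wm, X, shape, "logistic")
            numeric = (yp - ym) / (2 * eps)
            denom = np.maximum(np.abs(numeric), 1e-8)
            assert np.max(np.abs(J[:, p] - numeric) / denom) < 1e-5

    def test_sse_gradient_matches_differences(self):
        rng = np.random.default_rng(1)
        model = init_nguyen_widrow(NarxConfig(n_hidden=3, delay=1, seed=2),
                                   scalers=unit_scalers())
        X = rng.uniform(0, 1, size=(15, 3))
        t = rng.uniform(0, 1, size=15)
        w = pack_params(model)
        sse, g = _sse_and_grad(w, X, t, (3, 3), "logistic")
        eps = 1e-6
        for p in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[p] += eps
            wm[p] -= eps
            sp, _ = _sse_and_grad(wp, X, t, (3, 3), "logistic")
            sm, _ = _sse_and_grad(wm, X, t, (3, 3), "logistic")
            numeric = (sp - sm) / (2 * eps)
            assert abs(g[p] - numeric) <= 1e-5 * max(abs(numeric), 1e-6)


class TestTraining:
    @pytest.mark.parametrize("trainer", ["LM", "BR", "SCG"])
    def test_objective_never_increases(self, trainer, pine_noisy_frame,
                                       pine_noisy_split):
        cfg = NarxConfig(n_hidden=5, delay=1, trainer=trainer, max_epochs=40, seed=3)
        model = init_nguyen_widrow(cfg)
        _, report = train_narx(model, pine_noisy_frame, pine_noisy_split, cfg)
        hist = np.array(report.objective_history)
        best = np.minimum.accumulate(hist)
        assert (np.diff(best) <= 0).all()
        if trainer in ("LM", "SCG"):  # these only record accepted steps
            assert (np.diff(hist) <= 1e-15).all()

    def test_lm_with_huge_damping_is_gradient_descent_step(self, pine_noisy_frame,
                                                           pine_noisy_split):
        cfg = NarxConfig(n_hidden=4, delay=1, trainer="LM", max_epochs=1,
                         lm_mu0=1e8, seed=9)
        model = init_nguyen_widrow(cfg)
        _, report = train_narx(model, pine_noisy_frame, pine_noisy_split, cfg)
        assert len(report.objective_history) == 2
        assert report.objective_history[1] < report.objective_history[0]

    def test_bit_identical_reruns(self, pine_noisy_frame, pine_noisy_split):
        cfg = NarxConfig(n_hidden=5, delay=1, trainer="LM", max_epochs=25, seed=13)
        runs = []
        for _ in range(2):
            model = init_nguyen_widrow(cfg)
            fitted, report = train_narx(model, pine_noisy_frame, pine_noisy_split, cfg)
            runs.append((pack_params(fitted), report))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1].objective_history == runs[1][1].objective_history
        assert runs[0][1].mse == runs[1][1].mse

    def test_br_reports_zero_validation_by_convention(self, pine_noisy_frame,
                                                      pine_noisy_split):
        cfg = NarxConfig(n_hidden=4, delay=1, trainer="BR", max_epochs=30, seed=2)
        model = init_nguyen_widrow(cfg)
        _, report = train_narx(model, pine_noisy_frame, pine_noisy_split, cfg)
        assert report.mse["validation"] == 0.0 and report.r["validation"] == 0.0
        assert report.br_validation_convention

    def test_restart_stability(self, pine_noisy_frame, pine_noisy_split):
        # final training MSE varies little across starting weights (the
        # regularized trainer, which runs to its epoch budget, is the
        # stability reference)
        finals = []
        for seed in range(20):
            cfg = NarxConfig(n_hidden=8, delay=1, trainer="BR", max_epochs=150,
                             seed=seed)
            model = init_nguyen_widrow(cfg)
            _, report = train_narx(model, pine_noisy_frame, pine_noisy_split, cfg)
            finals.append(report.mse["training"])
        finals = np.array(finals)
        assert finals.std() / finals.mean() < 0.10

    def test_split_outside_series_rejected(self, pine_noisy_frame):
        bad = split_series(len(pine_noisy_frame) + 50, seed=0)
        cfg = NarxConfig(n_hidden=3, max_epochs=5)
        model = init_nguyen_widrow(cfg)
        with pytest.raises(ValueError, match="outside the series"):
            train_narx(model, pine_noisy_frame, bad, cfg)


class TestMetricsAndSerialization:
    def test_perfect_fit(self):
        assert compute_fit_metrics([1, 2, 3], [1, 2, 3]) == (0.0, pytest.approx(1.0))

    def test_bias_does_not_affect_correlation(self):
        mse, r = compute_fit_metrics([1, 2, 3], [2, 3, 4])
        assert mse == pytest.approx(1.0) and r == pytest.approx(1.0)

    def test_anticorrelation(self):
        mse, r = compute_fit_metrics([0, 1], [1, 0])
        assert mse == pytest.approx(1.0) and r == pytest.approx(-1.0)

    def test_zero_variance_flags_nan(self):
        mse, r = compute_fit_metrics([1, 1, 1], [1, 2, 3])
        assert np.isnan(r)

    def test_json_round_trip_exact(self, tmp_path):
        model = init_nguyen_widrow(NarxConfig(n_hidden=6, delay=2, seed=21),
                                   scalers=unit_scalers())
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.W1, model.W1)
        assert np.array_equal(back.w2, model.w2)
        assert back.b2 == model.b2 and back.delay == model.delay
        assert back.scalers == model.scalers

    def test_dict_round_trip(self):
        model = init_nguyen_widrow(NarxConfig(n_hidden=2, seed=1),
                                   scalers=unit_scalers())
        back = model_from_dict(model_to_dict(model))
        assert np.array_equal(pack_params(back), pack_params(model))
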