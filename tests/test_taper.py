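import numpy as np
import pytest

from barknarx.io_model import Dataset
from barknarx.series import build_series, series_to_frame
from barknarx.synthetic import SyntheticProfile, generate_dataset, noiseless
from barknarx.taper import (
    BreastHeightInfo,
    TaperCoefficients,
    TaperError,
    breast_height_info,
    fit_taper_coefficients,
    load_coefficients,
    predict_stat1,
    predict_stat2,
    printed_coefficients,
    save_coefficients,
)

from conftest import make_tree


class TestPredictStat1:
    @pytest.mark.parametrize("species,intercept", [("pine", -0.060022), ("oak", 0.488477)])
    def test_zero_diameter_leaves_intercept(self, species, intercept):
        coef = printed_coefficients("STAT1", species)
        assert predict_stat1(0.0, 5.0, 20.0, coef) == pytest.approx(intercept)

    def test_stump_prediction_pine(self):
        # avg_d=30, Hb=0, H=20: 30*(b1 + b4*20) + b5, evaluated independently
        coef = printed_coefficients("STAT1", "pine")
        assert predict_stat1(30.0, 0.0, 20.0, coef) == pytest.approx(3.889268)

    def test_vectorized_over_sections(self):
        coef = printed_coefficients("STAT1", "pine")
        out = predict_stat1(np.array([30.0, 20.0]), np.array([0.0, 10.0]), 20.0, coef)
        assert out.shape == (2,)

    def test_nonpositive_height_rejected(self):
        coef = printed_coefficients("STAT1", "pine")
        with pytest.raises(TaperError):
            predict_stat1(30.0, 0.0, 0.0, coef)

    def test_model_mismatch_rejected(self):
        coef = printed_coefficients("STAT2", "pine")
        with pytest.raises(TaperError):
            predict_stat1(30.0, 0.0, 20.0, coef)


class TestPredictStat2:
    @pytest.mark.parametrize("species,intercept", [("pine", 0.020500), ("oak", 0.404019)])
    def test_zero_diameter_leaves_intercept(self, species, intercept):
        coef = printed_coefficients("STAT2", species)
        assert predict_stat2(0.0, 5.0, 20.0, 0.9, coef) == pytest.approx(intercept)

    def test_barkless_breast_height_pine(self):
        # ratio=1, avg_d=10, Hb=0, H=20: 10*(c1 + c4*20 + c5) + c6
        coef = printed_coefficients("STAT2", "pine")
        expected = 10 * (0.525331 - 0.001421 * 20 - 0.407817) + 0.020500
        assert predict_stat2(10.0, 0.0, 20.0, 1.0, coef) == pytest.approx(expected)

    def test_reduces_to_stat1_when_quotient_term_vanishes(self):
        s1 = printed_coefficients("STAT1", "pine")
        s2 = TaperCoefficients("STAT2", "pine", b=s1.b[:4] + (0.0, s1.b[4]))
        avg_d, hb, h = np.array([30.0, 12.0]), np.array([1.3, 9.0]), 24.0
        assert np.allclose(
            predict_stat2(avg_d, hb, h, 0.77, s2), predict_stat1(avg_d, hb, h, s1)
        )

    @pytest.mark.parametrize("model", ["STAT1", "STAT2"])
    def test_linearity_in_diameter(self, model):
        coef = printed_coefficients(model, "oak")
        args = (4.0, 20.0) if model == "STAT1" else (4.0, 20.0, 0.9)
        def f(d):
            if model == "STAT1":
                return predict_stat1(d, *args[:2], coef)
            return predict_stat2(d, *args, coef)
        intercept = f(0.0)
        assert f(6.0) - intercept == pytest.approx(3 * (f(2.0) - intercept))


class TestBreastHeight:
    def test_info_from_exact_section(self):
        info = breast_height_info(make_tree())
        assert info.d1_bh == 28.0 and info.ratio == pytest.approx((28.0 - 1.9) / 28.0)

    def test_missing_section_names_tree(self):
        tree = make_tree("lone", rows=[(0.0, 30.0, 1.0, 1.0), (4.0, 24.0, 0.8, 0.7)])
        with pytest.raises(TaperError, match="lone"):
            breast_height_info(tree)

    def test_interpolation_behind_flag(self):
        tree = make_tree("t", rows=[(0.0, 30.0, 1.0, 1.0), (2.6, 26.0, 0.8, 0.6)])
        info = breast_height_info(tree, interpolate=True)
        assert info.d1_bh == pytest.approx(28.0)  # halfway between sections
        assert info.k1_bh == pytest.approx(0.9)

    def test_invalid_bark_exceeds_diameter(self):
        with pytest.raises(TaperError):
            BreastHeightInfo(d1_bh=2.0, d2_bh=2.0, k1_bh=1.5, k2_bh=1.0)


def _series_with_ratio(gen):
    frame = series_to_frame(build_series(gen.dataset))
    ratios = {t.tree_id: breast_height_info(t).ratio for t in gen.dataset.trees}
    return frame, frame["tree_id"].map(ratios).to_numpy(dtype=float)


class TestFit:
    @pytest.mark.parametrize("model,species", [
        ("STAT1", "pine"), ("STAT1", "oak"), ("STAT2", "pine"), ("STAT2", "oak"),
    ])
    def test_noiseless_exact_recovery(self, model, species):
        truth = printed_coefficients(model, species)
        prof = noiseless(SyntheticProfile(species=species, truth=model.lower(),
                                          min_dob=8.0))
        gen = generate_dataset(prof, 30, seed=5)
        frame, ratio = _series_with_ratio(gen)
        coef, diag = fit_taper_coefficients(
            frame["avg_d"], frame["Hb"], frame["H"], frame["DBT"],
            model=model, ratio=ratio if model == "STAT2" else None, species=species,
        )
        rel = np.abs((np.array(coef.b) - np.array(truth.b)) / np.array(truth.b))
        assert rel.max() < 1e-8
        assert diag["residual_variance"] < 1e-20

    def test_too_few_samples(self):
        with pytest.raises(TaperError, match="at least"):
            fit_taper_coefficients([1, 2, 3], [0, 1, 2], [10, 10, 10], [1, 1, 1])

    def test_degenerate_design_rejected(self):
        # all sections at the same height on same-size stems: columns collinear
        n = 12
        with pytest.raises(TaperError, match="rank"):
            fit_taper_coefficients(
                np.full(n, 25.0), np.full(n, 1.3), np.full(n, 20.0),
                np.linspace(1, 2, n),
            )


class TestCoefficientFiles:
    def test_round_trip(self, tmp_path):
        table = {
            ("STAT1", "pine"): printed_coefficients("STAT1", "pine"),
            ("STAT2", "oak"): printed_coefficients("STAT2", "oak"),
        }
        path = tmp_path / "coef.tsv"
        save_coefficients(table, path)
        assert load_coefficients(path) == table

    def test_unknown_combination(self):
        with pytest.raises(TaperError):
            printed_coefficients("STAT1", "spruce")

    def test_coefficient_length_enforced(self):
        with pytest.raises(TaperError):
            TaperCoefficients("STAT1", "pine", b=(1.0, 2.0))
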