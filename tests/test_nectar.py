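"""Nectar standardization, curve fitting and the availability matrix."""

import numpy as np
import pandas as pd
import pytest

from dielniche.nectar import (
    DEFAULT_HOUR_GRID,
    NectarCurve,
    NectarSecretionGLM,
    brix_to_concentration,
    build_availability_matrix,
    fit_nectar_curve,
    harmonize_dynamic,
    predict_hourly_production,
    scale_dense_flower_count,
    standardize_nectar,
    sucrose_density,
    sugar_mass,
)
from dielniche.overlap import mean_overlap


class TestBrix:
    def test_zero_reading_is_zero_at_any_temperature(self):
        for t in (5.0, 20.0, 35.0):
            assert brix_to_concentration(0.0, t) == 0.0

    def test_reference_temperature_applies_no_adjustment(self):
        # independent hand evaluation: mg/ml = 10*B*d(B), d(10) = 0.9982
        # + 3.85e-3*10 + 1.66e-5*100 = 1.03836
        assert brix_to_concentration(10.0, 20.0) == pytest.approx(10 * 10 * 1.03836, rel=1e-9)

    def test_warm_reading_corrected_upward(self):
        assert brix_to_concentration(10.0, 30.0) > brix_to_concentration(10.0, 20.0)
        assert brix_to_concentration(10.0, 12.0) < brix_to_concentration(10.0, 20.0)

    def test_out_of_range_inputs_named(self):
        with pytest.raises(ValueError, match="brix"):
            brix_to_concentration(90.0, 20.0)
        with pytest.raises(ValueError, match="temperature"):
            brix_to_concentration(10.0, 50.0)


def dynamic_frame(rows):
    """Rows of (slot, volume_ul, brix) for one dynamic-protocol flower."""
    return pd.DataFrame(
        [
            {
                "plant": "p",
                "individual": "i1",
                "flower": "f1",
                "slot": s,
                "volume_ul": v,
                "brix_pct": b,
                "temperature_c": 20.0,
                "protocol": "dynamic",
            }
            for s, v, b in rows
        ]
    )


class TestHarmonize:
    def test_volume_accumulation_and_concentration_carry(self):
        out = harmonize_dynamic(dynamic_frame([(6, 2.0, 15.0), (10, 3.0, 22.0)]))
        assert out["volume_ul"].tolist() == [2.0, 5.0]
        assert out["brix_pct"].tolist() == [15.0, 15.0]

    def test_zero_volume_takes_previous_values_verbatim(self):
        out = harmonize_dynamic(dynamic_frame([(6, 2.0, 15.0), (10, 0.0, 22.0)]))
        assert out["volume_ul"].tolist() == [2.0, 2.0]
        assert out["brix_pct"].tolist() == [15.0, 15.0]

    def test_single_slot_unchanged(self):
        out = harmonize_dynamic(dynamic_frame([(6, 2.0, 15.0)]))
        assert out["volume_ul"].tolist() == [2.0]

    def test_cumulative_rows_pass_through(self):
        df = dynamic_frame([(6, 2.0, 15.0), (10, 3.0, 22.0)])
        df["protocol"] = "cumulative"
        pd.testing.assert_frame_equal(harmonize_dynamic(df), df)

    def test_unordered_slots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            harmonize_dynamic(dynamic_frame([(10, 2.0, 15.0), (6, 3.0, 22.0)]))

    def test_volumes_non_decreasing_property(self):
        rng = np.random.default_rng(13)
        rows = [(s, float(v), 20.0) for s, v in zip((6, 10, 14, 18), rng.exponential(3.0, 4))]
        out = harmonize_dynamic(dynamic_frame(rows))
        assert np.all(np.diff(out["volume_ul"]) >= 0)

    def test_observed_concentration_flag(self):
        out = harmonize_dynamic(
            dynamic_frame([(6, 2.0, 15.0), (10, 3.0, 22.0)]), use_observed_concentration=True
        )
        assert out["brix_pct"].tolist() == [15.0, 22.0]


@pytest.mark.parametrize(
    "vol, conc, expected",
    [(0.0, 300.0, 0.0), (1000.0, 1.0, 1.0), (10.0, 250.0, 2.5)],
)
def test_sugar_mass(vol, conc, expected):
    assert sugar_mass(vol, conc) == pytest.approx(expected)
    with pytest.raises(ValueError):
        sugar_mass(-1.0, 1.0)


ARANEOSA = (5.086, 0.749, -0.043)


def curve_samples(coefs, slots=(6, 10, 14, 18), reps=1):
    b0, b1, b2 = coefs
    t = np.repeat(np.asarray(slots, float), reps)
    mg = np.exp(b0 + b1 * t + b2 * t * t) / 1000.0
    return pd.DataFrame({"plant": "p", "slot": t, "sugar_mg": mg})


class TestSecretionGLM:
    def test_noiseless_recovery_with_integer_response(self):
        # integer-µg rounding leaves coefficient quantization bias well below
        # 1e-3 for this species
        curve = fit_nectar_curve(curve_samples(ARANEOSA))
        np.testing.assert_allclose([curve.b0, curve.b1, curve.b2], ARANEOSA, atol=1e-3)
        assert curve.converged and curve.n == 4

    def test_too_few_slots_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_nectar_curve(curve_samples(ARANEOSA, slots=(6, 10)))

    def test_zero_heavy_response_still_fits(self):
        df = pd.DataFrame({"plant": "p", "slot": [6, 10, 14, 18], "sugar_mg": [0.0, 0.002, 0.001, 0.0]})
        curve = fit_nectar_curve(df)
        assert np.isfinite(curve.coef).all()

    def test_estimator_predict_and_domain(self):
        est = NectarSecretionGLM().fit([6, 10, 14, 18], curve_samples(ARANEOSA)["sugar_mg"])
        pred = est.predict([6.0, 12.0])
        assert pred.shape == (2,) and np.all(pred > 0)
        with pytest.raises(ValueError, match="domain"):
            est.predict([19.0])

    def test_multiple_plants_rejected(self):
        df = curve_samples(ARANEOSA)
        df.loc[0, "plant"] = "other"
        with pytest.raises(ValueError, match="multiple plants"):
            fit_nectar_curve(df)


class TestPrediction:
    def test_aechmea_peak_hour_in_reported_window(self):
        b0, b1, b2 = ARANEOSA
        peak = -b1 / (2 * b2)
        assert peak == pytest.approx(8.71, abs=0.01)
        assert 7 <= peak <= 13

    def test_quesnelia_vertex_is_interior_minimum(self):
        b0, b1, b2 = 10.661, -0.549, 0.021
        vertex = -b1 / (2 * b2)
        assert 10 <= vertex <= 15 and b2 > 0  # upward parabola: a minimum

    def test_flat_curve(self):
        curve = NectarCurve("p", 2.0, 0.0, 0.0)
        pred = predict_hourly_production(curve)
        np.testing.assert_allclose(pred, np.exp(2.0) / 1000.0)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="domain"):
            predict_hourly_production(NectarCurve("p", 1, 0, 0), hours=[5])

    def test_log_prediction_second_differences_constant(self):
        curve = NectarCurve("p", *ARANEOSA)
        logs = np.log(predict_hourly_production(curve, hours=range(6, 18)).to_numpy())
        np.testing.assert_allclose(np.diff(logs, n=2), 2 * ARANEOSA[2], atol=1e-10)


class TestAvailability:
    def build(self, totals):
        curves = {"a": NectarCurve("a", *ARANEOSA), "b": NectarCurve("b", 4.0, 0.3, -0.02)}
        return build_availability_matrix(curves, totals)

    def test_zero_flowers_zero_row(self):
        m3 = self.build({"a": 0, "b": 5})
        assert (m3.loc["a"] == 0).all() and (m3.loc["b"] > 0).all()

    def test_one_flower_equals_per_flower_prediction(self):
        m3 = self.build({"a": 1, "b": 5})
        np.testing.assert_allclose(
            m3.loc["a"], predict_hourly_production(NectarCurve("a", *ARANEOSA))
        )

    def test_doubling_flowers_scales_row_but_not_overlap(self):
        base = self.build({"a": 10, "b": 5})
        doubled = self.build({"a": 20, "b": 5})
        np.testing.assert_allclose(doubled.loc["a"], 2 * base.loc["a"])
        assert mean_overlap(doubled).mean_value == pytest.approx(
            mean_overlap(base).mean_value, abs=1e-12
        )

    def test_missing_total_names_plant(self):
        with pytest.raises(KeyError, match="b"):
            build_availability_matrix({"b": NectarCurve("b", 1, 0, 0)}, {"a": 3})

    def test_hour_grid_is_twelve_bins(self):
        assert self.build({"a": 1, "b": 1}).shape[1] == len(DEFAULT_HOUR_GRID) == 12


@pytest.mark.parametrize(
    "counts, branches, expected",
    [((2, 2, 2, 2, 2), 10, 20), ((5,), 1, 5), ((1, 2, 3), 4, 8)],
)
def test_scale_dense_flower_count(counts, branches, expected):
    assert scale_dense_flower_count(counts, branches) == expected


def test_scale_dense_flower_count_rejects_empty():
    with pytest.raises(ValueError):
        scale_dense_flower_count([], 3)


def test_standardize_pipeline_roundtrip():
    # volume/Brix pairs built from a known sugar target must reproduce it
    conc = brix_to_concentration(20.0, 20.0)
    target = 2.5  # mg
    df = dynamic_frame([(6, target / conc * 1000.0, 20.0)])
    df["protocol"] = "cumulative"
    out = standardize_nectar(df)
    assert out["sugar_mg"].iloc[0] == pytest.approx(target, rel=1e-12)
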