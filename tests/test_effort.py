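"""Swept-area computation, OLS imputation, length-weight, catch rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import trawlkit as tk
from conftest import make_dataset, make_hauls


class TestSweptAreaFormulas:
    def test_distance_times_opening(self):
        assert tk.swept_area_from_distance(3.0, 20.0) == pytest.approx(0.06)

    def test_zero_opening_is_domain_error(self):
        with pytest.raises(tk.DomainError):
            tk.swept_area_from_distance(3.0, 0.0)

    @given(d=st.floats(0.1, 50), o=st.floats(1, 100))
    def test_linearity_in_distance(self, d, o):
        assert tk.swept_area_from_distance(2 * d, o) == pytest.approx(
            2 * tk.swept_area_from_distance(d, o), rel=1e-12
        )

    def test_speed_formula_worked_examples(self):
        # 60 min at 3 kn: 3 x 1.852 = 5.556 km; x 25 m = 0.1389 km^2
        assert tk.swept_area_from_speed(60.0, 3.0, 25.0) == pytest.approx(0.1389)
        assert tk.swept_area_from_speed(30.0, 4.0, 20.0) == pytest.approx(0.074080)

    def test_zero_duration_is_domain_error(self):
        with pytest.raises(tk.DomainError):
            tk.swept_area_from_speed(0.0, 3.0, 25.0)

    @given(
        dur=st.floats(1, 300), speed=st.floats(0.5, 10), opening=st.floats(1, 100)
    )
    def test_speed_and_distance_formulas_agree_exactly(self, dur, speed, opening):
        direct = tk.swept_area_from_speed(dur, speed, opening)
        via_distance = tk.swept_area_from_distance(
            speed * 1.852 * dur / 60.0, opening
        )
        assert direct == via_distance  # shared code path: bitwise equal


def _haul_frame(n, rng=None, with_area=True):
    rng = rng or np.random.default_rng(0)
    dur = rng.uniform(20, 60, n)
    rows = []
    for i in range(n):
        rows.append(
            make_hauls(
                haul_id=f"H{i}",
                haul_dur=float(dur[i]),
                area_swept=0.001 * float(dur[i]) if with_area else None,
                depth=float(rng.uniform(50, 200)),
            )
        )
    df = pd.DataFrame(rows)
    for col in ("distance", "speed", "gear_opening", "sweep_length", "country", "vessel"):
        if col not in df.columns:
            df[col] = np.nan if col not in ("country", "vessel") else pd.NA
    return df


class TestSweptAreaModel:
    def test_zero_noise_recovers_exact_coefficients(self):
        hauls = _haul_frame(50)
        model = tk.fit_swept_area_model(hauls, candidate_predictors=("haul_dur",))
        assert model.params["haul_dur"] == pytest.approx(0.001, abs=1e-9)
        assert model.params["Intercept"] == pytest.approx(0.0, abs=1e-9)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_rows_is_fitting_error(self):
        hauls = _haul_frame(5)
        with pytest.raises(tk.FittingError):
            tk.fit_swept_area_model(hauls, candidate_predictors=("haul_dur",))

    def test_constant_predictor_leaves_predictions_unchanged(self):
        hauls = _haul_frame(50)
        hauls["sweep_length"] = 60.0  # constant, collinear with intercept
        base = tk.fit_swept_area_model(hauls, candidate_predictors=("haul_dur",))
        extended = tk.fit_swept_area_model(
            hauls, candidate_predictors=("haul_dur", "sweep_length")
        )
        assert "sweep_length" in extended.predictors
        np.testing.assert_allclose(
            base.predict(hauls), extended.predict(hauls), rtol=1e-8
        )

    def test_predictor_needs_80pct_availability(self):
        hauls = _haul_frame(50)
        hauls.loc[hauls.index[:20], "depth"] = np.nan  # 60% available
        model = tk.fit_swept_area_model(
            hauls, candidate_predictors=("haul_dur", "depth")
        )
        assert model.predictors == ("haul_dur",)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        hauls = _haul_frame(1000, rng)
        sigma = 0.005
        hauls["area_swept"] = 0.001 * hauls["haul_dur"] + rng.normal(0, sigma, 1000)
        model = tk.fit_swept_area_model(hauls, candidate_predictors=("haul_dur",))
        se = model.result.bse["haul_dur"]
        assert abs(model.params["haul_dur"] - 0.001) < 3 * se


class TestImputation:
    def _dataset_with_missing(self):
        hauls = _haul_frame(30)
        hauls.loc[hauls.index[25:], "area_swept"] = np.nan
        hauls.loc[25, "haul_dur"] = 30.0
        frame = hauls.assign(verbatim_name="Gadus morhua", num=1.0, wgt=1.0)
        return make_dataset(frame)

    def test_known_area_untouched_and_missing_filled(self):
        ds = self._dataset_with_missing()
        model = tk.fit_swept_area_model(ds.hauls, candidate_predictors=("haul_dur",))
        before = ds.hauls["area_swept"].copy()
        out = tk.impute_swept_area(ds, model)
        known = before.notna()
        pd.testing.assert_series_equal(
            out.hauls.loc[known, "area_swept"], before[known]
        )
        # zero-noise model: haul_dur 30 -> 0.03
        assert out.hauls.loc[25, "area_swept"] == pytest.approx(0.03, abs=1e-9)

    def test_haul_missing_all_predictors_left_absent(self):
        ds = self._dataset_with_missing()
        ds.hauls.loc[27, "haul_dur"] = np.nan
        model = tk.fit_swept_area_model(ds.hauls, candidate_predictors=("haul_dur",))
        out = tk.impute_swept_area(ds, model)
        assert pd.isna(out.hauls.loc[27, "area_swept"])
        assert any("lack every model predictor" in m for m in out.provenance)


class TestLengthWeight:
    def test_worked_example(self):
        # a=0.01, b=3, two 10 cm fish: 2 x 0.01 x 1000 g = 20 g = 0.020 kg
        assert tk.weight_from_lengths([(10.0, 2)], 0.01, 3.0) == pytest.approx(0.020)

    def test_empty_composition_weighs_nothing(self):
        assert tk.weight_from_lengths([], 0.01, 3.0) == 0.0

    @given(
        bins=st.lists(
            st.tuples(st.floats(1, 100), st.integers(0, 50)), min_size=1, max_size=6
        ),
        k=st.integers(1, 5),
    )
    def test_homogeneous_in_counts(self, bins, k):
        w1 = tk.weight_from_lengths(bins, 0.01, 3.0)
        wk = tk.weight_from_lengths([(l, k * c) for l, c in bins], 0.01, 3.0)
        assert wk == pytest.approx(k * w1, rel=1e-9)

    def test_adding_a_bin_never_decreases_weight(self):
        base = tk.weight_from_lengths([(10.0, 2)], 0.01, 3.0)
        more = tk.weight_from_lengths([(10.0, 2), (15.0, 1)], 0.01, 3.0)
        assert more >= base

    def test_reconstruct_weights_fills_only_missing(self, backbone):
        frame = pd.DataFrame(
            [
                {**make_hauls(haul_id="H1"), "verbatim_name": "Gadus morhua",
                 "num": 2.0, "wgt": np.nan},
            ]
        )
        ds = make_dataset(frame)
        ds, _ = tk.harmonize_dataset(ds, backbone)
        lengths = pd.DataFrame(
            {"haul_id": ["H1"], "taxon": ["Gadus morhua"],
             "length_cm": [50.0], "count": [2]}
        )
        out = tk.reconstruct_weights(ds, lengths, backbone)
        a, b = backbone.length_weight("Gadus morhua")
        assert out.catches["wgt"].iloc[0] == pytest.approx(2 * a * 50.0**b / 1000.0)


class TestRates:
    def _rated(self, num=50.0, wgt=20.0, dur=30.0, area=0.05):
        frame = pd.DataFrame(
            [{**make_hauls(haul_dur=dur, area_swept=area),
              "verbatim_name": "Gadus morhua", "num": num, "wgt": wgt}]
        )
        ds = make_dataset(frame)
        ds, _ = tk.harmonize_dataset(ds, tk.default_backbone())
        ds = tk.aggregate_per_taxon_haul(ds)
        return tk.compute_rates(ds)

    def test_worked_examples(self):
        out = self._rated()
        row = out.catches.iloc[0]
        assert row["num_cpue"] == pytest.approx(100.0)  # 50 per half hour
        assert row["wgt_cpua"] == pytest.approx(400.0)  # 20 kg / 0.05 km^2

    def test_absent_numerator_gives_absent_rates(self):
        out = self._rated(num=np.nan)
        row = out.catches.iloc[0]
        assert pd.isna(row["num_cpue"]) and pd.isna(row["num_cpua"])
        assert not pd.isna(row["wgt_cpue"])

    def test_rate_inversion_identity(self, small_survey, backbone):
        ds, _ = small_survey
        out, _ = tk.standardize(ds, backbone)
        catches = out.catches
        area = catches["haul_id"].map(out.hauls.set_index("haul_id")["area_swept"])
        both = catches["num_cpua"].notna() & catches["num"].notna()
        recon = (catches["num_cpua"] * area)[both]
        np.testing.assert_allclose(recon, catches.loc[both, "num"], rtol=1e-12)
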