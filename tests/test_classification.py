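"""Component thresholds and modified ATP III metabolic-syndrome rules."""

import numpy as np
import pandas as pd
import pytest

from homacut import (
    ComponentThresholds,
    EmptyStratumError,
    GrowthReference,
    InputError,
    classify_components,
    derive_component_thresholds,
    select_reference_population,
)
from homacut.classification import COMPONENT_FLAGS
from homacut.metrics import classify_weight_status_frame

from conftest import make_cohort_frame, make_subject


def small_stratum_cohort(wc_values, **overrides):
    """All subjects in one (sex=M, age 10) stratum with given waists."""
    return make_cohort_frame(
        [make_subject(wc_cm=w, **overrides) for w in wc_values]
    )


class TestDeriveThresholds:
    def test_wc_p90_rank_interpolation(self):
        # oracle: rank 1 + 9*0.9 = 9.1 on sorted values 60..69 -> 68.1
        df = small_stratum_cohort(range(60, 70))
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        assert thr.wc_p90[("M", thr.age_group_of(10.0))] == pytest.approx(68.1)

    def test_fixed_cuts_attached_verbatim(self):
        df = small_stratum_cohort(range(60, 70))
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        assert thr.tg_cut == 1.24
        assert thr.hdl_cut == 1.03
        assert thr.glucose_cut == 5.6

    def test_constant_wc_gives_constant_threshold(self):
        df = small_stratum_cohort([62.0] * 10)
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        assert thr.wc_p90[("M", thr.age_group_of(10.0))] == 62.0

    def test_undersized_stratum_named_in_error(self):
        df = small_stratum_cohort(range(60, 70))
        with pytest.raises(EmptyStratumError, match="sex=M"):
            derive_component_thresholds(df, min_stratum_size=20)

    def test_json_round_trip(self, default_cohort):
        thr = derive_component_thresholds(default_cohort)
        back = ComponentThresholds.from_json(thr.to_json())
        assert back.wc_p90 == pytest.approx(thr.wc_p90)
        assert back.sbp_p95 == pytest.approx(thr.sbp_p95)
        assert back.n_height_bands == thr.n_height_bands

    def test_wc_exceedance_near_ten_percent(self, default_cohort):
        # ~10% of each stratum exceeds its own p90 (quantile granularity)
        thr = derive_component_thresholds(default_cohort)
        prof = classify_components(default_cohort, thr)
        rate = prof["central_obesity"].mean()
        assert 0.08 <= rate <= 0.12


class TestClassifyComponents:
    def test_three_fixed_cut_components_is_ms(self):
        df = small_stratum_cohort(np.linspace(60, 80, 25))
        df.loc[0, ["wc_cm", "sbp", "dbp"]] = [55.0, 90.0, 50.0]  # below all cuts
        df.loc[0, ["tg", "hdl", "glucose"]] = [1.30, 1.00, 5.7]
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        prof = classify_components(df, thr)
        assert prof.loc[0, "count"] == 3
        assert bool(prof.loc[0, "ms"])

    def test_fixed_cuts_inclusive(self):
        df = small_stratum_cohort([60.0] * 25)
        df.loc[0, "tg"] = 1.24  # >= is inclusive
        df.loc[1, "hdl"] = 1.03
        df.loc[2, "glucose"] = 5.6
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        prof = classify_components(df, thr)
        assert bool(prof.loc[0, "high_tg"])
        assert bool(prof.loc[1, "low_hdl"])
        assert bool(prof.loc[2, "ifg"])

    def test_median_subject_has_low_count(self, default_cohort):
        med = default_cohort.median(numeric_only=True)
        df = make_cohort_frame(
            [
                make_subject(
                    wc_cm=med["wc_cm"], sbp=med["sbp"], dbp=med["dbp"],
                    tg=med["tg"], hdl=med["hdl"], glucose=med["glucose"],
                )
            ]
            + [make_subject(wc_cm=w) for w in np.linspace(50, 80, 24)]
        )
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        prof = classify_components(df, thr)
        # median values sit below every cohort-percentile and fixed cut
        assert prof.loc[0, "count"] in (0, 1)
        assert not bool(prof.loc[0, "ms"])

    def test_count_and_ms_consistent(self, default_cohort):
        thr = derive_component_thresholds(default_cohort)
        prof = classify_components(default_cohort, thr)
        assert (prof["count"] == prof[COMPONENT_FLAGS].sum(axis=1)).all()
        assert (prof["ms"] == (prof["count"] >= 3)).all()

    def test_monotone_in_risk_factors(self):
        df = small_stratum_cohort(np.linspace(55, 75, 30))
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        base = classify_components(df, thr)
        worse = df.copy()
        worse["tg"] += 1.0
        worse["glucose"] += 1.0
        worse["hdl"] -= 0.6
        worse["sbp"] += 30.0
        worse["wc_cm"] += 20.0
        prof = classify_components(worse, thr)
        assert (prof["count"] >= base["count"]).all()

    def test_missing_measurement_names_fields(self):
        df = small_stratum_cohort(range(60, 70))
        df.loc[3, "tg"] = np.nan
        thr = derive_component_thresholds(df, n_height_bands=1, min_stratum_size=1)
        with pytest.raises(InputError, match="tg"):
            classify_components(df, thr)


class TestReferencePopulation:
    def _parts(self, df):
        ref = GrowthReference.from_samples(df["bmi"], df["age"], df["sex"])
        weight = classify_weight_status_frame(df, ref)
        thr = derive_component_thresholds(df)
        prof = classify_components(df, thr)
        return prof, weight

    def test_subjects_with_components_excluded(self, default_cohort):
        prof, weight = self._parts(default_cohort)
        ref = select_reference_population(default_cohort, prof, weight)
        assert (prof.loc[ref.index, "count"] == 0).all()
        assert (weight.loc[ref.index, "category"] == "normal").all()

    def test_overweight_zero_component_excluded(self, default_cohort):
        prof, weight = self._parts(default_cohort)
        ref = select_reference_population(default_cohort, prof, weight)
        overweight_clean = (weight["category"] == "overweight") & (prof["count"] == 0)
        assert overweight_clean.sum() > 0  # such subjects exist...
        assert not overweight_clean.loc[ref.index].any()  # ...and are excluded

    def test_order_preserved_and_all_qualify_case(self):
        df = make_cohort_frame([make_subject() for _ in range(25)])
        prof = pd.DataFrame({"count": 0, "ms": False}, index=df.index)
        weight = pd.DataFrame({"category": "normal"}, index=df.index)
        ref = select_reference_population(df, prof, weight)
        pd.testing.assert_frame_equal(ref, df)

    def test_empty_reference_rejected(self):
        df = make_cohort_frame([make_subject() for _ in range(5)])
        prof = pd.DataFrame({"count": 1, "ms": False}, index=df.index)
        weight = pd.DataFrame({"category": "normal"}, index=df.index)
        with pytest.raises(EmptyStratumError):
            select_reference_population(df, prof, weight)
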