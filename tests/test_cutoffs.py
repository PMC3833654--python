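"""ROC construction, optimal cut-point selection, reference p95 tables."""

import numpy as np
import pytest

from homacut import (
    EmptyStratumError,
    GeneratorConfig,
    InputError,
    build_roc,
    derive_reference_p95_table,
    generate_cohort,
    operating_characteristics,
    optimal_cutoff,
)
from homacut.cutoffs import distance_to_corner_sq, youden_index

from conftest import make_cohort_frame, make_subject


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise concordance with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_optimum(roc, method):
    """Independent scan over all operating points with the stated tie-breaks."""
    best = None
    for c, se, sp in zip(roc.cutoffs, roc.sensitivity, roc.specificity):
        j = youden_index(se, sp)
        d2 = distance_to_corner_sq(se, sp)
        key = (-j, d2, c) if method == "youden" else (d2, -j, c)
        if best is None or key < best[0]:
            best = (key, c, se, sp)
    return best[1:]


class TestBuildRoc:
    def test_perfect_separation(self):
        roc = build_roc([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        perfect = (roc.sensitivity == 1.0) & (roc.specificity == 1.0)
        assert perfect.any()

    def test_no_discrimination_with_identical_scores(self):
        roc = build_roc([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_extreme_cutoffs(self):
        roc = build_roc([1.0, 2.0, 3.0], [0, 1, 1])
        assert (roc.sensitivity[0], roc.specificity[0]) == (1.0, 0.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (0.0, 1.0)

    def test_curve_monotone_in_cutoff(self, rng):
        scores = rng.normal(size=60).round(1)  # rounding forces ties
        labels = rng.random(60) < 0.4
        roc = build_roc(scores, labels)
        assert (np.diff(roc.sensitivity) <= 0).all()
        assert (np.diff(roc.specificity) >= 0).all()

    def test_auc_equals_pairwise_concordance(self, rng):
        # tie-corrected Mann-Whitney oracle on a random tied instance
        scores = rng.integers(0, 8, size=12).astype(float)
        labels = np.array([1, 0] * 6, bool)
        roc = build_roc(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            build_roc([1.0, 2.0], [1, 1])


class TestOptimalCutoff:
    def test_youden_identity_from_printed_operating_point(self):
        assert youden_index(0.86, 0.67) == pytest.approx(0.53, abs=1e-12)

    def test_perfect_point(self):
        roc = build_roc([1, 2, 3, 4], [0, 0, 1, 1])
        res = optimal_cutoff(roc, "youden")
        assert res.youden == pytest.approx(1.0)
        assert res.distance_sq == pytest.approx(0.0)

    @pytest.mark.parametrize("method", ["youden", "distance"])
    def test_matches_exhaustive_scan(self, method, rng):
        for _ in range(20):
            scores = rng.integers(0, 10, size=10).astype(float)
            labels = rng.random(10) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = build_roc(scores, labels)
            res = optimal_cutoff(roc, method)
            c, se, sp = exhaustive_optimum(roc, method)
            assert res.cutoff == c
            assert res.sensitivity == se
            assert res.specificity == sp

    def test_result_carries_both_criteria(self):
        roc = build_roc([1, 2, 3, 4, 5], [0, 0, 1, 0, 1])
        res = optimal_cutoff(roc, "youden")
        assert res.youden == pytest.approx(res.sensitivity + res.specificity - 1)
        assert res.distance_sq == pytest.approx(
            (1 - res.sensitivity) ** 2 + (1 - res.specificity) ** 2
        )


class TestOperatingCharacteristics:
    def test_cutoff_below_all_scores(self):
        roc = build_roc([1.0, 2.0, 3.0], [0, 1, 1])
        assert operating_characteristics(roc, 0.0) == (1.0, 0.0)

    def test_cutoff_above_all_scores(self):
        roc = build_roc([1.0, 2.0, 3.0], [0, 1, 1])
        assert operating_characteristics(roc, 10.0) == (0.0, 1.0)

    def test_candidate_cutoff_reproduces_operating_point(self):
        # six-subject fixture, recounted by hand: at cutoff 2.0 the
        # positives strictly above are {3.1, 4.0} of three -> sens 2/3;
        # all three negatives {0.5, 1.0, 2.0} sit at or below -> spec 1
        scores = [1.0, 2.0, 2.0, 3.1, 4.0, 0.5]
        labels = [0, 0, 1, 1, 1, 0]
        roc = build_roc(scores, labels)
        sens, spec = operating_characteristics(roc, 2.0)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)
        i = int(np.flatnonzero(roc.cutoffs == 2.0)[0])
        assert sens == roc.sensitivity[i]
        assert spec == roc.specificity[i]

    def test_off_grid_cutoff(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        roc = build_roc(scores, labels)
        assert operating_characteristics(roc, 2.5) == (1.0, 1.0)


class TestReferenceP95Table:
    def test_single_subject_covers_all_its_strata(self):
        df = make_cohort_frame([make_subject(age=8.0, tanner=1, insulin=10.0, glucose=4.5)])
        table = derive_reference_p95_table(df)
        for stratum in ["total", "male", "age_6_9", "tanner_I"]:
            assert table.loc[stratum, "p95"] == pytest.approx(2.0)
        assert table.loc["tanner_V", "n"] == 0
        assert np.isnan(table.loc["tanner_V", "p95"])

    def test_overlapping_strata_do_not_partition(self, default_cohort):
        table = derive_reference_p95_table(default_cohort)
        n = table.loc["total", "n"]
        assert table.loc["age_ge10", "n"] == (
            table.loc["age_10_15", "n"] + table.loc["age_ge16", "n"]
        )
        assert table.drop("total")["n"].sum() > n  # rows overlap by design

    def test_pubertal_p95_exceeds_prepubertal(self):
        # consequence of the configured Tanner-band insulin geometric means
        cohort = generate_cohort(GeneratorConfig(n_subjects=4000, seed=3))
        table = derive_reference_p95_table(cohort.data)
        assert table.loc["tanner_ge_II", "p95"] > table.loc["tanner_I", "p95"]

    def test_empty_reference_rejected(self):
        import pandas as pd

        with pytest.raises(EmptyStratumError):
            derive_reference_p95_table(pd.DataFrame(columns=["sex", "age", "tanner", "homa_ir"]))


class TestParameterRecovery:
    def test_youden_cutoff_recovers_density_crossing(self):
        # two equal-log-variance log-normal classes cross at the
        # geometric midpoint exp((mu0 + mu1) / 2); the empirical Youden
        # optimum should concentrate there
        mu0, mu1, sigma = np.log(1.2), np.log(3.0), 0.5
        truth = float(np.exp((mu0 + mu1) / 2))
        errs = []
        for seed in range(5):
            r = np.random.default_rng(1000 + seed)
            scores = np.concatenate(
                [np.exp(r.normal(mu0, sigma, 1000)), np.exp(r.normal(mu1, sigma, 1000))]
            )
            labels = np.repeat([False, True], 1000)
            res = optimal_cutoff(build_roc(scores, labels), "youden")
            errs.append(abs(res.cutoff - truth))
        assert np.mean(errs) < 0.15
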