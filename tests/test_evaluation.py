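"""Agreement metrics, device grading, and Bland–Altman summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsebp import (
    bland_altman,
    compute_metrics,
    cumulative_percent,
    evaluate,
    grade,
    grade_aami,
    grade_bhs,
    grade_ieee,
    mae,
    mean_difference,
    pearson_r,
    sd_error,
)


class TestPearson:
    def test_identity_is_one(self):
        y = np.array([100.0, 110, 120, 130])
        assert pearson_r(y, y) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        y = np.array([100.0, 110, 120, 130])
        assert pearson_r(y, -y + 200) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        y = rng.normal(120, 15, size=1000)
        yhat = y + rng.normal(0, 5, size=1000)
        # definitional loop oracle
        my, mp = sum(y) / 1000, sum(yhat) / 1000
        num = sum((a - my) * (b - mp) for a, b in zip(y, yhat))
        den = (sum((a - my) ** 2 for a in y) ** 0.5) * (
            sum((b - mp) ** 2 for b in yhat) ** 0.5
        )
        assert pearson_r(y, yhat) == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestErrorMetrics:
    def test_hand_worked_example(self):
        y, yhat = [119.0, 121.0], [120.0, 118.0]
        assert mean_difference(y, yhat) == pytest.approx(-1.0)
        assert mae(y, yhat) == pytest.approx(2.0)
        assert sd_error(y, yhat) == pytest.approx(2.0)

    def test_perfect_predictions(self):
        y = [119.0, 121.0]
        assert mean_difference(y, y) == 0.0
        assert mae(y, y) == 0.0
        assert sd_error(y, y) == 0.0

    def test_population_divisor_oracle(self, rng):
        y = rng.normal(120, 15, size=500)
        yhat = y + rng.normal(0, 6, size=500)
        err = [b - a for a, b in zip(y, yhat)]
        md_o = sum(err) / 500
        mae_o = sum(abs(e) for e in err) / 500
        sd_o = (sum((e - md_o) ** 2 for e in err) / 500) ** 0.5  # divisor m
        assert mean_difference(y, yhat) == pytest.approx(md_o, rel=1e-12)
        assert mae(y, yhat) == pytest.approx(mae_o, rel=1e-12)
        assert sd_error(y, yhat) == pytest.approx(sd_o, rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestCumulativePercent:
    def test_counting_example(self):
        y = np.zeros(4)
        yhat = np.array([1.0, 6.0, 12.0, 20.0])
        assert cumulative_percent(y, yhat) == (25.0, 50.0, 75.0)

    def test_all_zero_errors(self):
        assert cumulative_percent([1.0, 2.0], [1.0, 2.0]) == (100.0, 100.0, 100.0)

    def test_threshold_is_inclusive(self):
        assert cumulative_percent([0.0], [5.0])[0] == 100.0


# (CP5, CP10, CP15), MD, MAE, SD, expected BHS/AAMI/IEEE for each published
# prediction-network configuration (systolic rows then diastolic rows)
PUBLISHED_ROWS = [
    ((53.143, 81.489, 92.924), 0.774, 6.061, 8.076, "B", None, "C"),
    ((53.936, 82.218, 93.304), 0.074, 5.962, 7.998, "B", "Pass", "B"),
    ((59.823, 85.919, 94.925), -0.503, 5.306, 7.248, "B", "Pass", "B"),
    ((59.634, 86.001, 94.970), 0.031, 5.317, 7.263, "B", "Pass", "B"),
    ((74.117, 93.649, 98.073), -0.132, 3.812, 5.397, "A", "Pass", "A"),
    ((74.942, 93.778, 98.128), 0.049, 3.767, 5.335, "A", "Pass", "A"),
    ((79.632, 95.213, 98.576), -0.186, 3.328, 4.809, "A", "Pass", "A"),
    ((80.041, 95.418, 98.613), -0.162, 3.296, 4.764, "A", "Pass", "A"),
]


class TestGrading:
    @pytest.mark.parametrize("cp,md,mae_v,sd,bhs,aami,ieee", PUBLISHED_ROWS)
    def test_published_worked_examples(self, cp, md, mae_v, sd, bhs, aami, ieee):
        assert grade_bhs(*cp) == bhs
        assert grade_ieee(mae_v) == ieee
        if aami is not None:
            assert grade_aami(md, sd) == aami

    def test_aami_rule_is_strict_on_sd_bound(self):
        # SD marginally above 8 mmHg fails the printed rule
        assert grade_aami(0.774, 8.076) == "Fail"

    @pytest.mark.parametrize(
        "cp,expected",
        [((60, 85, 95), "A"), ((50, 75, 90), "B"), ((40, 65, 85), "C"),
         ((39.9, 99, 99), "D"), ((59.9, 85, 95), "B")],
    )
    def test_bhs_boundaries_inclusive(self, cp, expected):
        assert grade_bhs(*cp) == expected

    @pytest.mark.parametrize(
        "md,sd,expected",
        [(5.0, 8.0, "Pass"), (-5.0, 8.0, "Pass"), (0, 9, "Fail"),
         (-0.503, 7.248, "Pass"), (5.1, 3, "Fail"), (-5.1, 3, "Fail")],
    )
    def test_aami_boundaries_and_absolute_md(self, md, sd, expected):
        assert grade_aami(md, sd) == expected

    @pytest.mark.parametrize(
        "mae_v,expected",
        [(5.0, "A"), (5.306, "B"), (6.0, "B"), (6.061, "C"), (7.0, "C"),
         (7.001, "D"), (3.296, "A")],
    )
    def test_ieee_bands(self, mae_v, expected):
        assert grade_ieee(mae_v) == expected

    @given(
        cp5=st.floats(0, 100), d10=st.floats(0, 50), d15=st.floats(0, 30),
        bump=st.floats(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_bhs_monotone_in_each_cp(self, cp5, d10, d15, bump):
        cp10 = min(cp5 + d10, 100)
        cp15 = min(cp10 + d15, 100)
        base = grade_bhs(cp5, cp10, cp15)
        better = grade_bhs(
            min(cp5 + bump, 100),
            min(cp10 + bump, 100),
            min(cp15 + bump, 100),
        )
        assert better <= base  # letters compare lexicographically A < B < C < D

    @given(m1=st.floats(0, 20), m2=st.floats(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_ieee_monotone_in_mae(self, m1, m2):
        lo, hi = sorted([m1, m2])
        assert grade_ieee(lo) <= grade_ieee(hi)


class TestBlandAltman:
    def test_perfect_agreement(self):
        ba = bland_altman([119.0, 121.0], [119.0, 121.0])
        assert ba.mean_diff == 0.0
        assert ba.loa_low == ba.loa_high == 0.0
        assert ba.pct_within_5 == 100.0

    def test_hand_example_limits(self):
        ba = bland_altman([119.0, 121.0], [120.0, 118.0])
        assert ba.mean_diff == pytest.approx(-1.0)
        assert ba.loa_low == pytest.approx(-4.92)
        assert ba.loa_high == pytest.approx(2.92)

    def test_bands_match_cumulative_percent(self, rng):
        y = rng.normal(120, 15, size=400)
        yhat = y + rng.normal(0, 7, size=400)
        ba = bland_altman(y, yhat)
        cp5, cp10, cp15 = cumulative_percent(y, yhat)
        assert (ba.pct_within_5, ba.pct_within_10, ba.pct_within_15) == (cp5, cp10, cp15)
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high
        assert ba.ci95_low <= ba.mean_diff <= ba.ci95_high


class TestInvariantProperties:
    @given(st.lists(st.tuples(st.floats(50, 200), st.floats(50, 200)),
                    min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_metric_inequalities(self, pairs):
        y = np.array([p[0] for p in pairs])
        yhat = np.array([p[1] for p in pairs])
        report = compute_metrics(y, yhat)
        assert report.mae >= abs(report.md) - 1e-9
        assert report.cp5 <= report.cp10 <= report.cp15 <= 100.0
        assert report.sd >= 0.0
        if report.r_defined:
            assert -1.0 - 1e-12 <= report.r <= 1.0 + 1e-12


class _StubModel:
    def __init__(self, predictions):
        self._pred = np.asarray(predictions, dtype=float)

    def predict_segments(self, segments):
        return self._pred[: len(segments)]


class TestEvaluate:
    def test_perfect_model_gets_top_grades(self, clean_segments):
        subset = clean_segments[:50]
        model = _StubModel([s.sbp for s in subset])
        report, grades, ba = evaluate(model, subset)
        assert report.r == pytest.approx(1.0)
        assert (grades.bhs, grades.aami, grades.ieee) == ("A", "Pass", "A")
        assert ba.mean_diff == 0.0

    def test_constant_model_flags_undefined_r(self, clean_segments):
        subset = clean_segments[:50]
        model = _StubModel(np.full(50, 120.0))
        report, grades, _ = evaluate(model, subset)
        assert not report.r_defined
        assert np.isnan(report.r)

    def test_empty_test_set_errors(self):
        with pytest.raises(ValueError):
            evaluate(_StubModel([1.0]), [])

    def test_metrics_match_independent_recomputation(self, clean_segments, rng):
        subset = clean_segments[:80]
        y = np.array([s.sbp for s in subset])
        yhat = y + rng.normal(0, 5, size=len(y))
        report, grades, _ = evaluate(_StubModel(yhat), subset)
        err = yhat - y
        assert report.md == pytest.approx(float(np.mean(err)), rel=1e-12)
        assert report.mae == pytest.approx(float(np.mean(np.abs(err))), rel=1e-12)
        assert report.sd == pytest.approx(float(np.std(err)), rel=1e-12)
        regrade = grade(report)
        assert (regrade.bhs, regrade.aami, regrade.ieee) == (
            grades.bhs, grades.aami, grades.ieee,
        )
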