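"""Standard-curve analytics, quantification and the site-positivity rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edna_cooccur import (
    DilutionSeries,
    QpcrWell,
    StandardCurve,
    call_detections,
    compute_lod_loq,
    efficiency_from_slope,
    fit_standard_curve,
    predict_cq,
    quantify,
    quantify_cq,
)

SLOPE, INTERCEPT = -1.526, 41.232


def exact_series(n_levels=8, start=50.0, fold=10.0, n_reps=20):
    """Noiseless dilution series generated from the reference curve."""
    levels = []
    for k in range(n_levels):
        conc = start / fold**k
        cq = SLOPE * math.log(conc) + INTERCEPT
        levels.append((conc, tuple([cq] * n_reps)))
    return DilutionSeries(tuple(levels))


class TestStandardCurve:
    def test_noiseless_fit_recovers_coefficients_exactly(self):
        curve = fit_standard_curve(exact_series())
        assert curve.slope_ln == pytest.approx(SLOPE, abs=1e-12)
        assert curve.intercept == pytest.approx(INTERCEPT, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.valid

    def test_efficiency_value_and_log10_convention(self):
        # oracle: E = 10**(-1/slope10) - 1 with slope10 = slope_ln * ln(10)
        slope10 = SLOPE * math.log(10.0)
        expected = 10.0 ** (-1.0 / slope10) - 1.0
        assert efficiency_from_slope(SLOPE) == pytest.approx(expected, rel=1e-12)
        assert efficiency_from_slope(SLOPE) == pytest.approx(0.926, abs=5e-4)

    def test_predict_cq_at_reference_points(self, paper_curve):
        assert predict_cq(paper_curve, 1.0) == pytest.approx(41.232, abs=1e-12)
        assert predict_cq(paper_curve, math.e) == pytest.approx(
            41.232 - 1.526, abs=1e-12
        )

    def test_predict_cq_rejects_nonpositive_concentration(self, paper_curve):
        with pytest.raises(ValueError):
            predict_cq(paper_curve, 0.0)
        with pytest.raises(ValueError):
            predict_cq(paper_curve, -1.0)

    @given(x=st.floats(min_value=1e-6, max_value=1e6))
    def test_quantify_inverts_predict(self, x):
        curve = StandardCurve(SLOPE, INTERCEPT)
        assert quantify_cq(curve, predict_cq(curve, x)) == pytest.approx(
            x, rel=1e-9
        )

    def test_quantify_reference_values(self, paper_curve):
        assert quantify_cq(paper_curve, 41.232) == pytest.approx(1.0, rel=1e-12)
        assert quantify_cq(paper_curve, 41.232 + 1.526) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )
        well = QpcrWell("P01", 1, "A1", 1, 1, cq=None)
        assert quantify(paper_curve, well).quantity is None

    def test_zero_slope_curve_cannot_quantify(self):
        with pytest.raises(ValueError):
            quantify_cq(StandardCurve(0.0, 40.0), 35.0)

    def test_all_null_series_is_a_fit_error(self):
        series = DilutionSeries(((10.0, (None, None)), (1.0, (None, None))))
        with pytest.raises(ValueError):
            fit_standard_curve(series)

    def test_positive_slope_is_flagged_not_raised(self):
        # Cq rising with concentration: an inverted (invalid) assay
        levels = tuple(
            (conc, (22.0 - i,) * 3)
            for i, conc in enumerate((100.0, 10.0, 1.0))
        )
        with pytest.warns(UserWarning):
            curve = fit_standard_curve(DilutionSeries(levels))
        assert not curve.valid
        assert curve.slope_ln > 0

    def test_concentrations_must_strictly_decrease(self):
        with pytest.raises(ValueError):
            DilutionSeries(((1.0, (30.0,)), (10.0, (28.0,))))


class TestLodLoq:
    def test_all_levels_detected_lod_is_lowest_concentration(self):
        series = exact_series(n_levels=4)
        curve = fit_standard_curve(series)
        lod, loq = compute_lod_loq(series, curve)
        assert lod == min(c for c, _ in series.levels)
        assert loq is not None and lod <= loq

    def test_95_percent_rule_boundary(self, paper_curve):
        # detection 20/20, 20/20, 18/20, 9/20: 18/20 = 0.9 fails the >=0.95
        # rule, so LOD is the second level's concentration
        rates = [20, 20, 18, 9]
        levels = []
        for k, n_amp in enumerate(rates):
            conc = 50.0 / 10.0**k
            cq = SLOPE * math.log(conc) + INTERCEPT
            reps = tuple([cq] * n_amp + [None] * (20 - n_amp))
            levels.append((conc, reps))
        lod, _ = compute_lod_loq(DilutionSeries(tuple(levels)), paper_curve)
        assert lod == 5.0

    def test_no_level_qualifies_gives_null_limits(self, paper_curve):
        levels = (
            (10.0, (30.0,) + (None,) * 19),
            (1.0, (None,) * 20),
        )
        lod, loq = compute_lod_loq(DilutionSeries(levels), paper_curve)
        assert lod is None and loq is None

    def test_high_cv_level_fails_loq_but_not_lod(self, paper_curve):
        # all replicates amplify but back-calculated CV >> 0.35 at level 2
        noisy = tuple(
            SLOPE * math.log(1.0) + INTERCEPT + d
            for d in (-4.0, 0.0, 4.0, -4.0, 0.0, 4.0)
        )
        clean = tuple([SLOPE * math.log(10.0) + INTERCEPT] * 6)
        series = DilutionSeries(((10.0, clean), (1.0, noisy)))
        lod, loq = compute_lod_loq(series, paper_curve)
        assert lod == 1.0
        assert loq == 10.0


def wells_for_rule(cqs, lod_curve):
    """One site-month of 3x3 replicates for species A1; cqs maps
    (bio, tech) -> Cq."""
    wells = []
    for bio in (1, 2, 3):
        for tech in (1, 2, 3):
            wells.append(
                QpcrWell("P01", 1, "A1", bio, tech, cq=cqs.get((bio, tech)))
            )
    return wells


class TestDetectionRule:
    def cq_for(self, curve, quantity):
        return predict_cq(curve, quantity)

    def test_two_technical_positives_of_one_sample_detect(self, paper_curve):
        cq = self.cq_for(paper_curve, 10 * paper_curve.lod)
        calls, _ = call_detections(
            wells_for_rule({(1, 1): cq, (1, 2): cq}, paper_curve), paper_curve
        )
        (call,) = calls
        assert call.detected and call.basis == "technical"
        assert call.n_positive_replicates == 2

    def test_two_biological_positives_detect(self, paper_curve):
        cq = self.cq_for(paper_curve, 10 * paper_curve.lod)
        calls, _ = call_detections(
            wells_for_rule({(1, 1): cq, (2, 3): cq}, paper_curve), paper_curve
        )
        (call,) = calls
        assert call.detected and call.basis == "biological"

    def test_single_positive_is_not_detected(self, paper_curve):
        cq = self.cq_for(paper_curve, 10 * paper_curve.lod)
        calls, _ = call_detections(
            wells_for_rule({(2, 2): cq}, paper_curve), paper_curve
        )
        (call,) = calls
        assert not call.detected
        assert call.n_positive_replicates == 1

    def test_amplification_at_or_below_lod_is_not_positive(self, paper_curve):
        cq = self.cq_for(paper_curve, paper_curve.lod / 2)
        calls, _ = call_detections(
            wells_for_rule({(1, 1): cq, (1, 2): cq, (2, 1): cq}, paper_curve),
            paper_curve,
        )
        (call,) = calls
        assert not call.detected
        assert call.n_positive_replicates == 0

    def test_pooled_and_strict_modes_agree(self, paper_curve):
        cq = self.cq_for(paper_curve, 10 * paper_curve.lod)
        wells = wells_for_rule({(1, 1): cq, (2, 3): cq}, paper_curve)
        pooled, _ = call_detections(wells, paper_curve, mode="pooled")
        strict, _ = call_detections(wells, paper_curve, mode="strict")
        assert [c.detected for c in pooled] == [c.detected for c in strict]

    @given(
        pos=st.lists(
            st.tuples(st.integers(1, 3), st.integers(1, 3)),
            unique=True, max_size=8,
        ),
        extra=st.tuples(st.integers(1, 3), st.integers(1, 3)),
    )
    def test_adding_a_positive_never_undetects(self, pos, extra):
        from edna_cooccur import default_standard_curve

        curve = default_standard_curve()
        cq = predict_cq(curve, 10 * curve.lod)
        before, _ = call_detections(
            wells_for_rule({k: cq for k in pos}, curve), curve
        )
        after, _ = call_detections(
            wells_for_rule({k: cq for k in set(pos) | {extra}}, curve), curve
        )
        assert after[0].detected >= before[0].detected

    def test_missing_curve_for_species_is_an_error(self, paper_curve):
        wells = wells_for_rule({}, paper_curve)
        with pytest.raises(KeyError):
            call_detections(wells, {"F1": paper_curve})

    def test_undefined_lod_is_an_error(self):
        curve = StandardCurve(SLOPE, INTERCEPT, lod=None)
        with pytest.raises(ValueError):
            call_detections(wells_for_rule({}, curve), curve)

    def test_site_months_without_wells_are_missing(self, paper_curve):
        cq = predict_cq(paper_curve, 10 * paper_curve.lod)
        wells = [
            QpcrWell("P01", 1, "A1", 1, 1, cq=cq),
            QpcrWell("P01", 1, "A1", 1, 2, cq=cq),
            QpcrWell("P02", 2, "A1", 1, 1, cq=None),
        ]
        _, matrix = call_detections(wells, paper_curve)
        # P01 month 2 and P02 month 1 were never sampled
        assert np.isnan(matrix.state[0, matrix.site_ids.index("P01"), 1])
        assert np.isnan(matrix.state[0, matrix.site_ids.index("P02"), 0])
        assert matrix.state[0, matrix.site_ids.index("P01"), 0] == 1.0
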