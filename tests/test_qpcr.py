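"""Standard curves, copy quantification, deletion levels, QC gates and
paired region comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofoci.errors import CurveError, ParameterError, QCError
from mitofoci.qpcr import (
    RegionQuant,
    analyze_plate,
    deletion_level,
    dloop_nd1_check,
    fit_standard_curve,
    ntc_filter,
    paired_region_analysis,
    quantify_copies,
)
from mitofoci.synthetic import (
    QpcrSimParams,
    simulate_qpcr_plate,
    simulate_region_truth,
)

PERFECT_SLOPE = -1.0 / np.log10(2.0)  # exact doubling each cycle


def _standards(slope, intercept, copies=(1e6, 1e5, 1e4, 1e3, 1e2)):
    return [(c, intercept + slope * np.log10(c)) for c in copies]


class TestStandardCurve:
    def test_perfect_efficiency_passes_qc(self):
        curve = fit_standard_curve(_standards(-3.3219, 40.0), "ND1")
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.qc_pass and curve.r_squared == pytest.approx(1.0)

    def test_low_efficiency_fails_qc(self):
        # slope -3.45 -> efficiency 10**(1/3.45) - 1 = 0.9492, below 95%
        curve = fit_standard_curve(_standards(-3.45, 40.0))
        assert curve.efficiency == pytest.approx(0.94919403, abs=1e-6)
        assert not curve.qc_pass

    def test_noise_free_recovery(self):
        curve = fit_standard_curve(_standards(-3.5, 37.2))
        assert curve.slope == pytest.approx(-3.5, abs=1e-9)
        assert curve.intercept == pytest.approx(37.2, abs=1e-9)

    def test_positive_slope_rejected(self):
        with pytest.raises(CurveError):
            fit_standard_curve(_standards(3.3, 40.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_standard_curve(_standards(-3.3, 40.0, copies=(1e5, 1e4, 1e3)))

    def test_non_decreasing_series_rejected(self):
        pts = _standards(-3.3, 40.0)
        with pytest.raises(ParameterError):
            fit_standard_curve(pts[::-1])


class TestQuantifyCopies:
    def test_intercept_is_one_copy(self):
        curve = fit_standard_curve(_standards(PERFECT_SLOPE, 40.0))
        assert quantify_copies(40.0, curve) == pytest.approx(1.0, rel=1e-9)

    def test_ten_cycles_is_1024_fold(self):
        curve = fit_standard_curve(_standards(PERFECT_SLOPE, 40.0))
        assert quantify_copies(30.0, curve) == pytest.approx(1024.0, rel=1e-9)

    def test_failed_curve_blocks_without_override(self):
        curve = fit_standard_curve(_standards(-3.45, 40.0))
        with pytest.raises(QCError):
            quantify_copies(30.0, curve)
        assert quantify_copies(40.0, curve, override_qc=True) == pytest.approx(1.0)


class TestDeletionLevel:
    @pytest.mark.parametrize(
        "nd1,nd4,expected",
        [
            (1000.0, 1000.0, 0.0),  # no deletion
            (1000.0, 0.0, 100.0),  # every molecule deleted
            (1000.0, 1200.0, 0.0),  # negative raw value clipped to zero
            (1000.0, 500.0, 50.0),
        ],
    )
    def test_scale(self, nd1, nd4, expected):
        assert deletion_level(nd1, nd4) == expected

    def test_zero_nd1_undefined(self):
        assert np.isnan(deletion_level(0.0, 100.0))

    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, nd1, nd4, c):
        assert deletion_level(c * nd1, c * nd4) == pytest.approx(
            deletion_level(nd1, nd4), abs=1e-6
        )


class TestDloopCheck:
    def test_normal_ratio_unflagged(self):
        ratio, flag = dloop_nd1_check(100.0, 100.0)
        assert ratio == 1.0 and not flag

    def test_high_ratio_flagged_when_intact(self):
        ratio, flag = dloop_nd1_check(300.0, 100.0, nd1_intact=True)
        assert ratio == 3.0 and flag

    def test_check_skipped_when_nd1_deleted(self):
        _, flag = dloop_nd1_check(300.0, 100.0, nd1_intact=False)
        assert not flag


def _mean_cq_frame(rows):
    return pd.DataFrame(
        rows, columns=["region_id", "fiber_id", "region_kind", "target", "Cq"]
    )


class TestNtcFilter:
    def test_margin_pass_and_fail(self):
        df = _mean_cq_frame(
            [
                ("r1", "f1", "focus", "ND1", 30.0),
                ("r2", "f2", "focus", "ND1", 32.0),
            ]
        )
        out = ntc_filter(df, ntc_cq=34.0, margin_cycles=3.0)
        assert out == {"f1": True, "f2": False}

    def test_one_failing_region_fails_whole_fiber(self):
        df = _mean_cq_frame(
            [
                ("foc", "f1", "focus", "ND1", 28.0),
                ("m1", "f1", "matched_positive", "ND1", 33.0),
            ]
        )
        assert ntc_filter(df, ntc_cq=34.0) == {"f1": False}

    def test_sentinel_ntc_passes_amplified_regions(self):
        df = _mean_cq_frame(
            [
                ("a", "f1", "focus", "ND1", 30.0),
                ("b", "f2", "focus", "ND1", np.nan),
            ]
        )
        assert ntc_filter(df, ntc_cq=None) == {"f1": True, "f2": False}

    def test_tightening_margin_is_monotone(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"r{i}", f"f{i}", "focus", "ND1", float(rng.uniform(28, 34)))
            for i in range(30)
        ]
        df = _mean_cq_frame(rows)
        passing = [
            sum(ntc_filter(df, ntc_cq=34.0, margin_cycles=m).values())
            for m in (0.0, 1.0, 2.0, 3.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(passing, passing[1:]))


def _quant(region_id, fiber_id, kind, dloop, nd1, dl, ntc_pass=True):
    return RegionQuant(
        region_id=region_id,
        fiber_id=fiber_id,
        region_kind=kind,
        copies={"DLoop": dloop, "ND1": nd1, "ND4": nd1 * (1 - dl / 100)},
        mean_cq={},
        deletion_level=dl,
        dloop_nd1_ratio=dloop / nd1,
        ntc_pass=ntc_pass,
    )


class TestPairedAnalysis:
    def test_identical_pairs_are_null(self):
        quants = []
        for i in range(4):
            f = f"f{i}"
            quants += [
                _quant(f"{f}_F", f, "focus", 100.0, 100.0, 20.0),
                _quant(f"{f}_M1", f, "matched_positive", 100.0, 100.0, 20.0),
                _quant(f"{f}_M2", f, "matched_positive", 100.0, 100.0, 20.0),
            ]
        res = paired_region_analysis(quants)
        assert res.mean_folds["DLoop"] == pytest.approx(1.0)
        assert res.paired_tests["DLoop"].p == 1.0
        assert res.paired_tests["DLoop"].degenerate

    def test_balanced_differences_give_null_t(self):
        # focus-minus-matched differences {+1, -1} -> t = 0, p = 1
        quants = [
            _quant("a_F", "a", "focus", 101.0, 101.0, 0.0),
            _quant("a_M1", "a", "matched_positive", 100.0, 100.0, 0.0),
            _quant("b_F", "b", "focus", 99.0, 99.0, 0.0),
            _quant("b_M1", "b", "matched_positive", 100.0, 100.0, 0.0),
        ]
        res = paired_region_analysis(quants)
        assert res.paired_tests["DLoop"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res.paired_tests["DLoop"].p == pytest.approx(1.0)

    def test_ntc_failing_fiber_excluded(self):
        quants = [
            _quant("a_F", "a", "focus", 200.0, 200.0, 50.0),
            _quant("a_M1", "a", "matched_positive", 100.0, 100.0, 10.0),
            _quant("b_F", "b", "focus", 200.0, 200.0, 50.0, ntc_pass=False),
            _quant("b_M1", "b", "matched_positive", 100.0, 100.0, 10.0, ntc_pass=False),
        ]
        res = paired_region_analysis(quants)
        assert res.excluded_fibers == ["b"]
        assert res.n_pairs == 1

    def test_unmatched_focus_excluded(self):
        quants = [_quant("a_F", "a", "focus", 100.0, 100.0, 10.0)]
        res = paired_region_analysis(quants)
        assert res.n_pairs == 0 and res.excluded_fibers == ["a"]


class TestEndToEnd:
    def test_zero_noise_round_trip(self):
        truth = simulate_region_truth(n_pairs=8, seed=5)
        plate = simulate_qpcr_plate(truth, QpcrSimParams(noise_sd=0.0, seed=5))
        curves, quants, _ = analyze_plate(plate)
        by_id = {r.region_id: r for r in truth.regions}
        for q in quants:
            for target, copies in q.copies.items():
                true = by_id[q.region_id].copies[target]
                if true > 0:
                    assert copies == pytest.approx(true, rel=1e-6)
            true_dl = deletion_level(
                by_id[q.region_id].copies["ND1"], by_id[q.region_id].copies["ND4"]
            )
            assert q.deletion_level == pytest.approx(true_dl, abs=1e-6)

    def test_plate_missing_standards_rejected(self):
        truth = simulate_region_truth(n_pairs=2, seed=0)
        plate = simulate_qpcr_plate(truth, QpcrSimParams(noise_sd=0.0))
        with pytest.raises(ParameterError):
            analyze_plate(plate[plate["region_kind"] != "standard"])
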