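"""Perinuclear thresholding, focal classification and prevalence summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofoci.annotation import (
    DomainAnnotation,
    FiberClass,
    annotate_cohort,
    annotate_perinuclear,
    circular_runs,
    classify_deficient_points,
    classify_fiber,
    cohort_dapi_threshold,
    filter_short_runs,
    prevalence_summary,
)
from mitofoci.errors import ClassificationError, ParameterError
from mitofoci.io import intervals_to_mask
from mitofoci.profiling import PerimeterProfile, profile_cohort


def _profile(dapi=None, sdha=None, mtcoi=None, n=None):
    chans = {"DAPI": dapi, "SDHA": sdha, "MTCOI": mtcoi}
    chans = {k: np.asarray(v, float) for k, v in chans.items() if v is not None}
    n = n or len(next(iter(chans.values())))
    return PerimeterProfile(
        fiber_id="T0",
        arc_fractions=np.arange(n) / n,
        raw={k: v.copy() for k, v in chans.items()},
        corrected=chans,
        perimeter_px=float(n),
    )


class TestCohortThreshold:
    def test_linear_interpolation_quantile(self):
        prof = _profile(dapi=np.arange(1.0, 101.0))
        assert cohort_dapi_threshold([prof], q=0.85) == pytest.approx(85.15)

    def test_constant_pool_gives_empty_mask(self):
        prof = _profile(dapi=np.full(50, 7.0))
        thr = cohort_dapi_threshold([prof], q=0.85)
        assert thr == 7.0
        # strict '>' rule: ties are excluded
        assert not annotate_perinuclear(prof, thr).any()

    def test_limit_q_approaches_maximum(self):
        prof = _profile(dapi=np.arange(1.0, 101.0))
        assert cohort_dapi_threshold([prof], q=1 - 1e-12) == pytest.approx(100.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ParameterError):
            cohort_dapi_threshold([], q=0.85)

    def test_raising_q_shrinks_perinuclear_fraction(self, zero_noise_cohort):
        sections, _ = zero_noise_cohort
        profiles = profile_cohort(sections)
        fractions = []
        for q in (0.7, 0.8, 0.9, 0.95):
            thr = cohort_dapi_threshold(profiles, q=q)
            masks = [annotate_perinuclear(p, thr) for p in profiles]
            fractions.append(np.mean([m.mean() for m in masks]))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestPerinuclearMask:
    def test_all_below_threshold(self):
        prof = _profile(dapi=np.zeros(40))
        mask = annotate_perinuclear(prof, threshold=1.0)
        assert not mask.any()

    def test_wraparound_run_is_single(self):
        mask = np.zeros(50, bool)
        mask[[48, 49, 0, 1]] = True
        runs = circular_runs(mask)
        assert runs == [(48, 4)]

    def test_short_runs_removed(self):
        prof = _profile(dapi=np.zeros(40))
        prof.corrected["DAPI"][[5, 20, 21, 22, 23]] = 10.0
        mask = annotate_perinuclear(prof, threshold=1.0, min_run=3)
        assert not mask[5]
        assert mask[20:24].all()

    def test_single_nucleus_single_run(self, zero_noise_cohort):
        sections, truth = zero_noise_cohort
        profiles = profile_cohort(sections)
        thr = cohort_dapi_threshold(profiles)
        for prof, ft in zip(profiles, truth.fibers):
            if len(ft.nucleus_fractions) != 1:
                continue
            mask = annotate_perinuclear(prof, thr)
            runs = circular_runs(mask)
            assert len(runs) == 1
            u = ft.nucleus_fractions[0]
            assert mask[int(round(u * prof.n_samples)) % prof.n_samples]


class TestDeficientPoints:
    def test_uniform_channels_all_negative(self):
        prof = _profile(sdha=np.full(60, 100.0), mtcoi=np.full(60, 100.0))
        assert not classify_deficient_points(prof).any()

    def test_zero_noise_focus_recovered(self, zero_noise_cohort):
        sections, truth = zero_noise_cohort
        profiles = profile_cohort(sections)
        for prof, ft in zip(profiles, truth.fibers):
            mask = classify_deficient_points(prof)
            tm = intervals_to_mask(ft.focus_intervals, prof.arc_fractions)
            if not ft.focus_intervals:
                assert not mask.any()
                continue
            # detected focal run must match the true arc within 2 samples
            # at each edge
            mismatch = mask ^ tm
            assert mismatch.sum() <= 4

    def test_manual_mask_precedence(self):
        prof = _profile(sdha=np.full(30, 100.0), mtcoi=np.full(30, 100.0))
        manual = np.zeros(30, bool)
        manual[10:15] = True
        out = classify_deficient_points(prof, manual_mask=manual)
        assert np.array_equal(out, manual)

    def test_dead_sdha_channel_rejected(self):
        prof = _profile(sdha=np.zeros(30), mtcoi=np.full(30, 10.0))
        with pytest.raises(ClassificationError):
            classify_deficient_points(prof)


class TestDomainAnnotation:
    @given(
        st.integers(min_value=4, max_value=200).flatmap(
            lambda n: st.tuples(
                st.lists(st.booleans(), min_size=n, max_size=n),
                st.lists(st.booleans(), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_fraction_invariants(self, masks):
        peri, focal = masks
        ann = DomainAnnotation("H", np.array(peri), np.array(focal))
        assert ann.P == np.mean(peri)
        assert ann.F == np.mean(focal)
        assert ann.O <= min(ann.P, ann.F) + 1e-12

    def test_mask_length_mismatch(self):
        with pytest.raises(ParameterError):
            DomainAnnotation("X", np.zeros(5, bool), np.zeros(6, bool))


class TestFiberClass:
    @pytest.mark.parametrize(
        "F,label,has_focus",
        [
            (1.0, "fully COX-deficient", False),
            (0.96, "fully COX-deficient", False),
            (0.2, "COX-positive", True),
            (0.0, "COX-positive", False),
            (0.6, "intermediate", False),
        ],
    )
    def test_classification(self, F, label, has_focus):
        n = 100
        focal = np.zeros(n, bool)
        focal[: int(round(F * n))] = True
        ann = DomainAnnotation("X", np.zeros(n, bool), focal)
        cls = classify_fiber(ann)
        assert cls.label == label and cls.has_focus == has_focus
        if cls.has_focus:
            assert cls.label == "COX-positive"


class TestPrevalence:
    def test_counts_and_ratios(self):
        classes = (
            [FiberClass("COX-positive", True)] * 2
            + [FiberClass("fully COX-deficient", False)] * 100
            + [FiberClass("COX-positive", False)] * 898
        )
        s = prevalence_summary(classes)
        assert s["percent_foci"] == pytest.approx(0.2)
        assert s["percent_fully_deficient"] == pytest.approx(10.0)
        assert s["foci_to_total"] == "1:500"
        assert s["foci_to_fully_deficient"] == "1:50"

    def test_zero_foci_undefined(self):
        s = prevalence_summary([FiberClass("COX-positive", False)] * 10)
        assert s["percent_foci"] == 0.0
        assert s["foci_to_total"] == "undefined"

    def test_single_fiber_with_focus(self):
        s = prevalence_summary([FiberClass("COX-positive", True)])
        assert s["percent_foci"] == 100.0
        assert s["foci_to_total"] == "1:1"

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            prevalence_summary([])


def test_filter_short_runs_wraparound():
    mask = np.zeros(30, bool)
    mask[[29, 0]] = True  # wraparound run of length 2
    assert not filter_short_runs(mask, 3).any()
    assert filter_short_runs(mask, 2).sum() == 2


def test_cohort_annotation_recovers_ground_truth(zero_noise_cohort):
    sections, truth = zero_noise_cohort
    profiles = profile_cohort(sections)
    annotations = annotate_cohort(profiles)
    for ann, prof, ft in zip(annotations, profiles, truth.fibers):
        for u in ft.nucleus_fractions:
            idx = int(round(u * prof.n_samples)) % prof.n_samples
            assert ann.perinuclear[idx]
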