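"""Triplex qPCR quantification of mtDNA copy number and deletion level.

Copy numbers per microdissected region are read off a plasmid standard
curve, Cq = intercept + slope * log10(copies), fitted per target and per
plate by least squares. QC gates follow the assay's design: the standard
curve must show 95-100% amplification efficiency; every region of a fiber
must amplify ND1 at least three cycles below the no-template control; and
D-Loop/ND1 ratios in ND1-intact regions guard against D-Loop triplex
artifacts. The major-arc deletion level is (1 - ND4/ND1) * 100, clipped
to [0, 100] (negative raw values, which can arise when ND1 itself is
deleted, are shown as zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CurveError, ParameterError, QCError
from .stats import TestResult, paired_t, unpaired_t

logger = logging.getLogger("mitofoci")

__all__ = [
    "StandardCurve",
    "RegionQuant",
    "PairedAnalysisResult",
    "fit_standard_curve",
    "fit_plate_curves",
    "quantify_copies",
    "aggregate_replicates",
    "quantify_regions",
    "ntc_filter",
    "deletion_level",
    "dloop_nd1_check",
    "paired_region_analysis",
    "analyze_plate",
]

# printed-precision slopes (e.g. -3.3219 for perfect doubling) land a hair
# above 100% efficiency; tolerate that at the upper bound only
_EFF_TOL = 1e-4


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear standard curve for one target.

    ``efficiency`` is the per-cycle amplification gain minus one,
    10**(-1/slope) - 1; ``qc_pass`` requires it to lie in
    [eff_lo, eff_hi] (95-100% by default).
    """

    target: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    qc_pass: bool


@dataclass
class RegionQuant:
    """Copy numbers and deletion level for one region, with QC flags."""

    region_id: str
    fiber_id: str
    region_kind: str
    copies: dict[str, float]
    mean_cq: dict[str, float]
    deletion_level: float
    dloop_nd1_ratio: float
    ntc_pass: bool = True
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(
    standards,
    target: str = "",
    eff_lo: float = 0.95,
    eff_hi: float = 1.00,
) -> StandardCurve:
    """Least-squares fit of mean Cq on log10(copies) for a dilution series.

    ``standards`` is a sequence of (copies, mean Cq) pairs with at least
    4 points and strictly decreasing copies.
    """
    arr = np.asarray(list(standards), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 4:
        raise ParameterError("standard curve needs >= 4 dilution points")
    copies, cq = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(copies) < 0):
        raise ParameterError("standard copies must be strictly decreasing")
    res = sps.linregress(np.log10(copies), cq)
    if res.slope >= 0:
        raise CurveError(f"standard curve slope {res.slope:.3f} is not negative")
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    qc = eff_lo <= eff <= (eff_hi + _EFF_TOL)
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(eff),
        qc_pass=bool(qc),
    )


def quantify_copies(cq: float, curve: StandardCurve, override_qc: bool = False) -> float:
    """Invert the standard curve: copies = 10**((Cq - intercept)/slope)."""
    if not curve.qc_pass and not override_qc:
        raise QCError(
            f"standard curve for {curve.target} failed efficiency QC "
            f"({curve.efficiency:.1%})"
        )
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def aggregate_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per (region, target) across replicates.

    No-amplification wells (NaN Cq) are ignored within a triplicate; a
    (region, target) whose replicates all failed keeps NaN."""
    g = plate.groupby(["region_id", "fiber_id", "region_kind", "target"], sort=False)
    return g["Cq"].mean().reset_index()


def deletion_level(nd1_copies: float, nd4_copies: float) -> float:
    """Major-arc deletion level: (1 - ND4/ND1) * 100, clipped to [0, 100].

    0 means no ND4 deletion; 100 means every mtDNA molecule lacks ND4.
    Undefined (NaN) when ND1 copies are not positive.
    """
    if not nd1_copies > 0:
        return float("nan")
    return float(np.clip((1.0 - nd4_copies / nd1_copies) * 100.0, 0.0, 100.0))


def dloop_nd1_check(
    dloop_copies: float,
    nd1_copies: float,
    tolerance_fold: float = 2.0,
    nd1_intact: bool = True,
) -> tuple[float, bool]:
    """D-Loop/ND1 ratio with a triplex-artifact flag.

    Flag raised when the ratio exceeds ``tolerance_fold`` in a region
    believed ND1-intact; the check is skipped (never flags) otherwise.
    """
    ratio = float(dloop_copies / nd1_copies) if nd1_copies > 0 else float("nan")
    flag = bool(nd1_intact and np.isfinite(ratio) and ratio > tolerance_fold)
    return ratio, flag


def fit_plate_curves(
    plate: pd.DataFrame, eff_lo: float = 0.95, eff_hi: float = 1.00
) -> dict[str, StandardCurve]:
    """Fit one standard curve per target from the plate's standard wells
    (region ids of the form ``STD_<copies>``)."""
    std = plate[plate["region_kind"] == "standard"]
    if std.empty:
        raise ParameterError("plate contains no standard wells")
    curves = {}
    for target, grp in std.groupby("target", sort=False):
        agg = grp.groupby("region_id")["Cq"].mean()
        copies = np.array([float(r.split("_", 1)[1]) for r in agg.index])
        order = np.argsort(-copies)
        pts = list(zip(copies[order], agg.to_numpy()[order]))
        curves[target] = fit_standard_curve(pts, target, eff_lo, eff_hi)
    return curves


def ntc_filter(
    mean_cq: pd.DataFrame,
    ntc_cq: float | None,
    margin_cycles: float = 3.0,
    target: str = "ND1",
) -> dict[str, bool]:
    """Per-fiber-group NTC gate.

    A fiber group passes iff every one of its regions has a mean ``target``
    Cq at least ``margin_cycles`` below the no-template control Cq. A
    sentinel NTC (None/NaN: the control never amplified) passes any region
    that itself amplified. Failing groups are excluded from paired analyses.
    """
    sub = mean_cq[(mean_cq["target"] == target) & (mean_cq["fiber_id"] != "")]
    out: dict[str, bool] = {}
    for fiber, grp in sub.groupby("fiber_id", sort=False):
        cqs = grp["Cq"].to_numpy(dtype=float)
        if ntc_cq is None or not np.isfinite(ntc_cq):
            out[fiber] = bool(np.all(np.isfinite(cqs)))
        else:
            out[fiber] = bool(
                np.all(np.isfinite(cqs)) and np.all(cqs <= ntc_cq - margin_cycles)
            )
    return out


def quantify_regions(
    plate: pd.DataFrame,
    curves: dict[str, StandardCurve],
    ntc_margin_cycles: float = 3.0,
    dloop_tolerance_fold: float = 2.0,
    override_qc: bool = False,
) -> list[RegionQuant]:
    """Copy numbers, deletion levels and QC flags for every sample region.

    Replicate Cq values are averaged before the log-linear transform.
    """
    mean_cq = aggregate_replicates(plate)
    ntc_rows = mean_cq[mean_cq["region_kind"] == "NTC"]
    ntc_nd1 = None
    nd1_ntc_rows = ntc_rows[ntc_rows["target"] == "ND1"]
    if not nd1_ntc_rows.empty:
        v = float(nd1_ntc_rows["Cq"].iloc[0])
        ntc_nd1 = v if np.isfinite(v) else None
    sample_rows = mean_cq[~mean_cq["region_kind"].isin(["standard", "NTC"])]
    ntc_ok = ntc_filter(sample_rows, ntc_nd1, ntc_margin_cycles)

    quants = []
    for region_id, grp in sample_rows.groupby("region_id", sort=False):
        cq_by_target = dict(zip(grp["target"], grp["Cq"]))
        copies = {}
        flags = []
        for target, cq in cq_by_target.items():
            if target not in curves:
                flags.append(f"no_curve_{target}")
                continue
            if not np.isfinite(cq):
                copies[target] = 0.0
                flags.append(f"no_amplification_{target}")
                continue
            copies[target] = quantify_copies(cq, curves[target], override_qc)
        nd1 = copies.get("ND1", 0.0)
        nd4 = copies.get("ND4", 0.0)
        dl = deletion_level(nd1, nd4)
        if not np.isfinite(dl):
            flags.append("deletion_undefined")
        nd1_intact = np.isfinite(dl) and dl < 95.0
        ratio, artifact = dloop_nd1_check(
            copies.get("DLoop", 0.0), nd1, dloop_tolerance_fold, nd1_intact
        )
        if artifact:
            flags.append("dloop_nd1_ratio_high")
        fiber_id = str(grp["fiber_id"].iloc[0])
        quants.append(
            RegionQuant(
                region_id=str(region_id),
                fiber_id=fiber_id,
                region_kind=str(grp["region_kind"].iloc[0]),
                copies=copies,
                mean_cq={t: float(c) for t, c in cq_by_target.items()},
                deletion_level=dl,
                dloop_nd1_ratio=ratio,
                ntc_pass=ntc_ok.get(fiber_id, True),
                flags=flags,
            )
        )
    return quants


@dataclass
class PairedAnalysisResult:
    """Focus vs matched-region paired comparison plus whole-fiber groups."""

    pairs: pd.DataFrame
    mean_folds: dict[str, float]
    paired_tests: dict[str, TestResult]
    whole_fiber_tests: dict[str, TestResult]
    n_pairs: int
    excluded_fibers: list[str]


def paired_region_analysis(
    quants: list[RegionQuant], apply_ntc_filter: bool = True
) -> PairedAnalysisResult:
    """Within-fiber focus vs matched-region comparison.

    Per fiber the fold is focus / mean(matched regions) for D-Loop copies,
    ND1 copies and deletion level; significance is a two-tailed paired t
    on the within-fiber differences. Whole-fiber deficient vs positive
    groups are compared with two-tailed unpaired t tests. Fibers failing
    the NTC gate, and foci without matched regions, are excluded.
    """
    excluded = sorted(
        {q.fiber_id for q in quants if apply_ntc_filter and not q.ntc_pass}
    )
    usable = [q for q in quants if q.fiber_id not in excluded]

    def metric(q: RegionQuant, name: str) -> float:
        if name == "deletion":
            return q.deletion_level
        return q.copies.get(name, np.nan)

    rows = []
    by_fiber: dict[str, dict[str, list[RegionQuant]]] = {}
    for q in usable:
        by_fiber.setdefault(q.fiber_id, {}).setdefault(q.region_kind, []).append(q)
    for fiber, kinds in sorted(by_fiber.items()):
        foci = kinds.get("focus", [])
        matched = kinds.get("matched_positive", [])
        if not foci:
            continue
        if not matched:
            logger.warning("fiber %s: focus without matched regions; excluded", fiber)
            excluded.append(fiber)
            continue
        focus = foci[0]
        row = {"fiber_id": fiber}
        for name in ("DLoop", "ND1", "deletion"):
            fv = metric(focus, name)
            mv = float(np.nanmean([metric(m, name) for m in matched]))
            row[f"focus_{name}"] = fv
            row[f"matched_{name}"] = mv
            row[f"fold_{name}"] = fv / mv if mv > 0 else np.nan
        rows.append(row)
    pairs = pd.DataFrame(rows)

    mean_folds: dict[str, float] = {}
    paired: dict[str, TestResult] = {}
    if len(pairs) >= 2:
        for name in ("DLoop", "ND1", "deletion"):
            folds = pairs[f"fold_{name}"].to_numpy(dtype=float)
            finite = folds[np.isfinite(folds)]
            mean_folds[name] = float(finite.mean()) if finite.size else float("nan")
            paired[name] = paired_t(
                pairs[f"focus_{name}"].to_numpy(dtype=float),
                pairs[f"matched_{name}"].to_numpy(dtype=float),
            )

    whole: dict[str, TestResult] = {}
    pos = [q for q in usable if q.region_kind == "whole_fiber_positive"]
    neg = [q for q in usable if q.region_kind == "whole_fiber_deficient"]
    if len(pos) >= 2 and len(neg) >= 2:
        for name in ("DLoop", "ND1", "deletion"):
            whole[name] = unpaired_t(
                [metric(q, name) for q in neg], [metric(q, name) for q in pos]
            )
    return PairedAnalysisResult(
        pairs=pairs,
        mean_folds=mean_folds,
        paired_tests=paired,
        whole_fiber_tests=whole,
        n_pairs=len(pairs),
        excluded_fibers=sorted(set(excluded)),
    )


def analyze_plate(
    plate: pd.DataFrame,
    eff_lo: float = 0.95,
    eff_hi: float = 1.00,
    ntc_margin_cycles: float = 3.0,
    dloop_tolerance_fold: float = 2.0,
    override_qc: bool = False,
) -> tuple[dict[str, StandardCurve], list[RegionQuant], PairedAnalysisResult]:
    """End-to-end plate analysis: curves -> region quantification ->
    NTC-gated paired comparisons."""
    curves = fit_plate_curves(plate, eff_lo, eff_hi)
    quants = quantify_regions(
        plate, curves, ntc_margin_cycles, dloop_tolerance_fold, override_qc
    )
    result = paired_region_analysis(quants)
    return curves, quants, result
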