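"""Perinuclear and focal-deficiency annotation of perimeter profiles.

Perinuclear perimeter domains are perimeter samples whose corrected DAPI
intensity strictly exceeds a cohort-level quantile threshold (0.85 by
default, pooled over every sample of every fiber in the cohort). Focal
COX deficiency is taken from manual annotations when supplied; otherwise
an automated surrogate flags samples where the MTCOI/SDHA ratio collapses
while SDHA stays high (deficiency with preserved mitochondrial mass).
All masks are circular: runs wrap across the arc origin, and runs shorter
than ``min_run`` samples are suppressed as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError, ParameterError
from .io import AnalysisConfig
from .profiling import PerimeterProfile

__all__ = [
    "DomainAnnotation",
    "FiberClass",
    "circular_runs",
    "filter_short_runs",
    "cohort_dapi_threshold",
    "annotate_perinuclear",
    "classify_deficient_points",
    "annotate_cohort",
    "classify_fiber",
    "prevalence_summary",
]


@dataclass
class DomainAnnotation:
    """Boolean perinuclear and focal masks for one fiber, plus the derived
    perimeter fractions P (perinuclear), F (focal) and O (overlap).

    Always satisfies P = mean(perinuclear), F = mean(focal),
    O = mean(perinuclear & focal), hence O <= min(P, F).
    """

    fiber_id: str
    perinuclear: np.ndarray
    focal: np.ndarray
    perimeter_px: float = float("nan")
    P: float = field(init=False)
    F: float = field(init=False)
    O: float = field(init=False)

    def __post_init__(self) -> None:
        self.perinuclear = np.asarray(self.perinuclear, dtype=bool)
        self.focal = np.asarray(self.focal, dtype=bool)
        if self.perinuclear.shape != self.focal.shape:
            raise ParameterError("masks must have equal length")
        self.P = float(self.perinuclear.mean())
        self.F = float(self.focal.mean())
        self.O = float((self.perinuclear & self.focal).mean())


@dataclass(frozen=True)
class FiberClass:
    """Whole-fiber COX status.

    ``label`` is one of ``COX-positive``, ``intermediate`` or
    ``fully COX-deficient``; ``has_focus`` marks a circumscribed deficient
    region within an otherwise COX-positive fiber (so ``has_focus`` implies
    ``label == "COX-positive"``).
    """

    label: str
    has_focus: bool


def circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal true runs of a circular boolean mask as (start, length)
    pairs; a run crossing the origin is reported once, with its true
    (wrapped) start index."""
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if n == 0 or not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    # rotate so the sequence starts just after a False -> runs never split
    start0 = int(np.flatnonzero(~mask)[-1]) + 1
    rolled = np.roll(mask, -start0)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], rolled.astype(int), [0]])))
    runs = []
    for a, b in zip(edges[::2], edges[1::2]):
        runs.append(((int(a) + start0) % n, int(b - a)))
    return runs


def filter_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Drop circular true runs shorter than ``min_run`` samples."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    n = mask.size
    for start, length in circular_runs(mask):
        if length >= min_run:
            idx = (start + np.arange(length)) % n
            out[idx] = True
    return out


def cohort_dapi_threshold(
    profiles: list[PerimeterProfile], q: float = 0.85, channel: str = "DAPI"
) -> float:
    """Cohort quantile threshold on corrected DAPI intensity.

    Pools every corrected sample of every fiber and returns the q-quantile
    under the linear-interpolation definition (numpy default).
    """
    if not 0.0 < q < 1.0:
        raise ParameterError("q must lie in (0, 1)")
    pools = [np.asarray(p.corrected[channel], dtype=float) for p in profiles]
    if not pools or sum(p.size for p in pools) == 0:
        raise ParameterError("empty profile pool")
    pool = np.concatenate(pools)
    if pool.size < 20:
        warnings.warn(f"only {pool.size} pooled samples for quantile threshold")
    return float(np.quantile(pool, q))


def annotate_perinuclear(
    profile: PerimeterProfile,
    threshold: float,
    min_run: int = 3,
    channel: str = "DAPI",
) -> np.ndarray:
    """Boolean perinuclear mask: corrected DAPI strictly above threshold,
    with sub-``min_run`` runs removed (wraparound-aware)."""
    mask = np.asarray(profile.corrected[channel], dtype=float) > threshold
    return filter_short_runs(mask, min_run)


def classify_deficient_points(
    profile: PerimeterProfile,
    deficiency_fraction: float = 0.5,
    min_run: int = 3,
    manual_mask: np.ndarray | None = None,
    eps: float = 1e-9,
) -> np.ndarray:
    """Boolean focal-deficiency mask along the perimeter.

    A manual annotation mask, when provided, is returned verbatim. The
    automated surrogate flags samples where MTCOI/(SDHA+eps) drops below
    ``deficiency_fraction`` of the fiber's median ratio while SDHA exceeds
    its fiber median (deficiency must co-occur with preserved or elevated
    mitochondrial mass, the SDH-positive requirement).
    """
    if manual_mask is not None:
        mask = np.asarray(manual_mask, dtype=bool)
        if mask.shape != profile.arc_fractions.shape:
            raise ParameterError("manual mask length does not match profile")
        return mask.copy()
    sdha = np.asarray(profile.corrected["SDHA"], dtype=float)
    mtcoi = np.asarray(profile.corrected["MTCOI"], dtype=float)
    if np.all(sdha == 0):
        raise ClassificationError(
            f"fiber {profile.fiber_id}: SDHA channel is all zero"
        )
    ratio = mtcoi / (sdha + eps)
    med_ratio = float(np.median(ratio))
    med_sdha = float(np.median(sdha))
    mask = (ratio < deficiency_fraction * med_ratio) & (sdha > med_sdha)
    return filter_short_runs(mask, min_run)


def annotate_cohort(
    profiles: list[PerimeterProfile],
    config: AnalysisConfig | None = None,
    manual: dict[str, np.ndarray] | None = None,
) -> list[DomainAnnotation]:
    """Full cohort annotation: pooled DAPI quantile threshold, perinuclear
    masks, and focal masks (manual masks override per fiber)."""
    config = config or AnalysisConfig()
    thr = cohort_dapi_threshold(profiles, q=config.quantile_q)
    manual = manual or {}
    out = []
    for p in profiles:
        peri = annotate_perinuclear(p, thr, min_run=config.min_run)
        focal = classify_deficient_points(
            p,
            deficiency_fraction=config.deficiency_fraction,
            min_run=config.min_run,
            manual_mask=manual.get(p.fiber_id),
        )
        out.append(
            DomainAnnotation(
                fiber_id=p.fiber_id,
                perinuclear=peri,
                focal=focal,
                perimeter_px=p.perimeter_px,
            )
        )
    return out


def classify_fiber(
    annotation: DomainAnnotation,
    deficient_cover: float = 0.95,
    focus_max_fraction: float = 0.5,
) -> FiberClass:
    """Whole-fiber COX classification from the focal mask.

    Fully deficient when at least ``deficient_cover`` of samples are
    deficient; a focus is a deficient fraction strictly between 0 and
    ``focus_max_fraction`` in an otherwise COX-positive fiber; deficient
    coverage between those bounds is intermediate.
    """
    F = annotation.F
    if F >= deficient_cover:
        return FiberClass("fully COX-deficient", False)
    if F == 0.0:
        return FiberClass("COX-positive", False)
    if F < focus_max_fraction:
        return FiberClass("COX-positive", True)
    return FiberClass("intermediate", False)


def prevalence_summary(classes: list[FiberClass]) -> dict:
    """Cohort prevalence of foci and fully deficient fibers.

    Reports counts, percentages, and the foci:total and
    foci:fully-deficient ratios in "1:x" form (undefined with zero foci).
    """
    if not classes:
        raise ParameterError("prevalence summary needs >= 1 fiber")
    total = len(classes)
    n_full = sum(c.label == "fully COX-deficient" for c in classes)
    n_foci = sum(c.has_focus for c in classes)

    def ratio(denominator_count: int) -> str:
        if n_foci == 0:
            return "undefined"
        x = denominator_count / n_foci
        return f"1:{x:g}" if x != int(x) else f"1:{int(x)}"

    return {
        "total_fibers": total,
        "n_fully_deficient": n_full,
        "n_foci": n_foci,
        "percent_fully_deficient": 100.0 * n_full / total,
        "percent_foci": 100.0 * n_foci / total,
        "foci_to_total": ratio(total),
        "foci_to_fully_deficient": ratio(n_full),
    }
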