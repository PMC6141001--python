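"""Synthetic muscle-fiber sections and qPCR plates with known ground truth.

The image generator emulates transverse cryosections of skeletal muscle
fibers imaged in three channels: DAPI (nuclei), SDHA (mitochondrial mass,
nuclear-encoded) and MTCOI (complex IV subunit, mtDNA-encoded). Each fiber
is a perturbed-ellipse polygon with 1-5 myonuclei on its perimeter and,
optionally, one focal region of respiratory-chain deficiency: a contiguous
perimeter arc, confined to a subsarcolemmal band, in which SDHA is elevated
(3.3-fold by default) and MTCOI attenuated (to 0.1 of baseline by default).
The ``enrichment_rho`` dial sets the probability that a focus is centered
on a nucleus rather than placed uniformly at random, which is the quantity
the downstream overlap statistic is designed to detect.

The qPCR generator inverts the triplex D-Loop/ND1/ND4 quantification: true
per-region template copy numbers are pushed through a log-linear standard
curve, Cq = intercept + slope * log10(copies) + noise, in triplicate, with
plasmid standard dilutions and no-template controls on every plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask

from ._geometry import resample_boundary
from .errors import ParameterError
from .io import DEFAULT_CHANNELS, FiberSection

__all__ = [
    "CohortSimParams",
    "QpcrSimParams",
    "FiberTruth",
    "RegionTruth",
    "GroundTruth",
    "simulate_cohort",
    "simulate_region_truth",
    "simulate_qpcr_plate",
    "TARGETS",
]

TARGETS = ("DLoop", "ND1", "ND4")


@dataclass
class CohortSimParams:
    """Parameters for the synthetic fiber-section cohort.

    Geometry is in pixels; intensities are in the unsigned 16-bit range.
    ``enrichment_rho`` is the probability that a focus center coincides
    with a nucleus perimeter position (1 = fully perinuclear placement,
    0 = uniform placement, the independence null).
    """

    n_fibers: int = 74
    fiber_radius_px: float = 60.0
    radius_jitter: float = 0.1
    n_nuclei_range: tuple[int, int] = (1, 5)
    enrichment_rho: float = 1.0
    focus_arc_fraction: float = 0.2
    foci_per_fiber_prob: float = 1.0
    sdha_focus_fold: float = 3.3
    mtcoi_focus_atten: float = 0.1
    sdha_baseline: float = 100.0
    mtcoi_baseline: float = 100.0
    dapi_nucleus_amp: float = 400.0
    nucleus_sigma_px: float = 5.0
    nucleus_depth_px: float = 5.0
    band_depth_px: float = 10.0
    background_level: dict[str, float] = field(
        default_factory=lambda: {"DAPI": 40.0, "SDHA": 40.0, "MTCOI": 40.0}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"DAPI": 2.0, "SDHA": 2.0, "MTCOI": 2.0}
    )
    saturation_level: int = 65535
    n_boundary_vertices: int = 192
    margin_px: float = 16.0
    patient_id: str = "SIM"
    section_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("enrichment_rho", "foci_per_fiber_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} must lie in [0, 1]")
        if self.fiber_radius_px <= 0:
            raise ParameterError("fiber_radius_px must be positive")
        if not 0.0 < self.focus_arc_fraction < 0.5:
            raise ParameterError("focus_arc_fraction must lie in (0, 0.5)")
        if self.sdha_focus_fold <= 0 or self.mtcoi_focus_atten <= 0:
            raise ParameterError("intensity folds must be positive")
        lo, hi = self.n_nuclei_range
        if lo < 0 or hi < lo:
            raise ParameterError(f"invalid n_nuclei_range {self.n_nuclei_range}")
        if self.n_fibers < 1:
            raise ParameterError("n_fibers must be >= 1")


@dataclass
class FiberTruth:
    """Ground truth for one simulated fiber."""

    fiber_id: str
    nucleus_fractions: np.ndarray
    focus_intervals: list[tuple[float, float]]
    focus_perinuclear: bool


@dataclass
class RegionTruth:
    """True template copy numbers for one microdissected region."""

    region_id: str
    fiber_id: str
    region_kind: str
    copies: dict[str, float]


@dataclass
class GroundTruth:
    """Cohort-level ground truth: per-fiber geometry and per-region copies."""

    fibers: list[FiberTruth] = field(default_factory=list)
    regions: list[RegionTruth] = field(default_factory=list)

    def fibers_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fibers:
            rows.append(
                {
                    "fiber_id": f.fiber_id,
                    "nucleus_fractions": ";".join(f"{u:.6f}" for u in f.nucleus_fractions),
                    "focus_intervals": ";".join(
                        f"{a:.6f}-{b:.6f}" for a, b in f.focus_intervals
                    ),
                    "focus_perinuclear": f.focus_perinuclear,
                }
            )
        return pd.DataFrame(rows)

    def regions_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row = {"region_id": r.region_id, "fiber_id": r.fiber_id,
                   "region_kind": r.region_kind}
            row.update({f"copies_{t}": r.copies.get(t, np.nan) for t in TARGETS})
            rows.append(row)
        return pd.DataFrame(rows)


def in_arc(frac, start: float, end: float):
    """Membership of arc fraction(s) in the interval [start, end) on the
    circle; ``start > end`` wraps across the origin."""
    frac = np.asarray(frac)
    if start <= end:
        return (frac >= start) & (frac < end)
    return (frac >= start) | (frac < end)


def _fiber_polygon(params: CohortSimParams, rng: np.random.Generator) -> np.ndarray:
    """Perturbed-ellipse polygon: radial low-order harmonic noise on a circle."""
    radius = params.fiber_radius_px * (1.0 + params.radius_jitter * rng.uniform(-1, 1))
    theta = np.linspace(0.0, 2 * np.pi, params.n_boundary_vertices, endpoint=False)
    r = np.full_like(theta, radius)
    for k in (2, 3, 4, 5):
        amp = rng.uniform(0, params.radius_jitter / 4) * radius
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    side = int(np.ceil(2 * (radius * (1 + params.radius_jitter) + params.margin_px)))
    c = side / 2.0
    return np.column_stack([c + r * np.cos(theta), c + r * np.sin(theta)]), side


def _render_fiber(
    verts: np.ndarray,
    side: int,
    nuclei: np.ndarray,
    focus: tuple[float, float] | None,
    params: CohortSimParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    shape = (side, side)
    n_dense = max(64, int(np.ceil(4 * np.pi * params.fiber_radius_px)))
    pts, fracs, normals, _ = resample_boundary(verts, n_dense)

    mask = polygon2mask(shape, verts[:, ::-1])  # (row, col) = (y, x)
    depth = distance_transform_edt(mask)
    band = mask & (depth <= params.band_depth_px)

    bg = params.background_level
    sdha = np.full(shape, bg.get("SDHA", 0.0))
    mtcoi = np.full(shape, bg.get("MTCOI", 0.0))
    sdha[mask] += params.sdha_baseline
    mtcoi[mask] += params.mtcoi_baseline

    if focus is not None:
        rows, cols = np.nonzero(band)
        _, idx = cKDTree(pts).query(np.column_stack([cols, rows]).astype(float))
        sel = in_arc(fracs[idx], *focus)
        sdha[rows[sel], cols[sel]] = (
            bg.get("SDHA", 0.0) + params.sdha_baseline * params.sdha_focus_fold
        )
        mtcoi[rows[sel], cols[sel]] = (
            bg.get("MTCOI", 0.0) + params.mtcoi_baseline * params.mtcoi_focus_atten
        )

    dapi = np.full(shape, bg.get("DAPI", 0.0))
    sig = params.nucleus_sigma_px
    half = int(np.ceil(4 * sig))
    for u in nuclei:
        i = int(round(u * n_dense)) % n_dense
        cx, cy = pts[i] + params.nucleus_depth_px * normals[i]
        r0, r1 = max(0, int(cy) - half), min(side, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(side, int(cx) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dapi[r0:r1, c0:c1] += params.dapi_nucleus_amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2)
        )

    out = {}
    for name, img in (("DAPI", dapi), ("SDHA", sdha), ("MTCOI", mtcoi)):
        sd = params.noise_sd.get(name, 0.0)
        if sd > 0:
            img = img + rng.normal(0.0, sd, shape)
        img = np.clip(np.rint(img), 0, params.saturation_level)
        out[name] = img.astype(np.uint16)
    return out


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[list[FiberSection], GroundTruth]:
    """Simulate a cohort of fiber sections with known nuclei and foci.

    Returns one :class:`FiberSection` per fiber (each with its own raster)
    and the matching :class:`GroundTruth`. Fixed ``params.seed`` gives
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    sections: list[FiberSection] = []
    truth = GroundTruth()
    for i in range(params.n_fibers):
        fiber_id = f"F{i:03d}"
        verts, side = _fiber_polygon(params, rng)
        lo, hi = params.n_nuclei_range
        n_nuc = int(rng.integers(lo, hi + 1))
        nuclei = np.sort(rng.uniform(0.0, 1.0, n_nuc))

        focus = None
        perinuclear = False
        if rng.random() < params.foci_per_fiber_prob:
            if n_nuc > 0 and rng.random() < params.enrichment_rho:
                center = float(rng.choice(nuclei))
                perinuclear = True
            else:
                center = float(rng.uniform(0.0, 1.0))
            half = params.focus_arc_fraction / 2.0
            focus = ((center - half) % 1.0, (center + half) % 1.0)

        channels = _render_fiber(verts, side, nuclei, focus, params, rng)
        sections.append(
            FiberSection(
                patient_id=params.patient_id,
                section_id=params.section_id,
                fiber_id=fiber_id,
                boundary=verts,
                channels=channels,
            )
        )
        truth.fibers.append(
            FiberTruth(
                fiber_id=fiber_id,
                nucleus_fractions=nuclei,
                focus_intervals=[focus] if focus is not None else [],
                focus_perinuclear=perinuclear,
            )
        )
    return sections, truth


@dataclass
class QpcrSimParams:
    """Parameters of the simulated triplex qPCR plate.

    ``slope`` is cycles per log10 copies; the default -3.3834 corresponds
    to 97.5% amplification efficiency, typical of a well-optimized assay
    sitting inside the 95-100% plate-inclusion gate (a slope of -3.3219
    would be exact doubling). ``intercept`` is the Cq of a single template
    copy. ``standard_copies`` is the plasmid dilution series, strictly
    decreasing.
    """

    slope: float = -3.3834
    intercept: float = 40.0
    noise_sd: float = 0.1
    standard_copies: tuple[float, ...] = (1e6, 1e5, 1e4, 1e3, 1e2)
    ntc_cq: float | None = 38.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ParameterError("standard-curve slope must be negative")
        d = np.asarray(self.standard_copies, dtype=float)
        if d.size < 2 or not np.all(np.diff(d) < 0):
            raise ParameterError("standard dilution series must be strictly decreasing")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def simulate_region_truth(
    n_pairs: int = 27,
    dloop_fold: float = 2.2,
    nd1_fold: float = 2.5,
    fold_sigma: float = 0.25,
    base_dloop: float = 500.0,
    base_nd1: float = 500.0,
    between_fiber_sigma: float = 0.4,
    within_fiber_sigma: float = 0.05,
    deletion_focus_mean: float = 80.0,
    deletion_matched_mean: float = 30.0,
    deletion_sd: float = 10.0,
    n_whole_per_group: int = 8,
    whole_copy_scale: float = 20.0,
    whole_fold: float = 1.9,
    seed: int = 0,
) -> GroundTruth:
    """True copy numbers for microdissected regions: focus + two matched
    COX-positive subsarcolemmal regions per fiber, plus whole-fiber controls.

    Per-fiber fold elevations of the focus over the matched-region mean are
    lognormal with expectation ``dloop_fold`` / ``nd1_fold``; deletion
    levels (percent of molecules missing ND4) are higher in foci than in
    matched regions. ND4 copies are derived as ND1 * (1 - deletion/100),
    so true ND4 <= true ND1 always.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()

    def lognorm(mean_mult, sigma, size=None):
        z = rng.normal(0.0, sigma, size)
        return mean_mult * np.exp(z - sigma**2 / 2.0)

    def deletion(mean):
        return float(np.clip(rng.normal(mean, deletion_sd), 0.0, 100.0))

    for i in range(n_pairs):
        fiber = f"Q{i:03d}"
        scale = float(lognorm(1.0, between_fiber_sigma))
        c_dloop, c_nd1 = base_dloop * scale, base_nd1 * scale
        matched = []
        for j in (1, 2):
            dl = float(c_dloop * lognorm(1.0, within_fiber_sigma))
            n1 = float(c_nd1 * lognorm(1.0, within_fiber_sigma))
            d = deletion(deletion_matched_mean)
            matched.append((dl, n1))
            truth.regions.append(
                RegionTruth(
                    region_id=f"{fiber}_M{j}",
                    fiber_id=fiber,
                    region_kind="matched_positive",
                    copies={"DLoop": dl, "ND1": n1, "ND4": n1 * (1 - d / 100.0)},
                )
            )
        m_dl = float(np.mean([m[0] for m in matched]))
        m_n1 = float(np.mean([m[1] for m in matched]))
        f_dl = m_dl * float(lognorm(dloop_fold, fold_sigma))
        f_n1 = m_n1 * float(lognorm(nd1_fold, fold_sigma))
        d = deletion(deletion_focus_mean)
        truth.regions.append(
            RegionTruth(
                region_id=f"{fiber}_FOC",
                fiber_id=fiber,
                region_kind="focus",
                copies={"DLoop": f_dl, "ND1": f_n1, "ND4": f_n1 * (1 - d / 100.0)},
            )
        )

    for g, kind, fold, dmean in (
        ("P", "whole_fiber_positive", 1.0, 10.0),
        ("D", "whole_fiber_deficient", whole_fold, 70.0),
    ):
        for i in range(n_whole_per_group):
            fiber = f"W{g}{i:02d}"
            scale = float(lognorm(1.0, between_fiber_sigma)) * whole_copy_scale
            dl = base_dloop * scale * float(lognorm(fold, fold_sigma))
            n1 = base_nd1 * scale * float(lognorm(fold, fold_sigma))
            d = deletion(dmean)
            truth.regions.append(
                RegionTruth(
                    region_id=f"{fiber}_WF",
                    fiber_id=fiber,
                    region_kind=kind,
                    copies={"DLoop": dl, "ND1": n1, "ND4": n1 * (1 - d / 100.0)},
                )
            )
    return truth


def simulate_qpcr_plate(truth: GroundTruth, params: QpcrSimParams) -> pd.DataFrame:
    """Simulate a triplex qPCR plate export for the regions in ``truth``.

    Returns a table with columns ``well, region_id, fiber_id, region_kind,
    target, replicate, Cq``. Standards (one dilution series per target) and
    no-template controls are included. A region whose true copy number is
    not positive yields no amplification, encoded as Cq = NaN.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    widx = 0

    def cq_of(copies: float) -> float:
        if copies <= 0:
            return np.nan
        cq = params.intercept + params.slope * np.log10(copies)
        if params.noise_sd > 0:
            cq += rng.normal(0.0, params.noise_sd)
        return float(cq)

    def emit(region_id, fiber_id, kind, target, copies):
        nonlocal widx
        for rep in range(1, params.n_replicates + 1):
            widx += 1
            rows.append(
                {
                    "well": f"W{widx:03d}",
                    "region_id": region_id,
                    "fiber_id": fiber_id,
                    "region_kind": kind,
                    "target": target,
                    "replicate": rep,
                    "Cq": cq_of(copies) if kind != "NTC" else (
                        np.nan if params.ntc_cq is None else float(params.ntc_cq)
                    ),
                }
            )

    for target in TARGETS:
        for copies in params.standard_copies:
            emit(f"STD_{copies:g}", "", "standard", target, float(copies))
        emit("NTC", "", "NTC", target, 0.0)
    for region in truth.regions:
        for target in TARGETS:
            emit(
                region.region_id,
                region.fiber_id,
                region.region_kind,
                target,
                float(region.copies.get(target, 0.0)),
            )
    return pd.DataFrame(rows)
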