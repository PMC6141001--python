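"""Reading and writing the formats the pipeline touches.

Conventions
-----------
* Pixel coordinates are 0-based. Rasters are indexed ``[row, col]``;
  polygon vertices are stored in ``(x, y)`` image convention where
  ``x = col`` and ``y = row``.
* Arc-length positions along a fiber boundary are fractions of the total
  perimeter in ``[0, 1)``, measured counterclockwise from the polygon's
  first vertex.
* Multi-channel TIFFs are stored with the channel axis first, in the
  order given by ``channel_names`` (default DAPI, SDHA, MTCOI).
* ROI tables, annotations, profiles and results are CSV; configuration
  and summary reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .errors import FormatError

logger = logging.getLogger("mitofoci")

DEFAULT_CHANNELS = ("DAPI", "SDHA", "MTCOI")

__all__ = [
    "FiberSection",
    "AnalysisConfig",
    "read_section",
    "write_section",
    "read_roi_table",
    "read_manual_annotation",
    "intervals_to_mask",
    "DEFAULT_CHANNELS",
]


@dataclass
class FiberSection:
    """One muscle fiber cross-section: boundary polygon plus channel rasters.

    Attributes
    ----------
    patient_id, section_id, fiber_id : str
        Provenance identifiers.
    boundary : (n, 2) float array
        Ordered closed polygon in (x, y) pixel coordinates; the closing
        edge from the last to the first vertex is implicit. Must be
        simple (non-self-intersecting) with at least 8 vertices.
    channels : dict[str, ndarray]
        Channel name -> 2-D intensity raster; all rasters share a shape.
    pixel_size : float or None
        Physical length per pixel (units are the caller's concern).
    """

    patient_id: str
    section_id: str
    fiber_id: str
    boundary: np.ndarray
    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise FormatError("boundary must be an (n, 2) array")
        # drop consecutive duplicate vertices (closing vertex included)
        b = self.boundary
        keep = np.ones(len(b), dtype=bool)
        keep[1:] = np.any(b[1:] != b[:-1], axis=1)
        if np.all(b[-1] == b[0]):
            keep[-1] = False
        if not keep.all():
            logger.warning(
                "fiber %s: removed %d duplicate boundary vertices",
                self.fiber_id,
                int((~keep).sum()),
            )
            self.boundary = b[keep]
        if len(self.boundary) < 8:
            raise FormatError(
                f"fiber {self.fiber_id}: boundary needs >= 8 vertices, "
                f"got {len(self.boundary)}"
            )
        if not Polygon(self.boundary).is_valid:
            raise FormatError(f"fiber {self.fiber_id}: boundary polygon not simple")
        shapes = {ch: np.asarray(im).shape for ch, im in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise FormatError(f"fiber {self.fiber_id}: channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the pipeline defaults.

    ``quantile_q`` is the cohort quantile of corrected DAPI intensity used
    to call perinuclear perimeter domains; ``ntc_margin_cycles`` is the
    number of cycles every region of a fiber must clear below the
    no-template control for the fiber to enter paired analyses.
    """

    quantile_q: float = 0.85
    sampling_step_px: float = 1.0
    band_depth_px: float = 10.0
    saturation_level: int = 65535
    min_run: int = 3
    deficiency_fraction: float = 0.5
    deficient_cover: float = 0.95
    focus_max_fraction: float = 0.5
    efficiency_bounds: tuple[float, float] = (0.95, 1.00)
    ntc_margin_cycles: float = 3.0
    dloop_tolerance_fold: float = 2.0
    alpha: float = 0.05
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_q < 1.0:
            raise FormatError("quantile_q must lie in (0, 1)")
        if self.sampling_step_px <= 0 or self.band_depth_px <= 0:
            raise FormatError("sampling step and band depth must be positive")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["efficiency_bounds"] = list(self.efficiency_bounds)
        d["channel_names"] = list(self.channel_names)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        if "efficiency_bounds" in d:
            d["efficiency_bounds"] = tuple(d["efficiency_bounds"])
        if "channel_names" in d:
            d["channel_names"] = tuple(d["channel_names"])
        return cls(**d)


def write_section(section: FiberSection, image_path, roi_path) -> None:
    """Write one fiber's channels to a multi-channel TIFF and its polygon
    to an ROI CSV (one vertex per row)."""
    image_path, roi_path = Path(image_path), Path(roi_path)
    stack = np.stack([np.asarray(section.channels[ch]) for ch in section.channels])
    tifffile.imwrite(
        image_path,
        stack,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": list(section.channels)},
    )
    rows = pd.DataFrame(
        {
            "patient_id": section.patient_id,
            "section_id": section.section_id,
            "fiber_id": section.fiber_id,
            "image": image_path.name,
            "vertex_index": np.arange(len(section.boundary)),
            "x": section.boundary[:, 0],
            "y": section.boundary[:, 1],
        }
    )
    rows.to_csv(roi_path, index=False)


def read_roi_table(roi_path) -> pd.DataFrame:
    df = pd.read_csv(roi_path)
    required = {"fiber_id", "vertex_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"ROI table missing columns: {sorted(missing)}")
    return df


def read_section(
    image_path,
    roi_path,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
    patient_id: str = "NA",
    section_id: str = "NA",
) -> list[FiberSection]:
    """Read a multi-channel TIFF plus ROI table into FiberSections.

    One FiberSection is produced per distinct fiber_id in the ROI table
    (restricted to rows whose ``image`` column matches the TIFF file name,
    when that column is present). The TIFF must carry exactly
    ``len(channel_names)`` channels, in that order.
    """
    image_path = Path(image_path)
    with tifffile.TiffFile(image_path) as tf:
        stack = tf.asarray()
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"{image_path.name}: expected a (C, Y, X) stack")
    if stack.shape[0] != len(channel_names):
        raise FormatError(
            f"{image_path.name}: {stack.shape[0]} channels present, "
            f"{len(channel_names)} configured {channel_names}"
        )
    df = read_roi_table(roi_path)
    if "image" in df.columns:
        df = df[df["image"] == image_path.name]
    if df.empty:
        raise FormatError(f"no ROI rows reference {image_path.name}")
    channels = {ch: stack[i] for i, ch in enumerate(channel_names)}
    sections = []
    for fiber_id, grp in df.groupby("fiber_id", sort=False):
        grp = grp.sort_values("vertex_index")
        sections.append(
            FiberSection(
                patient_id=str(grp["patient_id"].iloc[0]) if "patient_id" in grp else patient_id,
                section_id=str(grp["section_id"].iloc[0]) if "section_id" in grp else section_id,
                fiber_id=str(fiber_id),
                boundary=grp[["x", "y"]].to_numpy(float),
                channels=channels,
            )
        )
    return sections


def read_manual_annotation(path) -> dict[str, list[tuple[float, float]]]:
    """Read manual COX-deficiency interval annotations.

    The CSV has columns ``fiber_id, start, end, label`` where start/end
    are arc-length fractions in [0, 1) and label is ``COX-deficient`` or
    ``COX-positive``. Only deficient intervals are retained; an interval
    with ``start > end`` wraps across the arc origin. Fibers absent from
    the file (or an empty file) are entirely COX-positive.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    required = {"fiber_id", "start", "end", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        s, e = float(row["start"]), float(row["end"])
        for v in (s, e):
            if not 0.0 <= v < 1.0:
                raise FormatError(
                    f"annotation position {v} outside [0, 1) for fiber {row['fiber_id']}"
                )
        if str(row["label"]).strip().lower() in ("cox-deficient", "deficient"):
            out.setdefault(str(row["fiber_id"]), []).append((s, e))
    return out


def intervals_to_mask(
    intervals: list[tuple[float, float]], arc_fractions: np.ndarray
) -> np.ndarray:
    """Union of wraparound-aware arc intervals rasterized onto a sampling grid.

    Each grid position is labeled by membership of its own arc fraction
    (nearest-sample alignment on an evenly spaced grid)."""
    pos = np.asarray(arc_fractions, dtype=float)
    mask = np.zeros(pos.shape, dtype=bool)
    for s, e in intervals:
        if s <= e:
            mask |= (pos >= s) & (pos < e)
        else:  # wraps across the origin
            mask |= (pos >= s) | (pos < e)
    return mask
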