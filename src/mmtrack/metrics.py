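"""Segmentation agreement metrics: Dice, Hausdorff, RMSE, centroid error.

Contours are closed polygons with continuous (row, col) vertex
coordinates in pixel units.  Region metrics (Dice, centroid) operate on
rasterized masks — a pixel belongs to the mask iff its center lies
inside the polygon.  Boundary metrics (Hausdorff, RMSE) operate on the
sub-pixel contours directly, after resampling both to uniform arc
length, with anisotropic pixel spacing applied per axis before any
distance is taken so results are in mm.

RMSE here is the symmetric nearest-neighbour contour distance: the root
mean square of closest-point distances, averaged over both directions.
Alternative conventions (e.g. RMSE over corresponding vertex pairs)
exist in the literature; this one requires no vertex correspondence and
pairs naturally with the Hausdorff distance, which is its max-norm
analogue.  The Hausdorff distance reported is the classical maximum
(not a percentile variant).

Anatomical axes: by default image rows run along the patient
superior-inferior (S-I) axis and columns along anterior-posterior
(A-P); pass a different ``axis_map`` if the acquisition differs.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from skimage.measure import grid_points_in_poly

from .grid import ValidationError

DEFAULT_AXIS_MAP = {"si": "row", "ap": "col"}
RESAMPLE_SPACING_PX = 0.5


@dataclass(frozen=True)
class Contour:
    """A closed polygon in continuous 0-based (row, col) pixel coordinates."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an (n, 2) array of (row, col)")
        if v.shape[0] < 3:
            raise ValidationError("contour needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contour vertices must be finite")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    def translated(self, d_row: float, d_col: float) -> "Contour":
        return Contour(self.vertices + np.array([d_row, d_col]), self.closed)

    def resampled(self, spacing_px: float = RESAMPLE_SPACING_PX) -> np.ndarray:
        """Points at uniform arc-length spacing along the closed polygon."""
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if total == 0.0:
            return v[:1]
        n = max(int(math.ceil(total / spacing_px)), 4)
        s = np.linspace(0.0, total, n, endpoint=False)
        rows = np.interp(s, arc, v[:, 0])
        cols = np.interp(s, arc, v[:, 1])
        return np.column_stack([rows, cols])

    def centroid(self) -> tuple[float, float]:
        r, c = self.vertices.mean(axis=0)
        return float(r), float(c)


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask: pixel (i, j) is foreground iff its center is inside.

    Pixel centers sit at integer coordinates (node i at coordinate i),
    matching the grid convention used everywhere else.  A degenerate
    (zero-area) polygon yields an empty mask.
    """
    mask = grid_points_in_poly(shape, contour.vertices)
    return np.asarray(mask, dtype=bool)


def _check_mask(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValidationError(f"{name} must be a 2D boolean mask")
    return m


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap  2|A ∩ B| / (|A| + |B|)  in [0, 1]."""
    a = _check_mask(a, "a")
    b = _check_mask(b, "b")
    if a.shape != b.shape:
        raise ValidationError("masks must share a shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        raise ValidationError("Dice undefined for two empty masks")
    return 2.0 * float(np.logical_and(a, b).sum()) / (sa + sb)


def _scaled_points(contour: Contour, spacing_mm: tuple[float, float]) -> np.ndarray:
    pts = contour.resampled()
    return pts * np.asarray(spacing_mm, dtype=float)


def hausdorff_distance(a: Contour, b: Contour, spacing_mm: tuple[float, float] = (1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between resampled contours, in mm."""
    pa = _scaled_points(a, spacing_mm)
    pb = _scaled_points(b, spacing_mm)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def contour_rmse(a: Contour, b: Contour, spacing_mm: tuple[float, float] = (1.0, 1.0)) -> float:
    """Symmetric nearest-neighbour RMSE between resampled contours, in mm."""
    pa = _scaled_points(a, spacing_mm)
    pb = _scaled_points(b, spacing_mm)
    d = cdist(pa, pb)
    msq_ab = float(np.mean(d.min(axis=1) ** 2))
    msq_ba = float(np.mean(d.min(axis=0) ** 2))
    return math.sqrt(0.5 * (msq_ab + msq_ba))


def centroid_difference(
    a: np.ndarray,
    b: np.ndarray,
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    axis_map: dict[str, str] | None = None,
) -> tuple[float, float, float]:
    """Absolute centroid displacement (S-I, A-P, 2D) between two masks, in mm.

    The centroid of a mask is the mean foreground pixel-center
    coordinate; per-axis differences are scaled by that axis's spacing
    and assigned to the anatomical directions through ``axis_map``.
    """
    a = _check_mask(a, "a")
    b = _check_mask(b, "b")
    if a.shape != b.shape:
        raise ValidationError("masks must share a shape")
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("centroid undefined for an empty mask")
    axis_map = axis_map or DEFAULT_AXIS_MAP

    ca = np.argwhere(a).mean(axis=0)
    cb = np.argwhere(b).mean(axis=0)
    d_row = abs(ca[0] - cb[0]) * spacing_mm[0]
    d_col = abs(ca[1] - cb[1]) * spacing_mm[1]
    by_axis = {"row": d_row, "col": d_col}
    d_si = float(by_axis[axis_map["si"]])
    d_ap = float(by_axis[axis_map["ap"]])
    return d_si, d_ap, float(math.hypot(d_si, d_ap))


@dataclass(frozen=True)
class MetricsReport:
    """All agreement metrics for a single frame."""

    dice: float
    hausdorff_mm: float
    rmse_mm: float
    centroid_si_mm: float
    centroid_ap_mm: float
    centroid_2d_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValidationError("dice must lie in [0, 1]")
        for name in ("hausdorff_mm", "rmse_mm", "centroid_si_mm", "centroid_ap_mm", "centroid_2d_mm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        expect = math.hypot(self.centroid_si_mm, self.centroid_ap_mm)
        if abs(self.centroid_2d_mm**2 - expect**2) > 1e-9:
            raise ValidationError("centroid_2d must combine the S-I and A-P components")


def evaluate_contours(
    predicted: Contour,
    reference: Contour,
    shape: tuple[int, int],
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    axis_map: dict[str, str] | None = None,
) -> MetricsReport:
    """Compute every agreement metric between a predicted and reference contour."""
    mask_p = rasterize_contour(predicted, shape)
    mask_r = rasterize_contour(reference, shape)
    si, ap, d2 = centroid_difference(mask_p, mask_r, spacing_mm, axis_map)
    return MetricsReport(
        dice=dice(mask_p, mask_r),
        hausdorff_mm=hausdorff_distance(predicted, reference, spacing_mm),
        rmse_mm=contour_rmse(predicted, reference, spacing_mm),
        centroid_si_mm=si,
        centroid_ap_mm=ap,
        centroid_2d_mm=d2,
    )


_CSV_COLUMNS = ("frame_index", "dice", "hd_mm", "rmse_mm", "si_mm", "ap_mm", "d2_mm")


def write_metrics_csv(reports: dict[int, MetricsReport], path: str | Path) -> None:
    """One row per frame: frame_index, dice, hd_mm, rmse_mm, si_mm, ap_mm, d2_mm."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for k in sorted(reports):
            r = reports[k]
            writer.writerow(
                [
                    k,
                    f"{r.dice:.6f}",
                    f"{r.hausdorff_mm:.6f}",
                    f"{r.rmse_mm:.6f}",
                    f"{r.centroid_si_mm:.6f}",
                    f"{r.centroid_ap_mm:.6f}",
                    f"{r.centroid_2d_mm:.6f}",
                ]
            )


def summarize_metrics(reports: dict[int, MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and standard deviation per metric over all frames."""
    if not reports:
        raise ValidationError("no reports to summarize")
    fields = ("dice", "hausdorff_mm", "rmse_mm", "centroid_si_mm", "centroid_ap_mm", "centroid_2d_mm")
    out: dict[str, dict[str, float]] = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in reports.values()])
        out[f] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


def write_metrics_summary(reports: dict[int, MetricsReport], path: str | Path) -> dict:
    summary = {"n_frames": len(reports), "metrics": summarize_metrics(reports)}
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
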