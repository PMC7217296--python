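"""Best-frame selection and tumor contour tracking over a treatment sequence.

The clinical loop: during planning, a pretreatment library of frames
with expert tumor contours is acquired.  During treatment, for every
incoming frame the most similar library frame is selected by plain L2
intensity distance (no registration), that frame is registered to the
treatment frame within the moving-mesh family, and its contour is
carried through the resulting point correspondence.

Each treatment frame is processed independently of the others, so the
tracked output is invariant to the order in which frames are handled —
the contract that makes the per-frame work embarrassingly parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ValidationError, interpolate_values
from .image import ImageFrame, ImageSequence
from .metrics import Contour
from .registration import RegistrationConfig, RegistrationResult, register
from .deformation import Transformation


@dataclass(frozen=True)
class PretreatmentLibrary:
    """Planning-stage frames, each with a known tumor contour."""

    frames: ImageSequence
    contours: tuple[Contour, ...]

    def __post_init__(self) -> None:
        if len(self.contours) != len(self.frames):
            raise ValidationError("library needs exactly one contour per frame")
        nr, nc = self.frames.shape
        for k, contour in enumerate(self.contours):
            v = contour.vertices
            if v[:, 0].min() < 0 or v[:, 0].max() > nr - 1 or v[:, 1].min() < 0 or v[:, 1].max() > nc - 1:
                raise ValidationError(f"library contour {k} extends outside the image domain")
        object.__setattr__(self, "contours", tuple(self.contours))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FrameTrackingRecord:
    """Per-frame outcome: chosen library frame, tracked contour, diagnostics."""

    frame_index: int
    best_frame_index: int
    contour: Contour
    selection_l2: float
    final_cost: float
    iterations: int
    converged: bool
    failed: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class TrackingResult:
    """Tracked contours and diagnostics for a whole treatment sequence."""

    records: list[FrameTrackingRecord]

    @property
    def contours(self) -> list[Contour]:
        return [r.contour for r in self.records]

    @property
    def best_frame_indices(self) -> list[int]:
        return [r.best_frame_index for r in self.records]


def _identity_l2(a: ImageFrame, b: ImageFrame) -> float:
    """Mean squared difference of min-max normalized frames, no registration."""
    return float(np.mean((a.normalized() - b.normalized()) ** 2))


def select_best_frame(library: PretreatmentLibrary, frame: ImageFrame) -> int:
    """Index of the library frame with minimal L2 distance to ``frame``.

    The dissimilarity is evaluated at the identity transform on
    intensity-normalized full frames; ties break to the smallest index
    (np.argmin semantics).
    """
    if len(library) == 0:
        raise ValidationError("pretreatment library is empty")
    if library.frames.shape != frame.shape:
        raise ValidationError("frame shape does not match the library")
    costs = np.array([_identity_l2(lib_frame, frame) for lib_frame in library.frames])
    return int(np.argmin(costs))


def propagate_contour(contour: Contour, phi: Transformation) -> Contour:
    """Map each contour vertex through the transformation.

    Vertices are in phi's grid coordinates; each is replaced by the
    bilinear interpolation of the mapping arrays at its position.
    Vertex count, ordering and closedness are preserved.  Vertices
    outside the grid are clamped by the interpolation (and would be
    flagged upstream by the library validator).
    """
    pos = contour.vertices.T  # (2, n), rows first
    new_rows = interpolate_values(phi.map_row, pos)
    new_cols = interpolate_values(phi.map_col, pos)
    return Contour(np.column_stack([new_rows, new_cols]), contour.closed)


def _contour_to_grid(contour: Contour, image_shape: tuple[int, int], grid_size: int) -> Contour:
    sr = (grid_size - 1) / (image_shape[0] - 1)
    sc = (grid_size - 1) / (image_shape[1] - 1)
    return Contour(contour.vertices * np.array([sr, sc]), contour.closed)


def _contour_to_image(contour: Contour, image_shape: tuple[int, int], grid_size: int) -> Contour:
    sr = (image_shape[0] - 1) / (grid_size - 1)
    sc = (image_shape[1] - 1) / (grid_size - 1)
    return Contour(contour.vertices * np.array([sr, sc]), contour.closed)


def track_frame(
    library: PretreatmentLibrary,
    frame: ImageFrame,
    config: RegistrationConfig,
) -> FrameTrackingRecord:
    """Track the tumor on a single treatment frame (independent unit of work)."""
    q = select_best_frame(library, frame)
    sel_l2 = _identity_l2(library.frames[q], frame)
    shape = frame.shape
    try:
        result: RegistrationResult = register(library.frames[q], frame, config)
        grid_contour = _contour_to_grid(library.contours[q], shape, config.grid_size)
        tracked = propagate_contour(grid_contour, result.phi)
        contour = _contour_to_image(tracked, shape, config.grid_size)
        return FrameTrackingRecord(
            frame_index=frame.index,
            best_frame_index=q,
            contour=contour,
            selection_l2=sel_l2,
            final_cost=result.cost_trace[-1],
            iterations=result.iterations,
            converged=result.converged,
            notes=list(result.notes),
        )
    except Exception as exc:  # registration failure: fall back to the unwarped contour
        return FrameTrackingRecord(
            frame_index=frame.index,
            best_frame_index=q,
            contour=library.contours[q],
            selection_l2=sel_l2,
            final_cost=float("nan"),
            iterations=0,
            converged=False,
            failed=True,
            notes=[f"registration failed: {exc}"],
        )


def track_sequence(
    library: PretreatmentLibrary,
    treatment: ImageSequence,
    config: RegistrationConfig,
) -> TrackingResult:
    """Track the tumor contour across every treatment frame.

    Frames are processed in order but each is handled independently:
    the result is identical under any processing order.
    """
    if library.frames.shape != treatment.shape:
        raise ValidationError("treatment frames must match the library shape")
    records = [track_frame(library, frame, config) for frame in treatment]
    return TrackingResult(records)
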