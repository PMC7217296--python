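"""Image containers for cine-MR frames and sequences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ValidationError


@dataclass(frozen=True)
class ImageFrame:
    """A single 2D grayscale frame with physical pixel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValidationError(f"frame must be a 2D array of at least 3x3, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("frame contains non-finite values")
        if not (self.spacing_mm[0] > 0 and self.spacing_mm[1] > 0):
            raise ValidationError("pixel spacing must be strictly positive")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing_mm", (float(self.spacing_mm[0]), float(self.spacing_mm[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def normalized(self) -> np.ndarray:
        """Min-max intensity normalization to [0, 1]; constant frames map to 0."""
        v = self.values
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class ImageSequence:
    """An ordered stack of equally shaped, equally spaced frames."""

    frames: tuple[ImageFrame, ...]

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValidationError("sequence must contain at least one frame")
        shape = frames[0].shape
        spacing = frames[0].spacing_mm
        for fr in frames[1:]:
            if fr.shape != shape:
                raise ValidationError("all frames in a sequence must share a shape")
            if fr.spacing_mm != spacing:
                raise ValidationError("all frames in a sequence must share pixel spacing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> ImageFrame:
        return self.frames[k]

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return self.frames[0].spacing_mm

    def as_array(self) -> np.ndarray:
        """Stack of frame values, shape (n_frames, rows, cols)."""
        return np.stack([fr.values for fr in self.frames])

    @classmethod
    def from_array(cls, values: np.ndarray, spacing_mm: tuple[float, float] = (1.0, 1.0)) -> "ImageSequence":
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValidationError("expected a (n_frames, rows, cols) array")
        return cls(tuple(ImageFrame(values[k], spacing_mm, index=k) for k in range(values.shape[0])))
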