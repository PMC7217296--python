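"""Readers and writers for image sequences, contours, and run artifacts.

Formats
-------
* Image sequences: NIfTI (primary; 2D+time stored as a (rows, cols, t)
  volume with pixel spacing in the affine) or a directory of PNG frames
  in lexicographic order with a ``spacing.json`` sidecar.  NIfTI
  round-trips float data and spacing exactly; PNG is quantized to
  16-bit and intended for visual inspection.
* Contours: CSV with columns ``frame_index, vertex_index, row, col`` in
  0-based continuous pixel coordinates, one closed polygon per frame.
* Motion logs: CSV with columns ``frame_index, d_si_mm, d_ap_mm``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import ValidationError
from .image import ImageFrame, ImageSequence
from .metrics import Contour

_CONTOUR_HEADER = ["frame_index", "vertex_index", "row", "col"]


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as an uncompressed NIfTI volume (rows, cols, time)."""
    path = Path(path)
    data = np.ascontiguousarray(np.moveaxis(seq.as_array(), 0, -1))
    affine = np.diag([seq.spacing_mm[0], seq.spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms((seq.spacing_mm[0], seq.spacing_mm[1], 1.0))
    nib.save(img, str(path))


def load_sequence(path: str | Path) -> ImageSequence:
    """Load a 2D+time sequence from NIfTI or a PNG frame directory."""
    path = Path(path)
    if path.is_dir():
        return _load_png_dir(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4:  # (rows, cols, 1, t) layout
        if data.shape[2] != 1:
            raise ValidationError("expected a 2D+time NIfTI, got a true 3D volume")
        data = data[:, :, 0, :]
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValidationError(f"cannot interpret NIfTI of shape {data.shape} as 2D+time")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    if spacing[0] <= 0 or spacing[1] <= 0:
        spacing = (1.0, 1.0)
    return ImageSequence.from_array(np.moveaxis(data, -1, 0), spacing)


def _load_png_dir(path: Path) -> ImageSequence:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise ValidationError(f"no PNG frames found in {path}")
    sidecar = path / "spacing.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = (float(meta["spacing_row_mm"]), float(meta["spacing_col_mm"]))
    else:
        import logging

        logging.getLogger(__name__).warning(
            "no spacing.json in %s; assuming 1 mm isotropic pixels", path
        )
        spacing = (1.0, 1.0)
    frames = []
    shape = None
    for k, f in enumerate(files):
        raw = iio.imread(f)
        arr = np.asarray(raw, dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValidationError(f"mixed frame shapes in {path}: {shape} vs {arr.shape} ({f.name})")
        if np.issubdtype(raw.dtype, np.integer):
            arr = arr / np.iinfo(raw.dtype).max
        frames.append(ImageFrame(arr, spacing, index=k))
    return ImageSequence(tuple(frames))


def write_png_dir(seq: ImageSequence, path: str | Path) -> None:
    """Write frames as 16-bit PNGs plus a spacing sidecar (lossy: quantized)."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(seq):
        v = np.clip(frame.values, 0.0, 1.0)
        iio.imwrite(path / f"{k:04d}.png", (v * 65535).round().astype(np.uint16))
    (path / "spacing.json").write_text(
        json.dumps({"spacing_row_mm": seq.spacing_mm[0], "spacing_col_mm": seq.spacing_mm[1]})
        + "\n"
    )


def write_contours(contours, path: str | Path) -> None:
    """Write one closed polygon per frame as a contour CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CONTOUR_HEADER)
        for k, contour in enumerate(contours):
            for i, (r, c) in enumerate(contour.vertices):
                writer.writerow([k, i, f"{r:.12g}", f"{c:.12g}"])


def load_contours(path: str | Path, n_frames: int | None = None) -> list[Contour]:
    """Read a contour CSV back into one Contour per frame.

    Vertices are reordered by ``vertex_index``.  If ``n_frames`` is
    given, every frame index in ``range(n_frames)`` must be present;
    missing frames are reported by index.
    """
    by_frame: dict[int, list[tuple[int, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(_CONTOUR_HEADER) - set(reader.fieldnames or [])
        if missing_cols:
            raise ValidationError(f"contour CSV missing columns: {sorted(missing_cols)}")
        for row in reader:
            k = int(row["frame_index"])
            by_frame.setdefault(k, []).append(
                (int(row["vertex_index"]), float(row["row"]), float(row["col"]))
            )
    if n_frames is not None:
        missing = sorted(set(range(n_frames)) - set(by_frame))
        if missing:
            raise ValidationError(f"contour CSV is missing frames: {missing}")
    contours: list[Contour] = []
    for k in sorted(by_frame):
        rows = sorted(by_frame[k])
        if len(rows) < 3:
            raise ValidationError(f"frame {k} has fewer than 3 contour vertices")
        contours.append(Contour(np.array([(r, c) for _, r, c in rows])))
    return contours


def write_motion_log(motion: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "d_si_mm", "d_ap_mm"])
        for k, (d_si, d_ap) in enumerate(np.asarray(motion)):
            writer.writerow([k, f"{d_si:.12g}", f"{d_ap:.12g}"])


def load_motion_log(path: str | Path) -> np.ndarray:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((int(row["frame_index"]), float(row["d_si_mm"]), float(row["d_ap_mm"])))
    rows.sort()
    return np.array([(a, b) for _, a, b in rows])


def load_config_overrides(path: str | Path) -> dict:
    """Flat key-value YAML config; unknown keys are rejected by the CLI."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError("config file must be a flat key-value mapping")
    return data
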