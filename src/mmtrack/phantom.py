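"""Synthetic free-breathing cine-MRI phantom with exact ground truth.

The generator emulates a sagittal thoracic acquisition protocol: a
pretreatment library of 30 frames with known tumor contours plus a
100-frame treatment sequence, acquired at 4 frames/s, with additive
Gaussian noise standing in for the image-quality drop of a low-field
(0.5 T) treatment scanner.

Anatomy is rendered analytically per frame — a smooth body background,
a dark lung field, a handful of bright vessel-like blobs, a diaphragm
edge, and a bright elliptical tumor.  Respiration follows the standard
``sin^2`` surrogate waveform with per-cycle amplitude and phase jitter:

    d_si(t) = (A_si + eps_A) * sin^2(pi * t / tau + phi0 + eps_phi)

with the anterior-posterior displacement a fixed ratio of the
superior-inferior one.  The tumor translates rigidly with
(d_si, d_ap), the diaphragm edge shares d_si, and the vessel blobs move
with a reduced fraction of the tumor displacement (lung parenchyma
moves less than structures near the diaphragm).  Because the tumor
translates rigidly, the per-frame ground-truth contour is an exact
64-vertex ellipse polygon — no discretization ambiguity in the truth.

Pretreatment and treatment sequences use different waveform phase
offsets and independent jitter streams, so no treatment frame exactly
repeats a library frame.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import ValidationError
from .image import ImageFrame, ImageSequence
from .metrics import Contour, rasterize_contour

# waveform phase offsets (radians) for the two acquisition stages; the
# treatment offset is pi/8 so that, at 4 frames/s and a 4 s period, the
# sampling grid hits the waveform peaks exactly
PRETREATMENT_PHASE = 0.37
TREATMENT_PHASE = math.pi / 8.0

_VESSEL_MOTION_FRACTION = 0.7


@dataclass(frozen=True)
class PhantomParams:
    """Acquisition and anatomy parameters of the synthetic protocol.

    Defaults mirror the emulated protocol: 30 pretreatment + 100
    treatment frames at 4 frames/s; a ~4 s free-breathing cycle with
    ~10 mm superior-inferior tumor excursion and a smaller
    anterior-posterior component; additive Gaussian noise of SD 0.03 on
    [0, 1] intensities to mimic low-field image quality.
    """

    image_size: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (2.0, 2.0)
    n_pretreatment: int = 30
    n_treatment: int = 100
    frame_rate_hz: float = 4.0
    breathing_period_s: float = 4.0
    si_amplitude_mm: float = 10.0
    ap_amplitude_mm: float = 3.0
    phase_jitter_sd: float = 0.1
    amplitude_jitter_sd: float = 0.5
    tumor_semiaxes_mm: tuple[float, float] = (8.0, 6.0)
    tumor_contrast: float = 0.5
    noise_sd: float = 0.03
    tumor_center_mm: tuple[float, float] = (100.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] < 16 or self.image_size[1] < 16:
            raise ValidationError("phantom image must be at least 16x16")
        if self.n_pretreatment < 1 or self.n_treatment < 1:
            raise ValidationError("frame counts must be positive")
        for name in ("frame_rate_hz", "breathing_period_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("si_amplitude_mm", "ap_amplitude_mm", "phase_jitter_sd",
                     "amplitude_jitter_sd", "tumor_contrast", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if min(self.tumor_semiaxes_mm) <= 0 or min(self.spacing_mm) <= 0:
            raise ValidationError("tumor semiaxes and spacings must be positive")
        self._check_field_of_view()

    def _check_field_of_view(self) -> None:
        """Reject parameter sets whose tumor can leave the image."""
        fov_r = (self.image_size[0] - 1) * self.spacing_mm[0]
        fov_c = (self.image_size[1] - 1) * self.spacing_mm[1]
        margin = 3.0 * self.amplitude_jitter_sd + 2.0 * max(self.spacing_mm)
        a, b = self.tumor_semiaxes_mm
        cr, cc = self.tumor_center_mm
        r_max = cr + a + self.si_amplitude_mm + margin
        c_max = cc + b + self.ap_amplitude_mm + margin
        if cr - a - margin < 0 or r_max > fov_r or cc - b - margin < 0 or c_max > fov_c:
            raise ValidationError(
                "tumor excursion exceeds the field of view for these parameters"
            )

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz


def _cycle_jitter(params: PhantomParams, stream: int, cycle: int) -> tuple[float, float]:
    """Per-cycle (amplitude, phase) jitter; random-access deterministic."""
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(stream, cycle))
    rng = np.random.default_rng(ss)
    eps_a = rng.normal(0.0, params.amplitude_jitter_sd)
    eps_p = rng.normal(0.0, params.phase_jitter_sd)
    return eps_a, eps_p


def breathing_displacement(
    params: PhantomParams,
    time_s: float,
    phase_offset: float = 0.0,
    stream: int = 0,
) -> tuple[float, float]:
    """Respiratory displacement (d_si_mm, d_ap_mm) at a given time.

    ``stream`` selects an independent jitter sequence (pretreatment vs
    treatment); jitter is drawn once per breathing cycle from seeded
    noise, so the trajectory is fully determined by the seed.
    """
    if time_s < 0:
        raise ValidationError("time must be nonnegative")
    tau = params.breathing_period_s
    cycle = int(time_s // tau)
    if params.amplitude_jitter_sd > 0 or params.phase_jitter_sd > 0:
        eps_a, eps_p = _cycle_jitter(params, stream, cycle)
    else:
        eps_a, eps_p = 0.0, 0.0
    amp = max(params.si_amplitude_mm + eps_a, 0.0)
    s = math.sin(math.pi * time_s / tau + phase_offset + eps_p) ** 2
    d_si = amp * s
    ratio = (params.ap_amplitude_mm / params.si_amplitude_mm) if params.si_amplitude_mm > 0 else 0.0
    return d_si, ratio * d_si


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def render_frame(params: PhantomParams, d_si_mm: float, d_ap_mm: float) -> np.ndarray:
    """Noise-free anatomy at a given respiratory displacement, on [0, 1]."""
    nr, nc = params.image_size
    sp_r, sp_c = params.spacing_mm
    r_mm = (np.arange(nr) * sp_r)[:, None]
    c_mm = (np.arange(nc) * sp_c)[None, :]
    fov_r = (nr - 1) * sp_r
    fov_c = (nc - 1) * sp_c

    # smooth body background with a gentle lateral intensity drift
    img = 0.52 + 0.05 * np.sin(2.0 * math.pi * c_mm / fov_c) * np.ones((nr, 1))

    # dark lung field: ellipse fixed in the thorax
    lung_c = (0.42 * fov_r, 0.5 * fov_c)
    lung_ax = (0.40 * fov_r, 0.38 * fov_c)
    q_lung = np.sqrt(((r_mm - lung_c[0]) / lung_ax[0]) ** 2 + ((c_mm - lung_c[1]) / lung_ax[1]) ** 2)
    w_lung = _sigmoid((1.0 - q_lung) / 0.03)
    img = img * (1.0 - w_lung) + 0.22 * w_lung

    # vessel-like blobs inside the lung, moving with a fraction of the tumor motion
    vr = _VESSEL_MOTION_FRACTION * d_si_mm
    vc = _VESSEL_MOTION_FRACTION * d_ap_mm
    for (br, bc, amp, sig) in (
        (0.30 * fov_r, 0.40 * fov_c, 0.22, 4.0),
        (0.38 * fov_r, 0.62 * fov_c, 0.18, 5.0),
        (0.52 * fov_r, 0.33 * fov_c, 0.20, 4.5),
    ):
        d2 = (r_mm - (br + vr)) ** 2 + (c_mm - (bc + vc)) ** 2
        img = img + amp * np.exp(-0.5 * d2 / sig**2) * w_lung

    # diaphragm edge sharing the superior-inferior breathing phase
    dia_base = 0.68 * fov_r
    curvature = 12.0 * ((c_mm - 0.5 * fov_c) / (0.5 * fov_c)) ** 2
    r_dia = dia_base + d_si_mm + curvature
    w_dia = _sigmoid((r_mm - r_dia) / 2.5)
    img = img * (1.0 - w_dia) + 0.70 * w_dia

    # bright tumor ellipse, rigidly translated by the breathing displacement
    a, b = params.tumor_semiaxes_mm
    cr = params.tumor_center_mm[0] + d_si_mm
    cc = params.tumor_center_mm[1] + d_ap_mm
    q_tum = np.sqrt(((r_mm - cr) / a) ** 2 + ((c_mm - cc) / b) ** 2)
    w_tum = _sigmoid((1.0 - q_tum) / 0.06)
    img = img + params.tumor_contrast * w_tum

    return np.clip(img, 0.0, 1.0)


def tumor_contour(params: PhantomParams, d_si_mm: float, d_ap_mm: float, n_vertices: int = 64) -> Contour:
    """Exact ground-truth tumor boundary as a polygon in pixel coordinates."""
    a, b = params.tumor_semiaxes_mm
    cr = params.tumor_center_mm[0] + d_si_mm
    cc = params.tumor_center_mm[1] + d_ap_mm
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    rows = (cr + a * np.cos(theta)) / params.spacing_mm[0]
    cols = (cc + b * np.sin(theta)) / params.spacing_mm[1]
    return Contour(np.column_stack([rows, cols]))


def add_noise(image: ImageFrame, noise_sd: float, rng: np.random.Generator) -> ImageFrame:
    """Add seeded zero-mean Gaussian noise (SD in [0,1] intensity units), clipped."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return image
    noisy = image.values + rng.normal(0.0, noise_sd, size=image.shape)
    return ImageFrame(np.clip(noisy, 0.0, 1.0), image.spacing_mm, image.index)


@dataclass(frozen=True)
class PhantomStage:
    """One acquisition stage: frames plus exact per-frame ground truth."""

    images: ImageSequence
    contours: tuple[Contour, ...]
    masks: np.ndarray  # (n_frames, rows, cols) boolean
    motion_log: np.ndarray  # (n_frames, 2): (d_si_mm, d_ap_mm)


@dataclass(frozen=True)
class PhantomOutput:
    """Full synthetic study: pretreatment library and treatment sequence."""

    params: PhantomParams
    pretreatment: PhantomStage
    treatment: PhantomStage


def _generate_stage(
    params: PhantomParams,
    n_frames: int,
    phase_offset: float,
    stream: int,
    rng: np.random.Generator,
) -> PhantomStage:
    frames = []
    contours = []
    masks = np.zeros((n_frames,) + tuple(params.image_size), dtype=bool)
    motion = np.zeros((n_frames, 2))
    for k in range(n_frames):
        t = k * params.frame_interval_s
        d_si, d_ap = breathing_displacement(params, t, phase_offset, stream)
        motion[k] = (d_si, d_ap)
        frame = ImageFrame(render_frame(params, d_si, d_ap), params.spacing_mm, index=k)
        frames.append(add_noise(frame, params.noise_sd, rng))
        contour = tumor_contour(params, d_si, d_ap)
        contours.append(contour)
        masks[k] = rasterize_contour(contour, params.image_size)
    return PhantomStage(ImageSequence(tuple(frames)), tuple(contours), masks, motion)


def generate_sequence(params: PhantomParams) -> PhantomOutput:
    """Render the full study (library + treatment) deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(99,)))
    pre = _generate_stage(params, params.n_pretreatment, PRETREATMENT_PHASE, stream=0, rng=rng)
    trt = _generate_stage(params, params.n_treatment, TREATMENT_PHASE, stream=1, rng=rng)
    return PhantomOutput(params, pre, trt)
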