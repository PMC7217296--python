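# mmtrack

Moving-mesh diffeomorphic registration and lung tumor tracking for 2D
cine MRI.

## What it is for

During MRI-guided radiotherapy (linac-MR), the treatment plane is
imaged at a few frames per second while the tumor moves with breathing.
The tumor boundary is drawn by an expert on a small *pretreatment*
library of frames; during irradiation it must be inferred on every
incoming *treatment* frame automatically.  `mmtrack` implements this
clinical loop for researchers in image-guided radiotherapy and
deformable registration:

1. **Best-frame selection** — for each treatment frame `T_k`, pick the
   library frame `T_q = argmin_j E_L2(T_j, T_k)` by plain intensity
   distance, so the library absorbs the gross breathing motion.
2. **Moving-mesh registration** — find the dense correspondence
   `phi = argmin_phi E_L2(T_q, T_k, phi)` within a diffeomorphic family
   parameterized by a *monitor function* `mu` (prescribed Jacobian:
   `det J_phi = mu`, with `mu > 0` and mean one) and a *curl field*
   `gamma`.  Realization: solve the div-curl system
   `div rho = mu - 1`, `curl rho = gamma`, `rho = 0` on the boundary,
   then integrate the velocity ODE
   `d psi/dt = rho(psi) / (t + (1-t) mu(psi))` from `t = 0` to `1`.
3. **Contour propagation** — map the library contour vertex-wise
   through `phi` onto the treatment frame.
4. **Evaluation** — Dice, Hausdorff distance, symmetric
   nearest-neighbour contour RMSE, and superior-inferior /
   anterior-posterior centroid differences, in mm.

A fully synthetic free-breathing phantom (analytic anatomy, `sin^2`
respiratory waveform with per-cycle jitter, exact polygon ground truth)
makes the entire pipeline testable without patient data.  See
`docs/methods.md` for the model, the numerical choices, and what the
phantom does and does not emulate.

## Worked example

Simulate a study, track the tumor, and score the result:

```bash
mmtrack --seed 1 simulate --out study
mmtrack track \
    --library study/pretreatment.nii \
    --library-contours study/pretreatment_contours.csv \
    --treatment study/treatment.nii \
    --out tracked
mmtrack evaluate \
    --predicted tracked/tracked_contours.csv \
    --reference study/treatment_contours.csv \
    --images study/treatment.nii \
    --out scores
```

The last command prints the per-metric summary (mean +/- SD over the
100 treatment frames; this exact output is reproduced by
`scripts/acceptance.py --seed 1`):

```
INFO mmtrack: dice: 0.9618 +/- 0.0185
INFO mmtrack: hausdorff_mm: 0.7307 +/- 0.1718
INFO mmtrack: rmse_mm: 0.4115 +/- 0.0837
INFO mmtrack: centroid_si_mm: 0.2417 +/- 0.1672
INFO mmtrack: centroid_ap_mm: 0.1987 +/- 0.1414
INFO mmtrack: centroid_2d_mm: 0.3452 +/- 0.1626
```

Reading: the tracked contour overlaps the analytic ground-truth tumor
with a mean Dice of 0.96; the worst boundary point disagrees by
~0.7 mm (well under one pixel at 2 mm spacing), the typical boundary
disagreement is ~0.4 mm, and the tumor centroid — the quantity a
beam-tracking system would follow — is localized to ~0.35 mm.
`tracked/diagnostics.json` records, per frame, which library frame was
selected, the final cost, and the iteration count.

The same machinery is available as a library:

```python
from mmtrack import (PhantomParams, generate_sequence, PretreatmentLibrary,
                     RegistrationConfig, track_sequence, evaluate_contours)

study = generate_sequence(PhantomParams(seed=1))
library = PretreatmentLibrary(study.pretreatment.images, study.pretreatment.contours)
result = track_sequence(library, study.treatment.images, RegistrationConfig())
report = evaluate_contours(result.contours[0], study.treatment.contours[0],
                           study.params.image_size, study.params.spacing_mm)
print(report.dice, report.centroid_2d_mm)
```

## Layout

- `src/mmtrack/grid.py` — grid containers, centered-difference
  operators, bilinear interpolation
- `src/mmtrack/divcurl.py` — Poisson and div-curl solves (DST/DCT fast
  paths, sparse cross-check backends)
- `src/mmtrack/deformation.py` — monitor normalization, velocity ODE,
  Jacobian determinant
- `src/mmtrack/registration.py` — L2 dissimilarity, image force,
  projected-descent optimizer
- `src/mmtrack/tracking.py` — best-frame selection, contour
  propagation, per-frame tracking loop
- `src/mmtrack/metrics.py` — Dice / Hausdorff / RMSE / centroid, CSV +
  JSON reports
- `src/mmtrack/phantom.py` — synthetic free-breathing study generator
- `src/mmtrack/io.py`, `src/mmtrack/cli.py` — NIfTI/PNG/CSV readers and
  writers, `mmtrack` command-line interface
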