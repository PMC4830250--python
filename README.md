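# hemvol

Automatic hematoma volumetry on binary segmentation masks: per-slice
geometric measurement, adjusted-depth ABC/2 volume estimators, regression
calibration against planimetry, and a full accuracy-evaluation pipeline
with synthetic phantoms for validation.

## What it does

Given a 3-D binary mask of a segmented lesion (NIfTI, axial slices), the
package:

1. measures each slice's **area**, **maximum length** (longest distance
   between any two contour pixels, in physical mm) and **maximum
   perpendicular width** (longest chord orthogonal to the length axis)
   — `hemvol.slice_geometry`;
2. finds the lesion-bearing slices and computes the **unadjusted depth**
   `C0` (thickness × bearing-slice count) and the **adjusted depth** `C1`
   (area-ratio weighted: >75% → 1, 25–75% → 0.5, <25% → 0)
   — `hemvol.depth_model`;
3. evaluates the **ABC/2 variations** — traditional `0.5·A·B·C` forms and
   regression-calibrated forms `a·A·B·C + b` — on the largest-area and
   central representative slices, plus the **planimetry** reference volume
   — `hemvol.estimators`;
4. fits new variations by **OLS calibration** of planimetry on an
   A·B·C product — `hemvol.calibration`;
5. scores estimators with **percentage deviations**, deviation bins,
   **closest-value counts**, Levene-gated t-tests and **Bland–Altman**
   limits of agreement — `hemvol.evaluation`.

`hemvol.synthetic` generates ellipsoid, biconvex-lens and irregular
phantoms with known true volumes, and ships the packaged 53-case study
table (`hemvol.synthetic.load_study_fixture`, checksum-verified).

## CLI

```sh
hemvol measure   --mask lesion.nii [--thickness MM] [--spacing MM MM] [--seed N]
hemvol estimate  --mask lesion.nii --variation 2p --variation 4p
hemvol calibrate --table cases.csv --product A1B1C1
hemvol evaluate  --table cases.csv --out report/ [--tie-policy earlier|later]
hemvol simulate  --n 20 --seed 7 --outdir phantoms/
hemvol reproduce-study --out study/   # calibration + summary from the packaged table
```

Any command accepts `--config FILE` (JSON/YAML defaults; explicit flags
win). Variation names: `1 2 3 4` (traditional `0.5·product`) and
`1p 2p 3p 4p` (calibrated forms).

`reproduce-study` writes `calibration.json` (the four OLS fits),
`cases.csv` (per-case table) and `summary.csv`/`summary.json` (the
per-variation accuracy summary).

## Conventions

- All in-plane distances are between pixel centres in physical mm;
  anisotropic spacing is supported. Slices stack along the third array
  axis.
- Products `A·B·C` are expressed in mL (mm³/1000), so calibration
  coefficients and intercepts live on the mL scale.
- Closest-value ties go to the earlier-listed variation by default
  (configurable via `tie_policy`).
- Slice thickness above 5 mm triggers a warning (the estimators were
  validated on thinner scans only).
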