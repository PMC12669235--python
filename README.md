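# ssdekit

Size-specific dose estimates (SSDE) for CT from water-equivalent diameter,
including the slice-averaged-image (SAI) method.

Given an axial CT series plus scan-level dose metadata (mean CTDI_vol and
mean mAs, supplied as a JSON sidecar standing in for the Radiation Dose
Structured Report), `ssdekit` computes per slice:

* the body cross-section (−900 HU threshold, largest 8-connected component
  to remove the CT table, internal air filled),
* the water-equivalent diameter
  `D_w = 2·sqrt((mean_HU/1000 + 1)·A_ROI/π)` (cm),
* the per-slice dose index `CTDI_vol,z = (mean CTDI_vol / mean mAs)·mAs(z)`,
* the size-conversion factor `f(D_w) = 4.378094·exp(−0.04331124·D_w)`
  (32 cm reference phantom), and `SSDE_z = CTDI_vol,z·f(D_w,z)`,

and from these the three scan-level indices:

| index | definition |
|---|---|
| mean SSDE | unweighted slice average of SSDE_z (reference standard) |
| SSDE_center | mean CTDI_vol × f(D_w of the central slice) |
| SSDE_SAI | mean CTDI_vol × f(D_w of the per-pixel mean of all slices) |

plus an n-slice mean-D_w baseline (default n = 9, evenly spaced).

The package also ships a seeded synthetic trunk-phantom simulator (ellipse
body, lung inserts, CT table, Gaussian HU noise, exponential tube-current
modulation, exact analytic ground truth) and a statistical comparison
framework (OLS regression with R²/RMSE, error distributions defined as
reference − method, exact Wilcoxon signed-rank testing, error–covariate
correlation).

DICOM I/O uses a small built-in codec covering uncompressed single-frame
little-endian CT images — the only flavor the toolkit reads or writes — so
there is no dependency on a full DICOM library.

## CLI

```
# dose indices for a DICOM series
ssdekit compute <dicom_dir> --dose-record record.json \
    [--method all|mean|center|sai|nslice] [--nslice 9] \
    [--threshold-hu -900] [--save-sai sai.dcm] \
    [--profiles-csv profiles.csv] --out summary.json

# synthetic phantoms (DICOM series + dose_record.json + ground_truth.json)
ssdekit simulate --out <dir> [--template cap] [--n-slices 40] \
    [--cohort N] [--noise-sigma 5] [--seed S]

# method comparison over a per-case summary table
ssdekit compare --cases cases.csv --out report.json \
    [--by-region/--no-by-region] [--rmse residual|raw]
```

The dose-record sidecar is JSON with keys `mean_ctdi_vol` (mGy),
`mean_mas` (mAs), `reference_phantom_diameter` (16 or 32; 32 expected for
trunk protocols) and optional `tube_voltage`.

Two RMSE conventions are available in `compare` because regression tables
in the literature rarely state which is meant: `residual` (about the
fitted line, the default) and `raw` (directly between method and
reference values).

## Library example

```python
import ssdekit as sk

cases = sk.make_cohort(10, "cap", seed=1)
volume, record, truth = cases[0]
summary, profiles = sk.summarize_scan(volume, record)
print(summary.mean_ssde, summary.ssde_center, summary.ssde_sai)
```
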