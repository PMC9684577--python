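# iopcorr

Method-comparison toolkit for paired tonometry readings: applies published
Goldmann-applanation (GAT) correction formulas to per-eye records and
quantifies agreement with dynamic-contour tonometry (DCT) using paired
t-statistics and Bland–Altman analysis.  Ships a moment-calibrated synthetic
cohort generator so the entire pipeline is exercisable without clinical data.

## What's inside

| module | contents |
|---|---|
| `iopcorr.cohort` | `EyeRecord`/`Cohort` domain types, CSV I/O, keratometry↔radius conversion (index 1.3375) |
| `iopcorr.corrections` | registry of ten GAT-correction formulas (`shimmyo`, `shimmyo_r`, `elsheikh2009`, `elsheikh2011`, `srodka`, `chihara`, `doughty`, `foster`, `kohlhaas`, `ehlers`) as pure vectorized functions with overridable constants |
| `iopcorr.agreement` | paired comparisons (signed + absolute), Bland–Altman with fixed/proportional-bias flags, Monte-Carlo (Lilliefors-style) KS normality |
| `iopcorr.power` | paired t-test sample size via exact noncentral-t power iteration |
| `iopcorr.synthetic` | structural generator: true IOP + thickness-linear applanation bias + independent instrument noises, with closed-form moment calibration |
| `iopcorr.pipeline` | `run_study` orchestration, report/table/coordinate exports |
| `iopcorr.cli` | `iopcorr` command-line tool |

Unit conventions: IOP in mmHg, central corneal thickness in µm at every
boundary (formulas published in mm convert internally), corneal radius in mm,
age in years.

Notable normative readings of ambiguously printed formulas (full rationale in
the module docstrings): the Shimmyo thickness correction defaults to the
linear `(550 − CCT)/18` with `power`/`literal` exponent variants behind a
config switch; the Ehlers correction is the affine `0.071·(520 − CCT)`; the
Chihara formula is evaluated with thickness/radius in mm (under which it is
numerically `GAT + 4.15`); the Śródka geometric multiplier uses `e = 1 mm⁻¹`
and a quadratic calibration polynomial; the Elsheikh 2009/2011 coefficient
functions are config-injected polynomials with identity defaults (their
published coefficients are not bundled).

## CLI

```sh
# generate a calibrated synthetic cohort
iopcorr simulate --n 112 --seed 112 --out cohort.csv

# apply one formula (adds an iop_corrected column)
iopcorr correct --formula kohlhaas --in cohort.csv --out corrected.csv

# agreement statistics for one formula
iopcorr agree --formula srodka --in cohort.csv

# paired t-test sample size
iopcorr power --alpha 0.05 --power 0.8 --delta 0.5 --sd 1.5

# full study: report.json, table2.csv, table3.csv, blandaltman_<formula>.csv
iopcorr report --simulate --seed 112 --n 112 --outdir out/
iopcorr report --in cohort.csv --outdir out/
```

Cohort CSV schema: `subject_id,age,cct_um,r_mm,km_D,iop_gat,iop_dct`
(`r_mm`/`km_D` may be blank; keratometry is auto-converted to a radius when
the radius is absent; formulas whose inputs are missing are skipped with a
warning in `report`).  A YAML config file can override formula constants and
agreement settings:

```yaml
corrections:
  shimmyo: {variant: power}
  srodka: {e_per_mm: 1.0}
  elsheikh2009: {a_cct: [0.92, 0.00015]}   # ascending polynomial coefficients
agreement: {k: 2.0, alpha: 0.05}
```

Exit codes: 0 success, 2 usage, 3 schema error, 4 record validation error,
5 numeric/dependency error.

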