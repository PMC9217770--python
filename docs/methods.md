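# Methods

## Risk model

For each organ at risk the projected radiation-induced secondary-malignancy
risk is computed in three steps.

**Risk-equivalent dose.** Carcinogenesis is linear in dose at low dose; at
the fraction doses used in breast radiotherapy, cell sterilization competes
with induction. The default kernel is the linear-exponential form
`RED(D) = D·exp(−αD)` (Gy), which peaks at `D = 1/α` (7.75 Gy for lung,
α = 0.129 per Gy) and decays beyond it. A pure linear kernel (the low-dose
limit) and a plateau kernel `(1 − exp(−δD))/δ` are available but disabled by
default; all shipped results use the linear-exponential form.

**Organ equivalent dose.** Organ doses are non-uniform, so the mean organ
dose is the wrong summary for risk: the same mean can come from a small
near-field hot region (where cell killing suppresses induction) or a diffuse
low-dose bath (where it does not). The OED is the volume-weighted mean of
RED over the differential DVH, `OED = Σ (v_i/V_T)·RED(D_i)`, evaluated at
bin centers on half-open bins `[edge_i, edge_{i+1})`. The bin-center
convention matches planning-system export semantics; a grid-refinement test
shows OED moves by < 0.5% between 0.1 Gy and 0.01 Gy bins for smooth DVHs,
and a voxel-sampling Monte-Carlo oracle agrees with the bin-center sum
within sampling error on random histograms.

**Excess absolute risk.** `EAR = µ·OED` in units of cases per 10,000
person-years; EAR = 1 means one excess malignancy per 1000 treated patients
over 10 years. Coefficients are held fixed — no age-at-exposure, attained-age
or latency modification — so EARs are *projections* for comparing techniques,
not absolute clinical predictions. Shipped values:

| tissue    | α (per Gy) | µ (per 10⁴ PY per Gy) |
|-----------|-----------:|----------------------:|
| lung      | 0.129      | 9.47                  |
| thyroid   | 0.033      | 0.86                  |
| esophagus | 0.274      | 1.9                   |
| breast    | 0.25       | 2.49                  |

The three lung structures (combined, ipsilateral, contralateral) share the
lung coefficients. The combined-lungs DVH is treated as the volume-additive
union of the two sides, which makes its OED exactly the volume-weighted mean
of the per-side OEDs.

## Imaging dose

Daily CBCT guidance for conventional-linac PBI adds dose to every organ.
The package models it as a uniform organ-level DVH shift by the protocol's
per-organ mean-dose increment, scaled linearly in scan count from the
reference totals (15 scans: 0.55/0.52/0.66/0.36/0.51/0.45 Gy for
contralateral breast / both lungs / ipsilateral lung / contralateral lung /
thyroid / esophagus; a 6-scan WBI protocol ships with 0.22/0.23/0.26/0.15/
0.15/0.20 Gy). This replaces a voxel-level Monte-Carlo dose calculation and
is the module's central approximation: only organ-mean increments are
published, the shift reproduces the organ mean exactly, and for a ≤ 0.7 Gy
component the OED error from ignoring spatial heterogeneity is second-order.
The two protocols are kept independent (no shared per-scan dose is
enforced) because patient anatomy and field arrangements differ between
them. Planning-CT dose is excluded: it is identical across platforms and
cancels from every comparison. By default WBI patients get no CBCT dose in
risk estimates (scan counts were patient-specific in practice); the 6-scan
assignment is available as a sensitivity mode.

## Statistics

Per organ, group EARs (n = 11 per group) are summarized as mean ± sample SD
and compared with the two-sided Welch (unequal-variance) t-test; raw
p-values are multiplied by the family size m = 4 (the four comparison
columns within an organ) *without* capping at 1, and significance is called
at 0.05 on the adjusted value. The Welch variant and the uncapped ×4 factor
were chosen because they jointly reproduce the published comparison table
from its printed summaries — adjusted cells above 1 (1.737, 3.96, 2.714)
are only consistent with an uncapped ×4 product, and the near-zero
CBCT-column cells match Welch but not the pooled-variance test.
Shapiro–Wilk normality screening is computed and reported but never gates
the t-test; degenerate (zero-variance) samples raise instead of silently
passing. Auxiliary comparisons (planning-target volume, contralateral-breast
maximum dose) use the same Welch machinery with a configurable family size
(default 1).

## Synthetic cohort

No per-patient planning data are available, so the pipeline ships a seeded
generator that emulates the three treatment groups (PBI at the MR-linac,
PBI and WBI at the conventional linac; 11 patients each; 40.05 Gy in 15
fractions).

**Dose model.** Each group × organ pair has a two-component mixture: a
fraction `p_high` of the organ volume receives a truncated-normal
"near-field" dose and the remainder an exponential low-dose bath — the
simplest family that can match both the published group-mean EARs and the
contralateral-breast maximum doses, and a reasonable cartoon of the bimodal
organ-at-risk DVHs seen in breast radiotherapy. Doses are capped at 110% of
prescription; organ volumes are truncated-normal (≥ 10 cm³). 4000 voxel
samples per organ are histogrammed at 0.1 Gy.

**Heterogeneity.** Each patient draws one standard-normal `z`; every organ
applies the multiplier `exp(σ_organ·z)` to `p_high` and the bath scale. A
shared `z` with organ-specific `σ` makes organ doses correlate within a
patient (as anatomy induces) while letting each organ match its published
between-patient spread.

**Calibration.** `calibrate_profiles` scales each profile by coordinate
search — `p_high` and bath scale toward the target mean EAR, the near-field
mean toward the target maximum dose, `σ` toward the target coefficient of
variation — using common random numbers, aiming at half of the acceptance
tolerances (mean ±10%, SD ±30%, Dmax ±20%) so accepted profiles sit inside
the band rather than on its edge. The shipped defaults in `_profiles.py`
were produced by one seeded calibration run against the published group
summaries; regenerating them is a one-liner documented there.

**What the generator does not emulate.** DVH shapes beyond the calibrated
summaries, anatomical correlation structure beyond the single shared
multiplier, dose gradients, and any MR-linac-specific physics (electron
stream/return effects enter only through the published summary differences).
Passing cohort-level tests therefore demonstrates that the *pipeline*
reproduces the published group-level statistics under a faithful statistical
emulation — not that the generator reproduces real planning data.

**A known distributional limit.** With group distributions matched to the
published means and SDs at n = 11, the *joint* significance pattern of the
"PBI at CTL vs PBI at MRL" column (breast lower at the MRL and thyroid
higher, both significant; all three lung rows non-significant) recurs in
only ~30% of seeded replicates: the published thyroid effect has ~65% power
at the ×4-adjusted threshold and the contralateral-lung comparison sits
close to it (its own adjusted value is 0.132), so it crosses 0.05 in about a
third of replicates. This is a property of the published effect sizes at
n = 11, not of the implementation; the per-condition rates are reported by
the acceptance script.

## Numerical choices

- Bin convention: half-open `[edge_i, edge_{i+1})`, dose at bin center;
  default export width 0.1 Gy.
- Volume bookkeeping is exact: conversions, rebinning and uniform shifts
  conserve total volume to < 1e−6 relative (asserted by the containers).
- Maximum dose is the upper edge of the highest bin with volume above
  1e−9 cm³ (numerical zero); no volume criterion is applied.
- Cumulative inputs that do not reach zero volume get a trailing residual
  bin of the last grid spacing.
- Relative-volume (%) DVH files require an explicit `volume_cm3` header;
  there is no silent default.
- Welch degrees of freedom follow Welch–Satterthwaite; p-values come from
  the t survival function (cross-checked against an independent permutation
  test and scipy's implementation in the test suite).
- Per-patient random streams are spawned from the master seed by patient
  index, so cohorts are bit-reproducible and independent of iteration order.
- Problem sizes used by the shipped studies: 4000 voxels per organ DVH,
  200 cohort replicates for distributional checks, 2×10⁵ samples per DVH
  for the Monte-Carlo oracle.

## Limitations

- EAR projections inherit large literature uncertainties in α and µ; only
  *between-group* contrasts within an organ are robust, since coefficients
  cancel.
- The uniform CBCT shift ignores intra-organ heterogeneity of the imaging
  dose.
- The generator's inter-patient model is a single lognormal factor per
  patient; real cohorts have richer covariance (size, laterality, BMI).
- No age-modified risk coefficients, no relative-risk (ERR) models, no
  site-specific latency; out of scope by design.
- DICOM RT-DOSE/RT-STRUCT import is a declared extension point; the shipped
  reader handles the text dialect only.
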