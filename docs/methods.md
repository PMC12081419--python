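# Methods

## Measurement model

A counting session examines `N_fields` SEM fields of area `a` (mm²,
calibrated per instrument at ×12,000 — never hard-coded) on a membrane
of active area `A` (mm²) carrying `p_TS` grams of dry tissue. With the
deposit homogeneous and fields sampled equiprobably, the fiber
concentration is the area-proportional extrapolation

```
C = n_f · A / (N_fields · a · p_TS)      [ff/g dry]
```

and the analytical sensitivity `AS = A/(N_fields·a·p_TS)` is the
concentration a single fiber represents, so `C = n_f · AS` holds as an
exact identity. `p_TS` follows from the preparation record:
`dry_mass_ashed · filtered_volume / suspension_volume` (100 mg ashed,
suspended in 100 mL, 20 mL filtered → 20 mg on the filter, an ash load
of ~9 mg/cm² on a 2.22 cm² membrane). Loads above 15 mg/cm² raise an
advisory flag only: overloading is a countability problem, not an
arithmetic one. A zero filtered volume is accepted as a procedural
blank; concentration and sensitivity are undefined for it and error.

**Counting rule.** Only asbestos-classified particles strictly longer
than 1 µm count; a fiber of exactly 1 µm does not. Non-asbestos
particles never count regardless of size.

**Counting uncertainty.** The count is modelled as Poisson, SD √n, so
the concentration CV is `100/√n_f` percent — 14.1% at the 50-fiber
stop, 28.3% expanded with coverage factor 2. Confidence intervals use
the exact (Garwood) gamma-quantile form by default,
`[qgamma(α/2, n), qgamma(1−α/2, n+1)]` scaled by AS, because sessions
with few fibers are routine; a normal `n ± z√n` option exists for
comparison with older reports. A zero count returns concentration 0,
a one-sided exact upper limit (`−ln(1−level)·AS`), and a
below-sensitivity flag rather than an error, since blanks produce zero
counts by design. Exact intervals are deliberately conservative:
analytic coverage at a true mean of ~44 counts is 95.7%, rising toward
99% at very small means.

**Planning.** `plan_fields` returns the smallest integer `N_fields`
with `AS ≤ target`; the boundary is settled by direct evaluation of the
same expression so float rounding cannot shift it by one field. A
target needing more fields than the filter holds (`N·a > A`) raises an
infeasible-plan error. The recommended sensitivity, 0.1 mil ff/g dry,
needs 1110 fields under the reference preparation. The working-range
upper end (~300 mil ff/g dry) is carried as a reporting constant with
the advice that a lower tissue load extends it; no derivation is
attempted.

Units: concentrations are stored in ff/g dry and reported in
`mil ff/g dry` (10⁶ ff/g), conversion factor fixed at 10⁶.

## CRM verification

Replicate campaigns (n = 8) on BCR-665 and BCR-666 are assessed by:

* **Precision:** `χ²_c = (s_w/σ_w0)²` with the sample SD `s_w`
  (n−1 denominator) and a *supplied* reference SD `σ_w0`; pass when
  strictly below `χ²(n−1; 0.95)/(n−1)` (2.01 at n = 8).
* **Trueness:** `|x̄ − x_CRM| ≤ k·√(u_meas² + u_CRM²)`, k = 2,
  boundary equality passing; `u_CRM = U/t` with the certificate
  t-factor (2.45, numerically a two-sided 95% Student factor at 6 df).

`σ_w0` and `u_meas` are inputs, not derived quantities: the Poisson
reference SD depends on how many fibers each measurement accumulates,
and the standard uncertainty of a result can carry components beyond
replicate scatter. The helper `poisson_reference_sd(C, n_max) =
C/√n_max` offers the pure-Poisson choice but is never invoked
implicitly. Published verification tables round intermediates before
printing; the bundled BCR-666 summary is internally inconsistent at
two cells ((0.92/0.72)² = 1.63, not 1.56; 2√(0.87²+0.61²) = 2.13, not
2.26 — the unrounded `s_w` and `u_meas` were not published). The tests
assert the recomputed values and document the mismatch; both verdicts
hold under either value, so the verification outcome is unaffected.

## Synthetic counting model

The simulator draws per-field countable-fiber counts i.i.d.
Poisson(λ) with `λ = C_true · p_TS · a / A` — the measurement formula
inverted — and walks fields until the planned area (from the target
AS, default 0.1 mil ff/g dry) is covered or the cumulative count
reaches the cap (default 50). The cap stop *completes the current
field*: the SEM operator's atomic unit is the field, and whole-field
bookkeeping keeps the examined area well defined. Filter inhomogeneity
is modelled as a gamma-mixed Poisson with a single dispersion
parameter d (per-field variance `λ(1+dλ)`; d = 0 by default, matching
the homogeneity the protocol demands of an acceptable filter). Fiber
lengths are cosmetic for the count statistics: log-normal
(µ = ln 3 µm, σ = 0.8) truncated below at 1 µm so every generated
fiber is countable, with an optional sub-micron fraction (generated at
rate `λ·f/(1−f)`, lengths uniform on 0.2–1 µm) to exercise the
counting rules. Widths are a uniform 2–30% of length. All randomness
flows from one `numpy` Generator seeded per config; campaigns are
bit-reproducible.

What the model does **not** emulate: spatial clustering beyond the
gamma mixture, EDS misclassification, inter-batch CRM variance
(replicates are i.i.d.), fiber fragmentation or clearance. Passing
tests therefore certify the statistical machinery under the method's
own assumptions, not the behaviour of real lung tissue.

**Stop-rule bias.** Stopping at the fiber cap makes `n_f/N_fields` a
waiting-time (inverse-sampling) ratio estimator with a known upward
relative bias of about `1/(cap−1)` ≈ 2% at the default cap of 50
(measured 2.08% ± 0.05 at the BCR-665 burden; 1.94% at ≥5 fibers per
field, where the within-field overshoot damps it). With the cap not
binding the examined area is fixed, the total count is Poisson, and
the estimator is exactly unbiased — the regime used for the
parameter-recovery and interval-coverage checks. The bias is an
inherent property of the field protocol, small against the ~14%
counting CV, and is asserted in the tests rather than corrected.

## Study sizes and numerical choices

Calibration experiments use 500 eight-replicate campaigns for the
pass-rate study, 4000 sessions for parameter recovery and 10⁴ for
interval coverage — sizes at which binomial/MC standard errors
(≤1.3%, ≤0.25%, ≤0.25% respectively) are small against the margins
being checked, while the whole study runs in seconds. The coverage and
recovery experiments fix a 100-field plan at the BCR-665 burden
(expected count ≈ 44) with the cap disabled, where analytic coverage
of the exact interval is 95.7%, inside the conservative band expected
of Garwood intervals at moderate means. Oracle comparisons for the
interval use a 10⁻⁴-step grid inversion of the Poisson CDF with
tolerance 10⁻³ on the mean.

## Interfaces

Count sheets are CSV (`field_index,length_um,width_um,mineral_class`,
one row per fiber) with a companion session JSON carrying
`n_fields_examined` and the stop reason, so empty examined fields need
no CSV rows. Preparation, CRM and simulation configs are small JSON
documents; the two CRM descriptors (certificate values plus the
published replicate summaries) ship with the package. The `fiberburden`
CLI exposes the four workflows (`concentration`, `plan`, `validate`,
`simulate`) as a thin layer over the library; reports echo their
inputs, `--strict` turns failed verdicts into a distinct exit code, and
parse, invalid-config and infeasible-plan errors exit with separate
codes (2/3/4/5).

## Known limitations

* `σ_w0` and `u_meas` must be supplied; the package cannot audit a
  laboratory's choice of them.
* The working-range upper bound is a constant, not a derived limit.
* Real count sheets may terminate mid-field at the fiber cap; the
  simulator (and the bias figures above) assume whole-field stops.
* Chrysotile has no certified lung-tissue reference material, so the
  verification path covers amphiboles only.
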