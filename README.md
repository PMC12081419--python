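# fiberburden

Quantification of the asbestos fiber burden in human lung tissue from
SEM membrane-filter counts, with Poisson counting statistics, analytical
sensitivity and examination planning, ISO-style method verification
against certified reference materials, and a seeded simulator of the
counting process.

## The problem

Past asbestos exposure is assessed by counting mineral fibers retained
in lung tissue. A known mass of freeze-dried tissue is ashed, the ash is
suspended and an aliquot filtered onto a membrane, and asbestos fibers
longer than 1 µm are counted by SEM-EDS in a number of microscope fields
at ×12,000. Because only part of the filter is examined, the count is
extrapolated by area proportion:

```
C  =  n_f · A / (N_fields · a · p_TS)        [fibers per gram of dry tissue]
```

where `n_f` is the number of countable fibers, `A` the active
filtration area, `a` the area of one SEM field, and `p_TS` the dry
tissue mass on the filter. The counting error is Poisson — the SD of a
count of n is √n — so the relative SD of `C` is `1/√n_f` (≈14% at the
customary 50-fiber stop, 28% expanded with k = 2). The **analytical
sensitivity** `AS = A/(N_fields·a·p_TS)` is the concentration one
single fiber represents; `C = n_f · AS` exactly. Results are reported
in `mil ff/g dry` (10⁶ fibers per gram of dry tissue).

Method verification uses the certified lung-tissue materials BCR-665
(amosite + crocidolite, 49.0 mil ff/g dry) and BCR-666 (anthophyllite,
5.1 mil ff/g dry), measured in replicate (n = 8):

* **precision** — `χ²_c = (s_w/σ_w0)²` against
  `χ²(n−1; 0.95)/(n−1)`, with the Poisson SD as reference `σ_w0`;
* **trueness** — `|x̄ − x_CRM| ≤ k·√(u_meas² + u_CRM²)` with k = 2,
  the certificate's standard uncertainty recovered as `u = U/t`.

Because no raw lung-tissue count sheets are publicly deposited, the
package includes a generative model of the counting process (per-field
Poisson deposition, optional gamma overdispersion, the area/50-fiber
stop rules) so every statistical property is testable end to end.

## Worked example

```python
from fiberburden import (FilterPrep, FiberRecord, CountingSession,
                         MineralClass, compute_concentration, plan_fields, MIL)

prep = FilterPrep(dry_mass_ashed_mg=100, suspension_volume_ml=100,
                  filtered_volume_ml=20, active_area_mm2=222.0,
                  field_area_mm2=1e-4)          # calibrated field at x12,000
fibers = tuple(FiberRecord(i % 100, 3.0, 0.3, MineralClass.AMOSITE)
               for i in range(9))
session = CountingSession(n_fields_examined=100, fibers=fibers)
r = compute_concentration(session, prep)
```

prints (via the fields of `r`):

```
n_f = 9, N_fields = 100
C  = 9.99 mil ff/g dry
AS = 1.11 mil ff/g dry
SD = 3.33  (CV 33.3%)
95% CI = [4.57, 18.96] mil ff/g dry
```

Nine fibers over 100 fields of a 20 mg-loaded filter give
9.99 mil ff/g dry; each fiber is worth 1.11 mil ff/g (the analytical
sensitivity), and the exact (Garwood) interval reflects the small
count. `plan_fields(0.1 * MIL, prep)` → `1110`: reaching the
recommended sensitivity of 0.1 mil ff/g dry requires 1110 fields.

The same workflows are available from the shell:

```
fiberburden validate --crm bcr665
```

reports the full BCR-665 verification (`chi2_c = 1.148 < 2.010`,
`|x̄−x_CRM| = 0.6 ≤ 19.74`, both verdicts `true`), and
`fiberburden concentration / plan / simulate` cover the other
workflows; see `--help`.

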