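# Methods

## Problem and scope

During capsule landings and launch aborts, a seated, suited crewmember is
exposed to short transient loads (tens of g over tens of milliseconds).
Occupant-protection requirements are phrased as injury assessment
reference values (IARVs): thresholds on quantities measured on the THOR
50th-percentile-male anthropomorphic test device (ATD) that must not be
exceeded at a stated acceptable probability of injury. This package
regenerates the full IARV table end to end from published risk-model
coefficients, computes the underlying signal metrics (HIC-15, BrIC, ADFS)
from time-history channels, and provides the surrogate-scale transfer
functions and a synthetic channel generator so every stage is testable
without any external data.

## Risk-function families

Each injury metric `x` has a dose-response model for the probability of an
injury at or above AIS (abbreviated injury scale) severity `n`:

* **Weibull**: `p = 1 - exp(-(x/beta_n)^alpha)`. HIC-15 uses
  `alpha = 4.34`, `beta_1 = 671`; BrIC uses `alpha = 2.84` with per-level
  scales that were never published (see "Missing parameters").
* **Ordered probit**: `p(AIS>=n) = 1 - Phi(c_n - beta*x)` with strictly
  increasing cut points `c_n`, used for neck axial tension
  (c = 6.30/8.56/9.28/10.19, beta = 0.0053 1/N), sternal compression
  (c = 4.17/5.61/6.29/7.32, beta = 0.103 1/mm) and ankle
  inversion/eversion (c = 4.0, beta = 0.10 1/Nm).
* **Logistic**: `p = 1/(1 + exp(a - b*x))`, used for the THOR lateral
  (acetabular) force (a = 6.403, b = 0.0011 1/N), ankle dorsiflexion
  (location 60.23 Nm, scale 9.217 Nm — the inversion uses the natural
  logarithm, the only base consistent with the published limits), the two
  forearm-moment fits, the distal-forearm-speed fits (intercepts 6.749
  PMHS-scale / 9.845 THOR-scale, slope 0.645 s/m), and the FMVSS/NCAP
  chest curves.
* **Covariate neck-compression tolerance**:
  `Fz50 = 934.2 + 8.9*A + 11.0*LR + 665.0*G - 0.134*A*LR` N, with age A
  (years), loading rate LR (m/s; 2 m/s adopted as the conservative
  default) and gender indicator G (0 female, 1 male). The logistic
  steepness around that tolerance was never published, so only the
  tolerance itself is evaluable.
* **DRI chain**: spinal injury risk **in percent** satisfies
  `p% = 10^((DRI - 15.8)/3.73)`; the percent convention (DRI 15.8 at 1%)
  is the only reading under which the published 5.80 kN nominal thoracic
  force reproduces. The THOR thoracic axial force maps to DRI by the
  fitted regression `DRI = 3.62*Fz - 2.59` (Fz in kN); the reverse-fitted
  `Fz = 0.277*DRI + 0.795` is also exposed but the two printed fits are
  not exact algebraic inverses, and the pipeline uses the force-to-DRI
  direction, which is the one the table encodes.

All closed-form inversions are cross-checked in tests against a bisection
root of the forward curve (independent numerical oracle) and round-trip to
1e-9 relative.

Logistic fits whose curves do not pass through the origin can invert to a
negative metric value at small probabilities (the SAE instrumented-arm
forearm fit at 1% is the canonical case, published as a limit of 0). Such
inversions are clamped to zero and announced with a `ClampedInversionWarning`,
never silently.

The hip-fracture model is lognormal in force with stature and posture
covariates. The posture factor is taken as
`1 - ((flexion - 30) - (abduction - 15))/100`, i.e. equal to 1 in the
neutral posture (flexion 30 deg, abduction 15 deg); the published grouping
is ambiguous on whether the raw angles or their deviations from neutral
enter, and the neutral-anchored reading is adopted because a risk curve
whose posture factor is not 1 at the stated neutral posture would shift the
published stature-only median. The grouping is isolated in one method so
the alternative reading is a one-line change.

## Acceptable risk and the IARV table

The acceptable-risk table maps injury class to a probability ceiling per
landing condition: class I (AIS1+) 5% nominal / 19% off-nominal, class II
(AIS2+) 1% / 4%, class III 0.3% / 1%, class IV 0.03% / 0.1%. The governing
class per metric: HIC-15, neck tension, chest deflection and the thoracic
DRI chain use class I (their AIS1+ curves are the most conservative);
shoulder, acetabular, ankle and forearm metrics use class II; BrIC takes
the minimum limit over all four classes.

Derivation order, chosen to reproduce every published deconditioned cell:

1. invert the governing risk model at the class probability (shoulder at
   the eldest-astronaut age, 56 years, where the age-dependent curve is
   lowest);
2. round to **two significant digits, half-up** (878.3 N -> 880; 16.5 ->
   17 and 13.5 -> 14, which only half-up reproduces; 23.25 -> 23);
   implemented in decimal arithmetic so binary-float halves round as
   written;
3. multiply the **rounded** conditioned value by the deconditioning factor
   (0.86 spinal, 0.75 lower extremity, 1.0 elsewhere) and re-round
   (1000 x 0.86 = 860; deconditioning the unrounded 1023 N would give 880,
   which is not what the published table holds).

The THOR/PMHS neck tension gain (1.38) is available in the transfer
catalog but is not applied in the tabulation path: the published 880 N
matches the unscaled probit inversion.

### Statuses instead of silent agreement

`build_iarv_table` attaches a status to every conditioned cell:

* `derived` — computed, and its two-significant-digit rounding equals the
  published value (27 cell values in total, counting deconditioned cells);
* `missing-parameter` — the model cannot be inverted because a coefficient
  was never published: the BrIC per-AIS scale parameters and the
  neck-compression logistic steepness. These rows carry the published
  values as reference constants only.
* `published-discrepancy` — the chain computes a value whose rounding differs
  from the published cell. The only instance is the thoracic spine
  off-nominal limit: the DRI chain at 19% gives 6,398 N -> 6,400, while
  the published table holds 6,500 N. The published value is adopted for
  the table (so the deconditioned cell reproduces: 6500 x 0.86 = 5590 ->
  5600) and the computed value is reported alongside.

## Signal metrics

* **HIC-15**: maximum of `((1/(t2-t1)) * int a dt)^2.5 * (t2-t1)` over
  windows `0 < t2-t1 <= 15 ms`. Integration is trapezoidal on the native
  (possibly non-uniform) time base; window endpoints are restricted to
  sample instants, which makes the search exactly equal to an O(n^2)
  all-pairs oracle (asserted over 200 randomised fixtures). Admissibility
  is judged on `t2 - t1` itself so boundary windows resolve identically in
  both implementations. Acceleration must be a non-negative resultant in g.
* **BrIC**: `sqrt(sum_i (max|omega_i| / omega_iC)^2)` with critical rates
  (66.3, 53.8, 41.5) rad/s about X, Y, Z. Per-axis maxima may occur at
  different times (the definition imposes no temporal coupling).
* **ADFS**: both a peak mode and a trapezoidal windowed-average mode are
  exposed, because the literature alternates between "average" and "peak"
  distal forearm speed and the exact averaging interval is defined in the
  source experiments, not reproducible here. Mass scaling to another
  surrogate arm is linear: `+1.94 (m/s)/kg` about the 2.67 kg reference
  arm; the THOR (Hybrid-III) arm assembly is 4.27 kg.
* No CFC filtering is applied by default (none is specified for these
  metrics); `hic15` accepts an optional pre-filter callable.

## Synthetic data

`make_pulse` renders haversine, half-sine, trapezoid (25/50/25 rise/
plateau/fall) or constant pulses at a default 10 kHz — typical
crash-channel capture, high enough that discrete metrics sit within 0.1%
of analytic values for the pulse durations used (a convergence test
asserts the error decreases with rate). Gaussian additive noise is
available but defaults to zero so oracle comparisons stay exact; all
generators are `numpy.random.Generator`-seeded and regenerate
byte-identical CSVs.

The generator emulates the unimodal, smooth, single-event character of
capsule-landing sled pulses. It does not emulate multi-impact landings,
channel cross-talk, sensor noise spectra, or suit/seat contact dynamics —
passing tests demonstrate metric and pipeline correctness on clean
unimodal inputs, not robustness to real instrumentation artefacts.

`sample_landings` draws a scalar severity index from a normal distribution
and classifies draws into nominal (<= mu + 1.5 sigma), off-nominal
(<= mu + 2.5 sigma) and contingency bands; at 10^6 draws the empirical
fractions recover the normal-CDF design-table values (93.3%, 6.1%, 0.6%)
within Monte-Carlo error. `landing_mode_stats` reports the closed-form
band statistics; the "1 in n" column rounds `1/(1-Phi(k))` to the nearest
integer, which at k = 3 gives 1 in 741 (a published variant, 1 in 769,
corresponds to rounding the tail percentage to 0.13 first; the closed form
is reported as computed).

## Missing parameters and known limits

* BrIC per-AIS Weibull scales and the neck-compression steepness `beta5`
  are unpublished; the models raise `MissingParameterError` until the user
  supplies them, and the IARV table flags those rows. The published BrIC
  limits (0.04 / 0.07) and neck-compression limits (580 / 1,100 N) are
  carried as reference constants.
* The pelvic-force composition is internally inconsistent in the sources:
  the EuroSID risk slope (0.00163) combined with the THOR-to-EuroSID gain
  (1.47) does not reproduce the THOR-scale slope (0.0011) in either
  direction; the THOR-scale curve is used as printed and the mismatch is
  documented in a test.
* Confidence scores (0-5 per row) are expert judgments, stored as
  constants, not computed.
* No uncertainty bands are propagated (only point fits were published).

## Parameter files

All coefficients ship embedded with citation strings
(`thoriarv.parameters.default_parameters`) and can be dumped to or loaded
from YAML; a partial file overrides only the coefficients it names, and
`models_from_parameters` rebuilds every model instance from the merged
mapping.

## Problem sizes

Everything except the Monte-Carlo landing check is closed-form and runs in
milliseconds. The test suite uses 200 randomised HIC fixtures of 60-400
samples against the O(n^2) oracle, and 10^6 landing draws for the band
fractions; both complete in seconds.
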