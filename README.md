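# thoriarv

Injury risk functions and injury assessment reference values (IARVs) for
the THOR anthropomorphic test device in spaceflight landing and launch-abort
conditions.

Capsule landings expose a seated crewmember to short transient loads.
Occupant-protection requirements cap each measurable injury metric — head
injury criterion (HIC-15), brain rotational injury criterion (BrIC), neck
axial forces, chest deflection, shoulder and acetabular lateral forces,
thoracic spine compression, ankle moments, distal forearm speed — at the
value where its dose-response risk function reaches an acceptable
probability of injury (5% nominal / 19% off-nominal for AIS1+ metrics,
1% / 4% for AIS2+). This package is for biomechanics and crashworthiness
engineers who need those limits derived transparently rather than copied:
it regenerates the full IARV table from the published risk-model
coefficients, computes the signal metrics from time-history channels, and
flags every cell that *cannot* be derived (unpublished parameters) or that
disagrees with its published value.

The core computation is the closed-form inversion of each risk family at
an acceptable probability `p`:

* Weibull (HIC-15): `IARV = beta * (-ln(1-p))^(1/alpha)`, alpha = 4.34,
  beta = 671;
* ordered probit (neck tension, chest, ankle inversion/eversion):
  `IARV = (c_n - Phi^{-1}(1-p)) / beta`;
* logistic (acetabular force, dorsiflexion, forearm, ADFS):
  `IARV = (a - ln(1/p - 1)) / b`;
* DRI chain (thoracic spine): `DRI = 3.73 log10(p%) + 15.8`, then
  `Fz = (DRI + 2.59)/3.62` kN;

followed by two-significant-digit half-up rounding and spaceflight
deconditioning factors (0.86 spine, 0.75 lower extremity) applied to the
rounded value.

## Worked example

```python
>>> from thoriarv import build_iarv_table, hic15, bric
>>> from thoriarv.synthetic_data import PulseSpec, make_channelset
>>> records = build_iarv_table()
>>> rec = records["neck_tension"]
>>> rec.conditioned, rec.deconditioned, rec.status
({'nominal': 880.0, 'off_nominal': 1000.0},
 {'nominal': 760.0, 'off_nominal': 860.0},
 {'nominal': 'derived', 'off_nominal': 'derived'})
>>> rec.computed["nominal"]          # before rounding
878.3295043487788
```

The nominal neck-tension IARV comes from inverting the ordered probit
`1 - Phi(6.30 - 0.0053 Fz)` at 5%: 878.3 N, rounded to 880 N; the
deconditioned limits are the rounded values times the 0.86 spinal factor,
re-rounded (880 -> 760, 1000 -> 860). The thoracic spine row shows how
disagreement is surfaced rather than absorbed:

```python
>>> thor = records["thoracic_spine_force"]
>>> thor.status["off_nominal"], thor.computed["off_nominal"], thor.conditioned["off_nominal"]
('published-discrepancy', 6397.721251810512, 6500.0)
```

the DRI chain at 19% yields ~6,400 N while the published table holds
6,500 N. Signal metrics work on channel objects:

```python
>>> cs = make_channelset(head_pulse=PulseSpec(shape="haversine",
...                                           amplitude=45, duration=0.060))
>>> round(hic15(cs["HEAD_RES"]).hic, 1)
179.3
```

a 45 g, 60 ms haversine head pulse gives HIC-15 = 179.3, comfortably under
the 340 nominal limit.

A command-line interface wraps the same functions:

```sh
thor-iarv table --format csv          # regenerate the IARV table
thor-iarv hic --input run.csv         # HIC-15 of a channel file
thor-iarv landing --sigma 2           # landing design-band statistics
thor-iarv evaluate --channels run.csv --population deconditioned
```

The `analysis/` scripts run the three stages as narrative drivers —
landing-mode band statistics, table regeneration, and a synthetic-channel
assessment — writing their tables under `results/`.

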