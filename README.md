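# mtcortex

Event-driven simulation of the plant cortical microtubule array, built for
studying how developing protoxylem concentrates its microtubules into the
transverse bands that prefigure secondary cell wall thickenings.

The cortical array lives on the unrolled surface of a cylindrical cell.
Microtubule plus ends switch stochastically between growth and shrinkage
(catastrophe rate r꜀, rescue rate rᵣ), minus ends treadmill, and collisions
are resolved by angle: entrainment into bundles below 40°, otherwise an
induced catastrophe with probability p꜀ = 0.09 or a crossover where katanin
may sever the overlying microtubule. On top of this classic model the
package adds:

- **finite persistence length** via stochastic growth deflections —
  exponential straight runs (mean δ) and uniform turns in [−m, m] with
  m = √(3δ/L_p), giving the worm-like-chain law ⟨θ²(s)⟩ = s/L_p;
- **local density-dependent, microtubule-based nucleation** — appearance
  events probe n straight metatrajectories; a ray crossing a microtubule at
  distance d contributes bound-nucleation weight exp(−d√(r_u/D))/n, the
  remainder nucleates unbound, and accepted nucleations occupy a finite
  complex pool;
- the **protoxylem band/gap scenario** — a static banded prepattern whose
  gaps get an f꜀ = 3 catastrophe multiplier after a biased, two-phase
  initiation that establishes a transverse array;
- the **analytic co-alignment geometry** — admissible banded/spiral ROP
  pattern orientations θₙ = arctan(n·b/W) on a cylinder of circumference W
  with band spacing b, and the worst-case mismatch between an array and the
  nearest admissible orientation.

Simulations are exactly event-driven (no time stepping): collisions with
moving, growing obstacles are scheduled from closed-form crossing times and
runs are bit-reproducible from a single seed.

## Worked example

Admissible ROP-pattern orientations for a VND7-like cell (R = 7.5 µm, ten
bands at 6 µm spacing):

```sh
python examples/coalignment_geometry.py
```

```
cylinder: W = 47.12 um, band spacing b = 6.0 um
admissible pattern orientations (deg from transverse): 0.00, 7.26, 14.29, 20.91, 26.99, 32.48
worst-case minimal mismatch: 3.63 deg (half the gap between rings and the single spiral)
largest mismatch at which a straight microtubule spans the circumference inside one band: 1.22 deg
  at 1.0 deg mismatch a straight microtubule fits 57.3 um inside a band
  at 2.0 deg mismatch a straight microtubule fits 28.7 um inside a band
  at 3.6 deg mismatch a straight microtubule fits 15.9 um inside a band
```

Rings (0°) and the single spiral (7.26°) are the nearest admissible
orientations, so an array oriented midway is stuck with a 3.6° mismatch —
and at 3.6° a straight microtubule fits only ~16 µm inside a 1-µm band,
far less than one circumference (47 µm), which is why such arrays struggle
to keep their bands populated.

A scaled-down band-formation run (R = 2 µm, four bands, ~1 min wall time):

```sh
python examples/protoxylem_banding.py
```

```
 time_s  n_mt  total_length_um  band_density  gap_density  populated_bands  frac_in_bands_pct
 1800.0   178          3557.94          9.09        12.34                0              12.85
 3600.0   116          3477.09          8.28        12.18                0              11.97
 5400.0    29           626.61          3.95         1.70                1              31.69
 7200.0    15           183.72          2.45         0.24                2              67.12
 9000.0     2            50.07          1.00         0.00                1             100.00
```

Before activation (t = 3600 s) the array covers bands and gaps uniformly
(~1/6 of its length in bands, the area share); afterwards the tripled gap
catastrophe rate drains the gaps and the surviving length concentrates into
the bands. `examples/persistence_length_calibration.py` and
`examples/nucleation_outcomes.py` demonstrate the flexibility calibration
round trip and the nucleation algorithm's analytic-vs-sampled agreement.

## Library and CLI

The importable API is the main interface (`mtcortex.Simulation`,
`mtcortex.scenario.run_protoxylem`, `mtcortex.coalignment`,
`mtcortex.metrics`, …). A thin CLI wraps it for shell use:

```sh
mtcortex simulate examples/protoxylem_config.json --out-dir out/   # metrics.csv, snapshot.csv, events.jsonl
mtcortex analyze out/snapshot.csv --radius-um 2 --height-um 24 --n-bands 4
mtcortex coalign --radius-um 7.5 --n-bands 10 --band-spacing-um 6
```

Configuration is JSON or YAML with units in the key names; the measured
dynamics parameters (speeds, switching and severing rates) are required
fields with no silent defaults. See `docs/methods.md` for the model,
numerical choices and parameter rationale.

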