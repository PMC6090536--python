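# timecellmap

A simulator for a population-based model of temporal memory in the
hippocampus, for researchers in interval timing and computational
neuroscience. Hippocampal "time cells" fire at specific moments of a timed
interval, with firing-field widths that grow in proportion to their peak
times. This package models how such a population, arranged short-to-long
along the ventral–dorsal axis (a topological map), can *learn* a criterion
time `T` through an error-driven weight rule — and why the resulting
behaviour inherits the scalar (Weber-like) property of interval timing.

## The model

Each time cell `n` is a Gaussian firing-rate field

```
a_n(t) = A_n · exp( −(t − t_n)² / (2σ_n²) ),     σ_n = cv · t_n
```

with peak time `t_n`, width `σ_n` proportional to `t_n`, and amplitude
(weight) `A_n`. The population readout is the **average time field**

```
a(t) = Σ_k A_k · exp( −(t − t_k)² / (2σ_k²) ).
```

On each learning trial toward criterion `T`, every weight is divided by its
error signal:

```
err_k = |T − t_k| + ε,        A_k ← A_k / err_k
```

so after `n` trials `A_k(n) = A_0 / (|T − t_k| + ε)ⁿ` — a power-law decay of
weight with temporal distance from the criterion. Cells uniformly tile
`(0, 3T]` (the temporal boundary is three times the criterion) and start
with equal weights. The average field then peaks near `T` and narrows over
trials; its half-width is set either by the cells' intrinsic widths
(`σ√(2 ln 2)`, the *scalar* regime, width ∝ T) or by `ε` (the
*learning-limited* regime, constant width), whichever is larger. Lesioning
the dorsal (long-duration) end of the map shifts the field peak toward
shorter times; ventral lesions shift it longer — matching the directional
lesion findings the topological map was built to explain.

## Worked example

Train the five-cell example population (peaks 4, 6, 8, 12, 14 s) toward
`T = 10 s` for two trials:

```
$ timecellmap simulate --criterion 10 --fixture fig2_T10 --trials 2 --out-dir demo
peak_time=8.47 s  half_width_mean=2.816 s  -> demo
```

`demo/weights.csv` holds the full weight trajectory:

```
trial,cell_index,peak_time_s,weight
0,0,4.0,1.0
...
1,0,4.0,0.15384615384615385
1,1,6.0,0.2222222222222222
1,2,8.0,0.4
1,3,12.0,0.4
1,4,14.0,0.2222222222222222
2,0,4.0,0.02366863905325444
2,1,6.0,0.04938271604938271
2,2,8.0,0.16
...
```

After trial 1 the weights round to 0.15, 0.22, 0.4, 0.4, 0.22: the cells at
8 s and 12 s — both 2 s from the criterion — are strongest, and weights fall
off with distance. Trial 2 compounds the same update (0.02, 0.05, 0.16,
0.16, 0.05), sharpening the profile; the field's half-width shrinks
accordingly. The run also writes the sampled field (`field.csv`), its peak
and half-widths (`width_report.json`), and a `manifest.json` from which the
run can be reproduced exactly.

The scalar property across criteria:

```
$ timecellmap scalar --criteria 10,30 --n-cells 50 --out-dir demo_scalar
 criterion  peak_time  half_width_mean  width_over_criterion  width_ratio
      10.0      10.08         3.797439              0.379744     1.000000
      30.0      30.12         9.790320              0.326344     2.578138
```

Tripling the criterion roughly triples the field's half-width (exactly
triples it when `ε` is scaled with `T` via `--scale-epsilon`): the
coefficient of variation of timing stays approximately constant, which is
the scalar property. And a lesion of the dorsal half of the map:

```
$ timecellmap lesion --side dorsal --fraction 0.5 --criterion 10 --n-cells 30 --out-dir demo_lesion
pre peak=10.05 s  post peak=9.98 s  shift=-0.07 s
```

shifts the learned peak leftward (toward shorter durations).

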