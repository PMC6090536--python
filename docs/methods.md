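# Methods

## Model

A timed interval is represented by `N` time cells with Gaussian firing
fields `a_n(t) = A_n exp(−(t − t_n)²/(2σ_n²))`. Two structural assumptions
drive everything else:

1. **Scalar widths.** `σ_n = cv · t_n`: a cell peaking later is
   proportionally broader, as observed in hippocampal recordings. Because
   of this, the whole construction is scale-covariant — multiplying every
   time-dimension parameter (criterion, peak times, widths, ε, sampling
   grid) by `k` scales the output field's peak and half-widths by exactly
   `k`. This covariance *is* the model's account of the scalar property of
   interval timing, and it is asserted as a property test.
2. **Ordered map with a boundary.** Cells are stored sorted by peak time
   (index 0 = ventral = shortest), uniformly tiling `(0, 3T]` where `T` is
   the criterion. The factor 3 mirrors how boundary-anchored place fields
   tile an enclosure: the population must cover well past the reinforced
   duration for learning to select within it. A lesion removes
   `floor(f·N)` cells from one end of the ordered sequence; `floor` keeps
   ablation deterministic and conservative.

Learning is multiplicative: per trial, `A_k ← A_k / (|T − t_k| + ε)`.
Iterating gives the closed form `A_k(n) = A_0 (|T − t_k| + ε)^(−n)`, used
throughout the tests as an independent oracle for the trial-by-trial
trainer. There is no weight decay, no normalisation (a normalised view is
available as `Population.normalized_weights()` but never applied
implicitly), and no trial-level noise: the model is fully deterministic.

The behavioural readout is the weighted sum of all fields (the *average
time field*). A plausible alternative reading of the published figures is
the upper envelope (pointwise max) of the individual curves; we implement
the sum because it is the only combination the model's defining equation
states.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `cv` | width/peak-time ratio `σ_k/t_k` (dimensionless) | 0.2 | never pinned down experimentally; 0.2 reproduces the sparse-population peak near 8 s and gives single-bump example fields |
| `ε` | error-signal offset (s) | 0.5 | removes the division singularity at `t_k = T`; 0.5 s reproduces the published two-trial weight sequence exactly (e.g. `1/(2+0.5) = 0.4`) |
| `boundary_factor` | boundary / criterion | 3 | the temporal-boundary hypothesis |
| `A_0` | initial weight | 1 | equal initial amplitudes; makes first-trial weights exactly `1/(d+ε)` |
| `n_cells` | population size | 100 | results are N-invariant (see below); 100 keeps runs instant |
| grid step | field sampling (s) | `T/1000` | ≤0.1% relative peak-location error at negligible cost |

`ε` is deliberately *not* "very small" by default: with `ε → 0` the weight
of an exactly-matching cell diverges as `ε^{−n}`. The ratio between a cell
at a learned criterion and one 90 s away is exactly `ε/(90+ε)` after one
trial (≈ 1/181 at ε = 0.5); the small-ε approximation of that ratio as
≈ 1/90 holds only at first order, so the package exposes the exact value.

## Width analysis and numerical choices

Half-widths are measured nonparametrically: the field's grid argmax (ties
broken toward the smaller time) and, on each side, the distance to the
first crossing of half the peak value, linearly interpolated between grid
samples. A side that never reaches half maximum inside the grid is
reported as NaN and excluded from the mean; a constant field raises an
error. No Gaussian is fitted to the output.

Two analytic widths decompose the field's spread: the intrinsic cell
half-width `width_cell = σ√(2 ln 2)` and the learning half-width
`width_learn = ε` (the distance at which the first-trial weight profile
`1/(d+ε)` halves). The regime classifier returns *scalar* iff
`width_cell > width_learn` strictly — at the tie the width is already
ε-pinned, so ties classify as learning-limited.

## What the generators emulate, and what they do not

The uniform generator (`t_i = i·3T/N`, no cell at `t = 0` where `σ = cv·t`
degenerates) and the three named fixtures (`fig2_T10`: 4,6,8,12,14 s;
`fig2_T30`: 12,18,24,36,42 s; `sparse_T10`: 6,8,12,20,30 s) are idealised
configurations: noise-free Gaussian rate curves, exact uniform tiling,
fixed criterion on every trial. Real time-cell data have trial-to-trial
rate variability, non-Gaussian asymmetries, and uneven coverage; passing
tests therefore validate the model's mathematics and its qualitative
predictions (peak placement, narrowing, width scaling, lesion directions),
not quantitative fits to recordings.

Known behaviours worth noting:

* **Rightward width bias.** Because `σ ∝ t`, later cells carry more area;
  the summed field's peak sits slightly right of `T` (≈ +0.07 s at
  `T = 10 s`, `cv = 0.2` in the continuum limit) and, for the coarse
  five-cell example, the trial-1 peak lands at 12.3 s before settling near
  8.5 s from trial 2 on. Peak-proximity guarantees are therefore stated
  relative to the inter-cell spacing and hold for moderate `N`; at very
  large `N` the cv-induced bias, not coverage, limits accuracy.
* **Sparse-coverage bias.** With cells only at 6,8,12,20,30 s, training
  toward 10 s leaves the field peaked near 8 s: accuracy is bounded by the
  distance to the nearest available cell, `err_timing = min_k |T − t_k|`
  (exactly 2 s here).
* **Absolute envelope widths are configuration-dependent.** The half-width
  of the example field after one or two trials depends jointly on `cv` and
  `N`, which are not independently constrained; the robust claims are the
  trial-over-trial narrowing and the ≈3× width ratio between the 30 s and
  10 s criteria (exactly 3× when ε scales with `T`), and those are what
  the tests assert.
* **Multi-criterion memory.** Training criteria sequentially carries
  weights forward without reset; after learning 10 s then 100 s, the cells
  at exactly those times tie for the largest weight at
  `1/(ε(90+ε))`. Whether biological consolidation would renormalise
  between criteria is an open modelling question; we follow the carried-
  forward algebra.

## Problem sizes

All computations are closed-form or small dense sums; the full test suite
runs in a few seconds and the acceptance script in well under a second.
The largest routine case is a 1000-cell population on a 3000-point grid
(3·10⁶ Gaussian evaluations), used to demonstrate N-invariance of the peak
location across `N ∈ {10, 100, 1000}`.

## Limitations

The model is an abstraction of rate coding: no spiking, no biophysics of
the dopaminergic error signal it hypothesises, no behavioural
response-threshold machinery, and the ventral–dorsal axis is an index
order, not anatomy. The learning rule's functional form (inverse distance,
multiplicative) is one of several consistent with distance-dependent
weighting; discriminating among them needs experiments that manipulate
time-cell activity directly.
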