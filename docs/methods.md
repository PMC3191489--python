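# Methods

## The model

Transcription initiation at a repressed/activated bacterial promoter is
treated as a cycle of `d` sequential, memoryless sub-processes — in the
biochemical picture: closed-complex formation, open-complex formation,
promoter clearance — each with an exponentially distributed duration with
mean `μ_i` (seconds). One RNA is produced per completed cycle and the cycle
restarts immediately (a pure renewal process; no refractory gap). The
interval `Δt` between consecutive RNA productions in one cell is then
hypoexponential:

```
π_d(x; μ) = Σ_i  μ_i^{d-2} e^{-x/μ_i} / Π_{j≠i} (μ_i - μ_j)        (distinct μ_i)
```

reducing to the Erlang (gamma with integer shape `d`, scale `μ`) when all
step means coincide. The mean interval is `Σ μ_i`, the variance `Σ μ_i²`,
so the interval CV of a d-step cycle is at most 1 (equals `1/√d` for equal
steps): the model is under-dispersed relative to a Poisson process, in
contrast to the over-dispersed intervals of an intermittent two-state
(telegraph/ON-OFF) promoter, which the package can simulate but
deliberately does not fit.

Given `N` measured intervals the log-likelihood is
`L(μ) = Σ_k log π_d(Δt_k; μ)`. Step count is chosen by fitting
`d = 1..d_max` and walking forward through likelihood-ratio tests of `d`
against `d+1` (`2(L_{d+1}-L_d)` against χ² with 1 df); the selected `d` is
the smallest whose test is not rejected at `α = 0.05`. Steps are
exchangeable, so fitted `μ` are reported sorted descending and carry no
ordering information.

## Numerical evaluation of the density

The textbook distinct-rate closed form cancels catastrophically as step
means approach each other (the singularity at `μ_i = μ_j` is removable).
We evaluate the density through the partial-fraction expansion of the
Laplace transform `Π_g (λ_g/(s+λ_g))^{r_g}` over *groups* of rates:
step means closer than 1e-6 (relative to the largest) are merged into one
repeated rate of multiplicity `r_g`, and the expansion coefficients are
obtained by the log-derivative recursion, giving the density as a signed
mixture of Erlang terms `A x^{k-1} e^{-λx}/(k-1)!`. With all means merged
this is exactly the Erlang density. Merging at the group mean perturbs a
symmetric function symmetrically, so the error is second order (≤ ~1e-12
relative at the 1e-6 threshold), and just outside the threshold the
distinct form retains ≥ 9 significant digits; tests verify ≤ 1e-8 relative
agreement against a nested-quadrature convolution oracle, including means
split by exactly 1e-6.

## Fitting

- `d = 1`: the MLE is the sample mean, in closed form.
- `d ≥ 2`: Nelder-Mead on `log μ` (positivity by construction),
  multi-start (default 20; smaller in bulk simulations) with initial `μ`
  splitting the sample mean by Dirichlet(1,…,1) weights, because the
  exchangeable-step likelihood has symmetric ridges. Iteration caps
  (600·d) matter: near the equal-duration ridge the likelihood is
  nearly flat in the difference direction (the score in that direction
  vanishes identically), and position along it converges long after the
  likelihood value has.
- A fitted step below 1e-6 × (sample mean) is reported as exactly 0
  (boundary solutions are legitimate: a vanishing step removes itself
  from the convolution).
- The equal-duration constrained fit (Erlang with fixed shape `d`) is
  closed form: per-step duration = sample mean / d.
- Fitted steps shorter than the frame interval are flagged
  "below resolution": one-minute sampling cannot support sub-minute
  steps.

The likelihood treats intervals as continuous values; neither the 60-s
measurement grid nor the finite observation window is corrected for,
matching the analysis style this package reproduces (see Limitations).

## Synthetic data

The generator emulates single-cell MS2-GFP time-lapse experiments in
*E. coli*: movies of 2 h sampled every 60 s starting 420 s after
induction; per cell, production times follow the d-step renewal from
induction; the trace reports the cumulative production count at each
frame, so a production becomes visible at the next frame (≤ 60 s
discretization). Default kinetics are the weak-induction two-step fit
(1116 s + 1116 s) in 283 cells. 60% of cells are silent by default: a
2-h movie at a 2232-s mean interval yields ~2.2 same-cell intervals per
producing cell, while experiments of this design yield under one interval
per imaged cell and a population-average rate ~0.4× the per-producer rate,
implying ~40% active cells. Optional cell divisions use exponential
inter-division times; at division the tracked daughter's count resets and
the initiation cycle restarts (the analysis only needs division-spanning
intervals to be excludable, not a mechanistic division model). Spot
intensities are `count × unit × (1 + ε)` with multiplicative Gaussian
noise truncated positive — the simplest model producing the broadened
integer-multiple peaks the slicing quantization consumes.

What the generator does *not* emulate: detection noise other than
count-decrease glitches, photophysics (bleaching, diffusion), segmentation
errors, cell-to-cell kinetic heterogeneity, and mother/daughter joint
tracking. Passing tests therefore validate the inference machinery and its
calibration, not robustness to those real-data artifacts.

## Interval extraction

Counts are first made monotone within each inter-division segment by a
running maximum (tagged RNA is not degraded on movie timescales, so
decreases are detection noise). An RNA appearance is the frame time at
which the count first increases; the appearance time is the detection
frame itself, not the midpoint of the preceding gap — deterministic, and
the ≤ 60-s error is immaterial against step durations of ~10³ s. A jump of
`k ≥ 2` at one frame stands for `k` productions less than one frame
apart; the `k−1` sub-resolution intervals are discarded rather than
assigned fabricated 60-s durations. Intervals are successive
appearance-time differences within one segment; intervals spanning a
division (mother's last RNA to daughter's first) are censored, and the
wait from movie start or division to the first appearance is never an
interval.

Slicing quantization: the single-RNA unit intensity is the first local
maximum of a Gaussian KDE of the spot-intensity sample (Silverman plug-in
bandwidth by default, overridable in intensity units); each spot's count
is `round(intensity/unit)`, floored at 1.

## Validation studies and what they showed

`recovery_experiment` simulates 200-interval samples from a 2-step model,
fits the unconstrained and the equal-duration models and tests equality by
LRT (1 df). Two operationalizations of "the two durations are
distinguished" are reported because they differ dramatically:

- **As distributions** the models are nearly indistinguishable at
  moderate separations: the KL divergence from the 25%-separated 2-step
  model to its best-fitting Erlang-2 is ~2.5e-5 nats, so at N = 200 *no*
  test — the LRT included — can materially beat the significance level
  (measured rejection: 0.02 at the null, 0.035 at 25%, ~0.5 at 3×
  separation). The χ²₁ reference is additionally conservative at the null
  because the difference parameter sits on a symmetric likelihood ridge.
- **As estimates** the separation is recovered from ~25% upward: at the
  default validation seed the median fitted duration ratio tracks the
  truth at ratio 1.25 (≈ 1.22, 200 replicates) and above, while at ratio
  1.15 the typical solution collapses toward equal durations (median
  ≈ 1.04) — the documented bias of this inference toward identical step
  durations when the true durations are similar. Near equality the
  fitted-ratio distribution is bimodal (a point mass of replicates
  collapsing to exactly equal durations plus a dispersed component), so
  the median is itself a noisy summary there; the per-replicate
  `detected_fraction` climbs smoothly from ~0.55 near the threshold to
  ~0.9 at 3× separation.

The end-to-end self-consistency study (simulate movies → extract → select)
recovers `d = 2` in ~90% of runs at study scale (~240 intervals). The
shortfall from the nominal 95% is a real, diagnosed effect: intervals must
fit inside the 2-h observation window, so the extracted sample is
right-truncated (its mean is ~1650 s against the 2232-s model mean), and
the uncorrected continuous likelihood occasionally prefers a third step to
absorb the distortion. With direct (untruncated) interval draws at the
same N, selection is correct in 20/20 seeded runs. A truncation-corrected
likelihood would fix this but would be a different estimator than the one
this package sets out to characterize.

## Problem sizes and defaults

| quantity | default | why |
|---|---|---|
| movie duration / frame | 7200 s / 60 s | the experimental protocol emulated |
| start delay | 420 s | imaging begins ~7 min post-induction |
| cells (weak-like) | 283, 60% silent | study scale; see derivation above |
| `d_max` | 4 | no fit improvement expected beyond 2; 4 bounds the search |
| `α` | 0.05 | conventional; forward stopping rule |
| multi-start | 20 (pipeline), 4–8 (bulk sims) | symmetric ridges; bulk runs trade starts for replicates |
| recovery study | N = 200, 200 reps | the method-verification scale |
| simulation checks | 1e5–2e5 draws | 3-standard-error mean/variance checks |
| histogram bin | 180 s | three frames per bar, readable occupancy |

## Known limitations

- No interval-censored or window-truncation likelihood corrections (see
  above); consequently mild anti-conservatism of the (2,3) test on
  window-limited movie data.
- The ON-OFF (telegraph) model is simulated for contrast only, never
  fitted.
- No confidence intervals on fitted durations; the recovery study's RMSE
  (~220 s per step at N = 200) is the realistic uncertainty scale.
- The KDE first-peak quantization assumes the single-RNA peak is the
  first mode; heavily overlapping peaks (intensity CV ≳ 0.25) defeat it.
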