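# initsteps

**How many rate-limiting steps does transcription initiation have, and how
long is each?** `initsteps` answers this from single-cell time-lapse data:
given the intervals Δt between consecutive RNA productions in individual
cells (e.g. MS2-GFP-tagged transcripts in *E. coli* counted once per
minute for ~2 h), it fits models in which each interval is a sum of *d*
sequential, exponentially distributed sub-steps — closed-complex
formation, open-complex formation, promoter clearance — and selects *d*
by likelihood-ratio testing. It is aimed at researchers analysing
single-molecule gene-expression movies, and ships a full synthetic-data
generator so every stage can be exercised and calibrated without
microscopy data.

## The model

An interval is hypoexponential with step means μ = [μ₁…μ_d] (seconds):

    π_d(x; μ) = Σᵢ μᵢ^{d−2} e^{−x/μᵢ} / Πⱼ≠ᵢ (μᵢ − μⱼ)

(the Erlang/gamma density of shape *d* when all μᵢ coincide — the package
evaluates the removable singularity stably). Fitting maximizes
L(μ) = Σₖ log π_d(Δtₖ; μ) over μ ≥ 0; nested step counts are compared with
2(L_{d+1} − L_d) against χ²₁, and the selected *d* is the smallest whose
test against *d*+1 is not rejected at α = 0.05. Steps are exchangeable:
the data determine the set of durations, not their order.

## Worked example

Simulate a weak-induction-like experiment (283 cells, 2-h movies, one
frame per minute, two 1116-s steps, 60% silent cells), extract the
same-cell intervals, and select the step count:

```
$ python analysis/02_simulate_and_extract.py --seed 1
slicing quantization over 11550 spot observations: unit 149.7 a.u. (true 150.0), 95% of per-frame counts recovered exactly
283 cells -> 269 same-cell intervals; mean 1763 s, sd 1114 s, 2.0 RNA/h per producer

$ python analysis/03_model_selection.py --seed 1
d=1: loglik=-2279.6  steps [1763] s
d=2: loglik=-2242.1  steps [881, 881] s
d=3: loglik=-2242.0  steps [873, 873, 17] s
d=4: loglik=-2242.0  steps [873, 873, 9, 9] s
(1,2): stat=75.01 p=4.69e-18
(2,3): stat=0.28 p=0.597
(3,4): stat=0.03 p=0.864
selected d = 2
```

Reading the output: the unit (single-RNA) spot intensity is recovered by
the slicing quantization; a single exponential step (d = 1) is decisively
rejected (p ≈ 5e-18), adding a third step buys essentially no likelihood
(p ≈ 0.6), so initiation behaves as **two rate-limiting steps of nearly
equal duration** (~880 s each here). The extracted sample mean (1763 s)
sits below the model mean 2232 s because only intervals that fit inside
the 2-h movie are observable; the d = 3 fit's 17-s step is below the 60-s
frame resolution and flagged as such in `results/fits.tsv`.

The same stages are available as a CLI (`initsteps simulate | extract |
fit | select | validate | run`) and as library calls
(`simulate_cell_traces`, `extract_dataset`, `fit_mle`, `select_model`,
`recovery_experiment`, …).

The other analysis drivers: `01_reference_fits.py` (desk-scale fits at the
published summary statistics of the weak/medium-induction regimes),
`04_recovery_power.py` (how separated two step durations must be to be
recovered from 200 intervals — and the bias toward equal durations below
~25% separation), `05_onoff_comparison.py` (interval distributions of the
sequential-step vs the two-state ON-OFF promoter: CV 0.71 vs 4.1, KS
distance 0.91 at matched scales).

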