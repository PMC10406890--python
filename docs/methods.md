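# Methods

## Model and procedure

### Generative process

Each trial draws two binary hidden sources independently from categorical
priors `P(s_j = 1) = D₁` (balanced, `D₁ = 0.5`, unless stated) and 32
binary inputs from a mixing tensor `A`.  With mixing fraction `m`, the ON
probabilities over joint states `(1,1), (1,0), (0,1), (0,0)` are
`(1, 1−m, m, 0)` for inputs 1–16 and `(1, m, 1−m, 0)` for inputs 17–32;
`m = 0.25` is the standard condition, `m = 0` unmixed, `m = 0.5`
inseparable.  The same parametrisation is used for both groups at every
`m`, including `m = 0`.  There are no state transitions: the protocol is
i.i.d. across trials, with the standard design repeating one 256-trial
sequence for 100 sessions.  Internally the tensor is value-indexed,
`A[i, j, k, l] = P(oᵢ = j | s₁ = k, s₂ = l)`, with the joint-state order
above used wherever a flat ordering is needed.

### Ideal observer

Mean-field variational inference with a factorised state posterior
`Q(s₁)Q(s₂)` and a Dirichlet posterior over `A`.  Per trial: the expected
log likelihood is the digamma difference `ψ(a) − ψ(a₁ + a₀)`; the state
posterior is the per-source softmax of accumulated evidence plus log
prior, iterated to a coupled fixed point; the Dirichlet counts gain the
outer product of the (two-level) observation with the joint posterior, one
unit of mass per input per trial.  Both observation levels (`o` and
`1−o`) contribute to the evidence, mirroring the two-block structure of
the network cost.  Free energy is the time sum
`Σ s_τ·(ln s_τ − ln A·o_τ − ln D)` with `0 ln 0 = 0`; the
parameter-complexity term, constant in the states and logarithmic in `t`,
is omitted everywhere, so only free-energy *differences* are meaningful.

Two numerical points matter:

* **Multi-start mean field.**  The coupled per-source updates can have
  several fixed points; iterating from the prior alone locks into wrong
  joint states on a fifth of trials (exact Bayes is near-perfect under
  the standard conditions) and the resulting soft mis-assignments dilute
  the Dirichlet counts until the likelihood estimate collapses toward
  symmetry.  The update is therefore restarted from the prior and from
  both corners of the second source's state space, keeping the fixed
  point with the lowest per-trial free energy.  When the evidence is
  additive across sources (the network-equivalent case) all restarts
  coincide and the posterior is exact.
* **Symmetry breaking.**  An exactly flat Dirichlet prior is itself a
  fixed point of the coupled inference/learning loop — constant evidence
  keeps the posterior at the prior, which keeps the counts symmetric —
  so learning would never start.  `run_ideal_observer` adds a small
  structured bias (default 0.1 counts on top of the flat `a_init = 1`)
  tying source 1 to the first input group; this both seeds the escape
  and pins which posterior label tracks which source, exactly as the
  network's ensembles are labelled by their eventual preference.  The
  magnitude is far below one trial's worth of evidence and does not
  shift converged estimates at the tolerances used here.  `a_init`
  scales the inverse learning rate: large values (e.g. 320) give the
  gradual, session-scale learning curves characteristic of the slow
  biological preparation and are used for the prior-bias comparisons.

### Canonical network and its cost

Two rate ensembles, `ẋ ∝ −sig⁻¹(x) + W o + h`, with `W = W₁ − W₀`
(excitatory/inhibitory) and thresholds
`h_l = ln(1 − sig(W_l))·1 + φ_l`.  Responses are evaluated directly at
the sigmoid fixed point (a forward-Euler integrator with step 0.1 is
provided and converges to it; the proportionality constant of the
dynamics only sets the time scale and is irrelevant at session
resolution).  Integrating the dynamics gives the cost
`L = Σ (x; 1−x)ᵀ{ln(x; 1−x) − ln[sig W₁, 1−sig W₁; sig W₀, 1−sig W₀](o; 1−o) − (φ₁; φ₀)}`,
whose gradients reproduce the dynamics (`−∂L/∂x`) and the
Hebbian/homeostatic rule (`−(1/t) ∂L/∂W`); the weight-dependent
integration constant is omitted (it is sub-linear in `t` and constant in
`x`, so per-session differences are unaffected).  `L` equals the
observer's free energy exactly — not just asymptotically — when the
observer's likelihood tensor is the factorised one implied by the
weights (`neurofep.reverse.factorised_evidence_tensor`); this identity
and the gradient identities are verified by the test suite to 1e−12 and
1e−6 respectively.

Training alternates fast responses (fixed point per trial) with slow
learning (once per session, cumulative-from-start statistics).  The
cumulative statistics are seeded with pseudo-counts of weight
`λ^W = 1280` trials-equivalent at the initial weights — the inverse
learning rate, equivalently the concentration of the implicit parameter
prior — which spreads learning over tens of sessions instead of letting
session 2 jump to the data fixed point.  Weights start at i.i.d. Gaussian
noise (σ = 0.01) plus a symmetry-breaking excitatory bias of 0.1 from
each input group to its ensemble; without the bias the two units pick
sources at random and often lock onto the same source or a mixture of
both, which a two-unit model cannot recover from (a multi-neuron culture
can, because its ensembles are defined post hoc by observed preference).
A `plasticity_rate` in (0, 1] scales the per-session step in sigmoid
space; 1 is the full fixed-point step, small values emulate partial NMDA
blockade.  Ratios are clipped to `[10⁻³, 1 − 10⁻³]` before the logit so
deterministic couplings keep the weights finite; responses are clipped
infinitesimally inside (0, 1) so logarithms stay finite.

### Reverse engineering

From a normalised response series `x ∈ (0,1)²`: threshold factors
`φ = ln(⟨x⟩; ⟨1−x⟩)` over the first 10 sessions (so
`exp(φ₁) + exp(φ₀) = 1` holds exactly and `exp(φ₁)` is the implicit
prior); per-session effective connectivity as the plasticity fixed point
on cumulative statistics from session 1 through the session in question;
the posterior likelihood encoded by the weights as
`A₁l = sig(W_l)`.  The error of the reconstructed likelihood is scored
per column — the four (ensemble × source-level) vectors over the 32
inputs — as squared error over squared reference norm, against the
analytic marginal `P(oᵢ = 1 | s_e = v)` of the true mixing tensor under
the balanced prior (the value the converged ideal observer attains, in
closed form).  Empirical free energy per session substitutes the observed
responses and that session's estimated weights into `L` and is reported
as change from session 1.

The free-energy landscape is a 2-D projection chosen here (the original
embedding is not defined anywhere): the axes are sigmoid-space mean
excitatory weights from each input group to ensemble 1, with ensemble 2
mirrored and inhibitory weights tied to the complements.  The
construction makes the landscape exactly symmetric under swapping the
axes, so the global minimum appears at the generative structure and at
its source↔ensemble mirror image as an exact tie.

### Prediction

`φ` and `W` estimated from sessions 1–10 initialise a closed-loop
forecast: per session, responses at the network fixed point, then the
weight fixed point on cumulative *predicted* statistics seeded with
pseudo-counts `λ^W = 2560` (the evidential weight of the 10-session
window that produced the initial estimate; the correspondence between
initial weights and prior Dirichlet concentrations motivates the form
and the window size fixes the magnitude).  Empirical responses after the
window are never read — replacing them with noise leaves the prediction
bit-identical, which is a test.  Scores: normalised squared weight error
in sigmoid space, response error `err = E[|x − x^P|²]/2`, the complement
proportion `1 − err/0.5` (the worst case on the unit box is 0.5, making
the complement a proportion-predicted read-out), and Pearson correlations
over the last ten sessions, both pooled per-trial and on per-session
means (the two variants answer slightly different questions; both are
reported).

### Synthetic recordings

44 electrodes (≈17 source-1-preferring, 15 source-2-preferring, 12
no-preference, the reported group sizes) emit negative-binomial spike
counts (gamma-mixed Poisson, dispersion 10) with mean
`baseline + gain·drive + trend·session`; `baseline = 1.0` and
`gain = 4.0` spikes/trial put the control grand mean at ≈3 spikes/trial,
the reported response intensity, while leaving the preference statistics
of the low-rate (hypoexcitable) condition above the classification
cutoff.  Preferring electrodes follow the latent ensemble responses of a
canonical-network training simulation; no-preference electrodes follow
the per-trial stimulus mean (the directly evoked component).  Per-electrode
gains carry mild lognormal jitter (σ = 0.2).  Spike times and the
post-stimulus counting window are not simulated; counts are generated at
trial resolution.

Pharmacology maps to the latent network's parameters: GABA-A blockade
(bicuculline) sets the implicit prior to 0.8, benzodiazepine (diazepam)
to 0.2 — the in silico analogue values — and NMDA blockade (APV) keeps
the balanced prior but scales the plasticity rate to 0.01.  Mixing
conditions set `m` to 0 or 0.5.

Preprocessing follows the analysis rules: electrodes with all-session
mean ≤ 1 spike/trial are excluded; the all-session average of the
per-session conditional difference `E[r|(1,0)] − E[r|(0,1)]` classifies
the rest (> +0.5 source 1, < −0.5 source 2, ties and the boundary itself
no preference).  Ensemble responses are group means of
variance-stabilised counts (`√(r + 3/8)`, an Anscombe transform — raw
spike counts have variance growing with the mean, which otherwise skews
the normalisation and biases the recovered prior), detrended by a
least-squares line through session means (offset and slow trend), min–max
scaled between the 1st and 99th percentiles and clipped to
`[10⁻³, 1 − 10⁻³]`; a zero-variance series maps to 0.5.  The exact
offset/trend procedure of the original analysis is unspecified; the
linear fit is a documented stand-in.  Under the inseparable 50% mix no
electrode can genuinely prefer a source (the condition is exactly
symmetric), so the pipeline falls back to nominal ensembles formed from
the top/bottom quartile of the preference statistic, keeping every
downstream quantity defined with specificity near zero.

Response specificity is the detrended within-session difference between
preferred-source-ON and -OFF trial means, reported as change from session
1; the pipeline computes it both on normalised responses and on raw
group-mean counts (spikes/trial).  Condition comparisons use the
count-scale version: min–max normalisation stretches each recording to
the unit interval and therefore hides part of a drug's absolute effect.

## What the generator does and does not emulate

It reproduces: source-preferring/no-preference electrode structure with
the reported group sizes and mean rates; overdispersed trial-level count
noise; offset and slow drift; gradual, session-scale plasticity; prior
shifts and partial plasticity blockade; mixing-fraction manipulations.
It does not reproduce: spike waveforms and sorting, bursting and other
temporal structure inside a trial, electrode cross-talk, culture-to-
culture heterogeneity beyond seed and gain jitter, or any deviation of
real neurons from the canonical rate model itself.  Passing tests
therefore show that the estimation and prediction machinery is correct
and self-consistent under the model class and realistic count noise —
not that cortical cultures obey the model; that evidence lives in the
original recordings.

## Problem sizes and numerical choices

All study-condition simulations use the full protocol (100 sessions ×
256 trials, 32 inputs).  The prediction bounds average 10 seeded
experiments; the prior-bias comparison uses 100 seeded observer runs per
condition (per-session update schedule, which is vectorised and agrees
with the online schedule to within estimation noise); drug and mixing
comparisons use 10–20 seeded pipelines per condition with two-sided or
directional Mann–Whitney tests.  Probability floors: 10⁻⁸ inside
logarithms, 10⁻³ for ratio clipping, 10⁻⁹ response clipping.  Ties at
the classification boundary go to "no preference" (strict inequality).
Degenerate inputs (silent ensembles, zero-variance series, empty grids,
boundary responses) raise or are clipped as documented per function.

## Known limitations

* The two-unit latent network needs explicit symmetry breaking and
  occasionally (biased-prior conditions) still fails to separate within
  five redraws; such runs proceed with rank-fallback ensembles, which is
  itself informative (disrupted learning) but conflates two mechanisms.
* The landscape projection is one reconstruction of an undefined
  original; only its qualitative features (descent of the estimated
  trajectory, minimum at the generative structure) should be compared.
* Per-session empirical free energy inherits count noise; single-session
  increases of a few percent of the total drop are expected, and descent
  is assessed on block means.
* Response-scale specificity saturates (sigmoid responses reach high
  contrast with partially learned weights), so partial plasticity
  blockade shows up mainly in the reverse-engineered connectivity rather
  than in session-100 response specificity.
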