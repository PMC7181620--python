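# Methods

This note documents the generative model, the numerical procedures, the
synthetic-data conditions and the open design choices made in `triconf`.

## Generative observer

The task is three-alternative categorization: three isotropic Gaussian
categories (means **m**₁, **m**₂, **m**₃; common SD σ_s = 2° visual angle)
and a single target at position **s**. The observer model has two noise
stages:

1. **Sensory noise.** The measurement is **x** ~ N(**s**, σ²**I**). With a
   uniform category prior, the posterior is
   p(C | **x**) ∝ N(**x**; **m**_C, (σ_s² + σ²)**I**). It is evaluated in
   log space with a max-shift, so arbitrarily distant measurements still
   produce finite normalized posteriors.
2. **Decision noise.** The observer acts on **q** ~ Dirichlet(α·**p**):
   E[**q**] = **p**, Var(q_i) = p_i(1 − p_i)/(α + 1). α = ∞ disables the
   stage exactly. Because Dirichlet(α·**p**) is improper when any α·p_i = 0,
   components of **p** below 10⁻⁶ are clamped and the vector renormalized
   before sampling; this perturbs E[**q**] by at most the clamp value and is
   invisible at the Monte-Carlo sizes used anywhere in the package.

The category report is argmax_C q_C, with exact ties broken uniformly at
random (ties have probability zero under either noise source but occur in
the fully noiseless reduced model). Confidence is a scalar read-out c\* of
**q** — Max, Difference, Entropy (natural log; 0·log 0 ≡ 0) or Ratio —
thresholded into a 1–4 rating by criteria b₁ < b₂ < b₃ that live in the
native range of each rule's c\*. Any base for the entropy logarithm, and
any strictly monotone transform of the Ratio read-out, is absorbed by the
criteria; the Ratio rule is implemented as the top-two renormalized
posterior q₍₁₎/(q₍₁₎ + q₍₂₎), which is strictly monotone in the top-two
likelihood ratio. A lapse rate λ replaces both responses by independent
uniform button presses (category uniform on 3, rating uniform on 4).

## Response probabilities and likelihood

The measurement is internal, so p(Ĉ, c | **s**; θ) is estimated by Monte
Carlo: simulate n_mc measurements at each target position (default
n_mc = 10,000), push each through the full pipeline, tabulate relative
frequencies, then mix with the lapse: (1 − λ)·table + λ/12. Trials are
conditionally independent; the joint log-likelihood sums log table[Ĉᵢ, cᵢ]
over trials. Confidence-only and decision-only fitting modes use the
corresponding table marginals (lapse cells λ/4 and λ/3). During fitting the
lapse is bounded below at 10⁻⁴ so every response cell has probability at
least λ/12 > 0 and the log-likelihood is always finite despite
Monte-Carlo zeros.

Configurations whose category means share a vertical coordinate
(Experiments 1 and 3) are evaluated in one dimension: the vertical
measurement component contributes equally to every category's distance and
cancels from the posterior, halving the simulation cost without
approximation.

**Common random numbers.** Likelihood evaluations at different θ reuse the
same randomness: measurement-noise standard normals are drawn once per
(configuration, unique-position) from a seed sequence keyed by the base
seed and configuration, and the Dirichlet gamma stream is re-seeded
identically on every evaluation. The objective is therefore an exact
deterministic function of θ, which removes Monte-Carlo jitter from the
derivative-free search. Unique positions are deduplicated by exact
coordinates — no silent binning of nearby targets.

## Fitting

The optimizer is a staged derivative-free scheme (the package's own
substitute for specialized noisy-objective optimizers; what matters for the
science is parameter and model recovery, which the acceptance tests check
directly):

1. **Screening.** A Latin hypercube over the bounded noise parameters
   (σ ∈ [0, 5]°, log α ∈ [log 1, log 5000]) plus four canonical starts in
   the plausible regime (σ ∈ {0.3, 1.0}, α ∈ {20, 200}), evaluated at
   reduced Monte-Carlo fidelity (default 250). The canonical starts matter:
   the σ–α trade-off creates a broad ridge on which hypercube screening
   alone can strand the simplex search.
2. **Profiled refinement.** Nelder–Mead over (σ, log α) from the two best
   screened points. At every evaluation the three criteria are profiled out
   by quantile matching (criteria placed at the simulated-c\* quantiles of
   the observed cumulative rating frequencies) and the lapse by its exact
   conditional MLE — the lapse enters the per-trial likelihood as a linear
   mixture, so the conditional problem is concave and a bounded 1-D search
   solves it.
3. **Criteria refinement.** At full fidelity, with the simulation cached at
   the stage-2 noise parameters, Nelder–Mead over the criteria (transformed
   as b₁ plus log-spacings to enforce ordering), lapse still profiled.
4. **Joint polish.** A short full-fidelity Nelder–Mead over noise + criteria
   simultaneously.

All stages use explicit initial simplices (edge 0.15–0.6 in transformed
coordinates); the default simplex of Nelder–Mead degenerates near the
origin of a logit-transformed space. Bounds are enforced by smooth
transforms, so the search itself is unconstrained. Reported log-likelihood,
AIC = −2 logL + 2k and BIC = −2 logL + k log n (n = number of trials) are
always evaluated at the full Monte-Carlo size; the reduced-fidelity stages
are internal to the optimizer only. k counts free parameters: 6 for a full
model, 5 with one noise source removed, 3/2 in decision-only mode (no
criteria).

Default fit settings (`FitOptions`) were chosen so a 336-trial subject fits
in a few seconds on one core while recovering generator parameters well
within the recovery tolerances; the recovery harnesses in the test suite
run at n_mc = 2,000.

## Model comparison and recovery

Group comparison sums per-subject AIC across subjects; uncertainty is a 95%
percentile bootstrap over subjects (resample subjects with replacement,
recompute the summed difference; default 10,000 resamples). The percentile
method is used for its simplicity and monotone invariance. Model recovery
simulates one session per subject from each generating rule's known
parameters under a chosen experiment design, fits every candidate rule to
every session, and tabulates group-summed AIC (and per-subject win counts)
in a generator × fitted matrix; recovery succeeds when the diagonal is
minimal in every row.

## Synthetic data

The generator reproduces the three experiment designs: the standard
category geometries (Experiment 3 reuses Experiment 1's configurations);
targets
sampled uniformly in x over the extended category range with Gaussian y
(Exp 1), uniformly over a 2.6°-radius disc (Exp 2), or from a uniformly
chosen category's own distribution (Exp 3, where the true category is
recorded); 84 trials per configuration (Exp 1) or 120 (Exps 2–3),
randomized and interleaved, split into eight equal blocks. 336 (= 4 × 84)
is divisible into 8 blocks of 42 but not into equal per-block configuration
counts, so blocks are formed by splitting the shuffled global sequence;
block indices are recorded for realism but ignored by the (trial-
independent) models.

Cohort parameter ranges are package defaults chosen to span realistic
observers rather than any particular empirical population: σ ~ U[0.1, 1]°
(well below the 2° category SD — the task presents high-signal stimuli),
α log-uniform on [5, 200] (clearly noisy to nearly noiseless posteriors),
λ ~ U[0.005, 0.05], and criteria at the quartiles of each subject's own
simulated c\* distribution so that all four ratings are used in
expectation, emulating subjects' idiosyncratic scale use. The generator
emulates stationary, trial-independent observers; it does not emulate
learning or feedback effects (Exp 3 feedback is part of the design, not the
observer), reaction times, sequential dependencies, or criterion drift —
so passing recovery tests certifies the estimation machinery under the
model's own assumptions, not the model's adequacy for real data.

## Summaries

Psychometric curves: mean confidence in a sliding window of width 0.6°
stepped at 0.1°, computed per subject and then averaged across subjects
(mean ± s.e.m.), over −3.5°…+3.5° (Exp 1) or −5°…+5° (Exp 3). Empty windows
are reported as missing, never as zero; windows where any subject has fewer
than 5 trials are flagged, not dropped. Experiment 2 uses non-overlapping
hexagonal windows of radius 0.25° (read as center-to-vertex), flat-top
orientation with the lattice anchored at the origin — orientation and
anchor are cosmetic but fixed for reproducibility — covering −3°…+3° on
both axes; hexagons unoccupied across all subjects stay empty. Model
predictions compute E[c | s; θ] from the Monte-Carlo response distribution
on a 0.1°-step grid and then pass through the *same* windowing code as the
data, so binning details cancel in data-model comparisons.

## Known limitations

- The Monte-Carlo likelihood is biased low for cells whose true probability
  is below ~1/n_mc; the lapse floor bounds the damage but very small
  non-lapse probabilities are effectively truncated.
- The staged optimizer is a local search with a small global stage; with
  the default budgets it can return a near-optimum rather than the exact
  MLE. Budgets are adjustable via `FitOptions`, and optimizer diagnostics
  (restart scores, evaluation counts) are kept on the results object.
- The σ–α decomposition is weakly identified when both noise sources are
  small; recovery tolerances in the acceptance tests reflect that.
- Lapse trials draw the category and rating as two independent uniforms;
  a single shared draw would be indistinguishable in the joint table up to
  relabeling, and is not modeled.
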