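# Methods

## Isotope-exchange forward model

The package models the ¹⁸O labeling kinetics of flash-evolved O₂ after a
rapid jump of the water-pool enrichment from αᵢ to α_f. Each O₂ molecule
draws one oxygen from the fast-exchanging substrate site (W_f, rate k_f) and
one from the slow site (W_s, rate k_s). The unit-plateau signals are

- m/z 34: `a (1 − b e^(−k_f t)) + (1 − a)(1 − e^(−k_s t))` — biphasic;
- m/z 36: `1 − e^(−k_s t)` — monophasic, because a doubly labeled O₂
  requires the slow site to have exchanged.

**Fast-phase amplitude a.** With the fast site equilibrated at α_f and the
slow site still at αᵢ, the single-label probability is
α_f(1−αᵢ) + (1−α_f)αᵢ; normalized by the fully equilibrated single-label
probability 2α_f(1−α_f) this gives

    a = [α_f(1−αᵢ) + (1−α_f)αᵢ] / [2 α_f (1−α_f)].

`isotopologue_fractions` implements the underlying two-site enumeration and
is used in tests as an independent oracle for this closed form. For the
typical enrichment jump 0.07% → 13%, a ≈ 0.577.

**Inter-flash correction b.** When the S₂ state is probed with 100 Hz
turnover flashes, each Kok cycle dwells t_S3 ≈ 10 ms in S₃, during which the
fast site exchanges with rate k_f^S3. The surviving unexchanged fast
amplitude is b = e^(−k_f^S3 · t_S3); at k_f^S3 = 29 s⁻¹ and 10 ms,
b ≈ 0.748, so the m/z 34 signal starts at a(1−b) ≈ 0.145 of its plateau
rather than zero. Probing S₃ itself needs no correction (b = 1), likewise a
zero dwell. A formulation of this factor circulates in the literature with a
positive exponent, which would give b > 1 and contradict its meaning as an
amplitude-reduction factor; this package uses the decaying form above. The
correction is applied for a single dwell, not compounded over multiple
cycles, matching the one-dwell-per-cycle protocol at 100 Hz.

The m/z 36 model is deliberately monophasic in k_s. The product alternative
(1−e^(−k_f t))(1−e^(−k_s t)) — both sites must have exchanged — is available
via `mz36_model(..., gated_by_fast=True)` for sensitivity analysis; the two
are indistinguishable whenever k_f ≫ k_s.

Exponentials are evaluated with `expm1` and clipped exponents; rates are
bounded to [1e-6, 1e6] s⁻¹ in fitting contexts.

## Synthetic data generator

`simulate_mims` emulates the data structure the analysis has to cope with:

- a pre-injection baseline (default 10 points) followed by log-spaced
  post-injection sampling (default 64 points, 2 ms–20 s), chosen to resolve
  both a fast phase near 100 s⁻¹ and a slow phase near 1 s⁻¹;
- per-channel gains (raw signals are not unit-normalized);
- a residual-O₂ step: dissolved O₂ carried in with the injected water
  appears as an instantaneous additive offset on both channels at injection;
- optional first-order mixing of the injected label (`mixing_tau`; off by
  default so the kernel equals the closed-form models exactly; 6 ms is a
  realistic value for a fast syringe injection, and the exchange response to
  a first-order enrichment rise is computed analytically, including the
  k = 1/τ degenerate limit);
- homoscedastic i.i.d. Gaussian detector noise per channel, from a
  `numpy.random.default_rng(seed)` generator; the seed is recorded in trace
  metadata, so traces are bit-reproducible.

Default study conditions used throughout tests and the acceptance script:
wild-type-magnitude truth (k_f = 111 s⁻¹, k_s = 0.93 s⁻¹ in S₂;
k_f^S3 = 29 s⁻¹), enrichment 0.0007 → 0.13, 100 Hz flashes, noise σ = 1% of
the unit plateau, 50–100 seeds per Monte-Carlo experiment. These sizes keep
every experiment in the seconds range while leaving the Monte-Carlo medians
stable to well under a percent.

What the generator does **not** emulate: membrane-inlet gas consumption,
detector drift, isotope-ratio calibration, flash photophysics, Kok-cycle
miss/double-hit statistics, or heteroscedastic noise (the true channel noise
structure of isotope-ratio instruments is not characterized here). Passing
recovery tests therefore demonstrate correctness of the estimator under the
stated noise model, not robustness to every instrument artifact.

`simulate_fluorescence` evaluates A₀ + Σ Aᵢ e^(−t/τᵢ) on a logarithmic grid
(default 8 points per decade, 150 µs–100 s, mirroring standard measuring-
flash protocols) and adds seeded Gaussian noise.

## Preprocessing

Per channel, the mean of the pre-injection baseline is subtracted; the
residual-O₂ step is then removed and time re-zeroed to the injection
trigger. In `auto` mode the step is estimated from the discontinuity between
the last pre-injection and first post-injection samples. Because the m/z 34
kernel itself jumps to a(1−b) at injection when probing S₂, that model
discontinuity is computed from the trace metadata (enrichment + protocol,
plateau estimated from the trace tail) and excluded from the step estimate;
without metadata the jump is taken as zero (the b = 1 case). The estimator
remains biased by the genuine fast-phase rise across the first sampling
interval, so it is only trustworthy when the first post-injection sample
lies well within 1/k_f of the injection; otherwise supply explicit step
amplitudes or fit data without step removal. Channels are never rescaled at
this stage — the global fit carries free gains, which avoids biasing k_s by
endpoint noise.

## Global exchange fit

Both channels are fitted jointly by trust-region least squares
(`scipy.optimize.least_squares`, `trf`) with residuals
y₃₄ − s₃₄·model₃₄(t) and y₃₆ − s₃₆·model₃₆(t) stacked. Parameterization:
k_s = e^(x₀), k_f = k_s(1 + e^(x₁)) — log-scaled rates with the ordering
k_f > k_s built in — and log-scaled gains; when `a` is floated it enters
through a logit. `a` is fixed from the enrichments by default (the analysis
convention here is that `a` is calculated, not fitted) and `b` from the
protocol; disabling `fix_b_from_protocol` fits with b = 1, which is also how
the bias of ignoring inter-flash exchange is quantified. Initialization uses
a two-segment heuristic (half-rise time of the m/z 36 channel → k_s; half-
rise of the fast component of m/z 34 after subtracting the provisional slow
part → k_f), with an optional coarse grid of k_f/k_s ratios as fallback.
Weighting is uniform by default; inverse-variance weighting from the
pre-injection noise estimates is optional.

Non-convergence is reported through a flag, never an exception. A fitted
contrast k_f/k_s < 2 marks the biphasic model weakly identified: the result
is flagged degenerate and a monophasic single-rate comparison fit is
attached; the model choice is reported, never silently swapped.

## Jackknife uncertainties

Standard errors come from a delete-one jackknife over post-injection time
points, removing the i-th sample from both channels simultaneously so each
replicate preserves the global-fit structure. Replicates refit from the base
solution (warm start); the SE is the textbook jackknife formula
√[(n−1)/n · Σ(θ̂₍ᵢ₎ − θ̄)²]. The replicate table is returned for diagnostic
plots of the resampling distribution. If more than 20% of replicates fail to
converge the SEs are flagged unreliable. A block-deletion variant was
considered and left out: with i.i.d. noise on a log-spaced grid, single-point
deletion is the natural resolution, and the delete-one SE of k_s agrees with
the Monte-Carlo SD over independent noise realizations within a factor of
two (verified in the acceptance checks).

## Fluorescence deconvolution

The three-exponential model is fitted on the natural (linear) signal over
the log-spaced grid with uniform point weights, amplitudes bounded at zero
and lifetimes fitted on a log scale, unordered, then sorted — so returned
lifetimes are always strictly increasing without constraining the optimizer.
The model is a plain sum of exponentials; no instrument-response convolution
is applied, on the assumption that the ~30 µs actinic flash is fully
resolved by the first sample at 150 µs. Uncertainties are square roots of
the covariance diagonal (Gauss–Newton approximation from the Jacobian,
scaled by residual variance), with lifetime variances mapped from log scale
by the delta method. Because lifetime-vs-half-time conventions are easily
conflated, both τ and t½ = τ ln 2 are reported. Amplitude percentages are
computed over the three decaying amplitudes only, with the offset A₀
reported separately (percentage triples then sum to 100 exactly; including a
small offset in the denominator would make them sum just below 100).
Adjacent lifetimes closer than 3× trigger a degeneracy warning plus an
attached single-exponential comparison fit.

A note on attainable precision: at the default conditions (fast-phase
amplitude 7%, noise σ = 0.01, 8 points per decade) the Cramér–Rao bound
gives a relative SD of ~26% for the fast lifetime — the fit operates at this
bound, so scatter of that size in τ₁ is a property of the experiment design,
not of the estimator; τ₂ and τ₃ are determined to ~12% and ~8%. Averaging
replicate measurements or sampling more densely is the way to tighten τ₁.

## File formats and reproducibility

Traces are CSV with `#`-prefixed metadata lines (times in seconds, zero
conventions: injection trigger for MIMS, actinic flash for fluorescence);
numeric values round-trip to better than 1e-12. Result files are
deterministic text: fixed column order, rates to 3 significant figures,
explicit `not_estimated` markers, provenance block (config hash, seed,
version) and no timestamps — identical inputs produce byte-identical
outputs, which the test suite asserts end-to-end through the CLI.

## Known limitations

- The residual-O₂ auto-estimator needs an early first post-injection sample
  (see Preprocessing); with the default simulation grid (first sample at
  2 ms) and k_f ≈ 100 s⁻¹ it over-subtracts, so explicit amplitudes are
  preferred there.
- The b-correction uses a single S₃ dwell and requires k_f^S3 from a
  companion S₃ measurement; it is never estimated jointly with the S₂ data.
- Noise is modeled homoscedastic Gaussian; no drift or 1/f components.
- The fluorescence phases are reported purely kinetically; assigning them to
  recombination pathways is outside the package's scope.
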