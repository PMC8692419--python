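# Methods

## Kinetic models

All four signal models treat phototransformations as effective
first-order reactions at fixed irradiance; rates are therefore
apparent constants in s⁻¹ valid for the illumination conditions under
which a trace was recorded (400 nm at 146 mW/cm² for photoconversion,
470 nm at 167 mW/cm² for off-switching, 400 nm at 21.3 mW/cm² for the
10 s regeneration pulse).  No intensity-dependent rate laws, no
excited-state photophysics and no temperature dependence are modelled.

**Photoconversion.**  Green → Red → Bleached with rate constants k₁
(red-form formation) and k₂ (red-form photodestruction).  Observing the
red population of this consecutive monomolecular scheme gives
I(t) = I·k₁/(k₂−k₁)·(e^(−k₁t) − e^(−k₂t)) + c.  The expression is
evaluated in the algebraically equivalent form
`I·k1·exp(−min(k1,k2)·t)·(1 − exp(−|k2−k1|·t))/|k2−k1|`, which neither
cancels catastrophically for close rates nor overflows for either rate
ordering.  Coincident rates (within 1e-9 relative) raise an error by
default because they are not identifiable from a single trace; an
explicit limit mode evaluates the L'Hôpital limit I·k₁·t·e^(−k₁t) + c.
Since the curve is invariant under (I, k₁, k₂) → (I·k₁/k₂, k₂, k₁),
fitted parameters are canonicalised to k₁ ≥ k₂ (formation faster than
destruction), the convention of the published tables.

**Photoswitching.**  Bi-exponential with either opposed components
(first illumination cycle; the negative term captures the transient
green-intensity increase at 519 nm) or same-sign components (second and
later cycles).  The sign is carried by a boolean, never by a negative
amplitude.  For the same-sign form the slower component is reported
first (k₁ ≤ k₂), which matches the published column convention; the
opposed form needs no ordering rule because the sign identifies the
components.

**Thermal relaxation.**  Mono-exponential recovery
A(t) = A₀(1 − e^(−kt)) + c of the anionic-form absorbance, with
half-life ln2/k.

**Reaction-network integrator.**  An arbitrary first-order scheme
(states, rate-labelled transitions, linear observable) is integrated
with LSODA at rtol 1e-8 / atol 1e-10 — the systems are tiny, so
stiff-safe tolerances are cheap.  It serves as the independent oracle
for the closed forms (agreement to 1e-6 relative is a tested
invariant, with total population conserved to 1e-8 for closed schemes)
and as the simulator for multi-population photo-oxidation schemes: a
four-state network On → Off (k_sw), On → OxOn (k_ox, first 470 nm cycle
only), OxOn → OxOff (k_sw′), with regeneration pulses returning the off
states completely.  This scheme is a stated modelling assumption — it
reproduces same-sign first-cycle kinetics when a photo-oxidised
subpopulation switches alongside the original one — not a transcribed
mechanism.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`,
TRF) with rates constrained to [1e-6, 10] s⁻¹ and amplitudes/offsets
non-negative.  Analytic Jacobians are supplied for the exponential
models (finite differences for the photoconversion form, whose
derivatives degenerate as k₁ → k₂).  Tight stopping tolerances
(ftol = xtol = 1e-12, gtol = 1e-14) matter here: bi-exponential
likelihood surfaces have long flat valleys in which looser criteria
stop measurably short of the optimum.

Initialisation is model-aware: offset from the trace edges, tail
log-slope for the slow component, early-residual log-slope for the
fast component (classic peeling), and for photoconversion an inversion
of the peak-time relation t_peak = ln(k₁/k₂)/(k₁−k₂).  If the first
attempt fails, the optimiser restarts from two deterministic
geometry-based starts and log-normally jittered variants (five
restarts total) before reporting non-convergence.  A failed attempt
can exhibit a marginally lower residual than a converged one by
crawling along the degenerate k₁ ≈ k₂ ridge (opposed amplitudes
diverging) until its evaluation budget runs out; the converged
solution is preferred whenever its cost is within 1% of the best seen.

Standard errors come from s²(JᵀJ)⁻¹ at the optimum (s² = RSS/dof).
Traces may carry a per-point σ column, in which case residuals are
inverse-σ weighted; the default is unweighted, as no noise model is
attached to the recorded data.

**Offset handling.**  The background c is floated (bounded c ≥ 0) by
default.  For background-subtracted traces `fit_trace(..., fix_c=0.0)`
pins it, and the round-trip recovery studies do so: with the true
background sitting exactly on the c = 0 boundary and nearly coincident
rates, the floated offset opens a flat valley that visibly biases the
opposed-bi-exponential rate and amplitude estimates, whereas with the
known baseline fixed the estimator median is unbiased (verified over
1000 replicates).

**Model selection.**  Candidates are ranked by AICc (small-sample
corrected; traces have ~600 points but models differ by only two
parameters).  Fits within ΔAICc < 2 are reported as indistinguishable.
The RSS entering AICc is floored at numerical precision relative to
the trace range: on noise-free data every adequate model fits to
rounding error, and comparing logarithms of rounding errors would
reward whichever model chased numerical noise hardest; at the floor,
ranking reduces to parsimony.

## Cycle analysis

Cycle 1 is model-selected over {opposed biexp, same-sign biexp, mono};
later cycles over {same-sign biexp, mono}.  One boundary case needs
explicit handling: as k₂ → k₁ with I₂ = B/(k₂−k₁), the opposed model
tends to (A + B·t)·e^(−kt) + c, and for a few percent of noisy draws
of a genuinely opposed cycle the least-squares optimum sits exactly on
that boundary — the opposed fit then diverges (amplitudes growing
along the ridge) from every start, because no interior minimum exists.
When that happens the coincident-rate limit model is fitted in the
opposed model's place; it converges, captures the opposed transient,
and counts as an opposed shape for classification.  It is deliberately
*not* offered as a routine candidate: being one parameter cheaper it
would win the AICc comparison on most draws and replace the separately
resolved rate pair that the summary tables report.  The opposed
component is declared present when the opposed model (or its limit)
wins with AICc at least 10 below the best non-opposed candidate.  Two alternatives were
considered and rejected: a Wald test I₂ > 3·se(I₂) fails structurally
for close switching rates, where the I₂/k₂ correlation inflates se(I₂)
beyond the estimate itself even on unmistakably opposed traces; and a
bare AICc win at the conventional margin of 2 is cleared by
noise-chasing in a few percent of mono-generated traces.  Genuine
opposed first cycles win by hundreds of AICc units, so the decisive
margin costs no sensitivity.

Retention (photofatigue) is the cycle-initial intensity relative to
cycle 1.  The default estimator is the fitted model value at t = 0,
which is exact on noise-free data; a first-*w*-samples window mean
(w = 5 by default) is available and is the fallback when a cycle fit
fails.  The window mean was rejected as the default because first- and
later-cycle decay rates differ, so the within-window decay biases the
wt-like retention estimate by ~1.7% at 1 Hz sampling — comparable to
the 2% recovery tolerance the estimator is expected to meet.
Acceleration is k₁(cycle 2)/k₁(cycle 1) and is invariant to overall
intensity scaling.

Classification: `c175a_like` requires both a non-opposed first cycle
and a monotonic retention decline (each step > 0.005) over at least
three cycles; an opposed first cycle gives `wt_like`; anything short of
three cycles without an opposed component is reported unavailable
rather than guessed.

## Spectra and titrations

Emission peaks are located by a light moving-average smoothing, the
discrete maximum, and 3-point quadratic interpolation (log-parabolic
optional, exact for a Gaussian band).  That estimator is model-free but
uses only the curvature at the maximum, giving a noise floor of a few
tenths of a nm at realistic noise; blue-shift quantification therefore
defaults to a whole-band Gaussian-plus-baseline least-squares fit
(seeded by the quadratic estimate), which exploits the band flanks
where the position information resides and reaches the ~0.02–0.04 nm
Cramér–Rao bound.  Shifts are reported signed, negative = blue.

Titrations are fitted with a single-site Henderson–Hasselbalch model
S(pH) = S_min + (S_max − S_min)/(1 + 10^(n(pKa − pH))), Hill
exponent n = 1 by default (one protonatable group; n can be floated).
A series that does not span a full pH unit on either side of the
inflection raises a partial-coverage warning; flat series, or fits
whose pKa leaves the sampled range, raise an unidentifiability error.

Brightness is ε·φ rounded half-up to one decimal (in 10³ M⁻¹cm⁻¹),
the convention that reproduces the published table (75.0 × 0.59 =
44.25 → 44.3).  One published row (C175A: 80.1 × 0.55 = 44.055,
printed 44.0) is inconsistent with that convention by one unit in the
last digit; the computed value is reported as computed.

## Synthetic data

Generators produce photoconversion traces, cycle series, relaxation
traces, Gaussian emission bands and titration curves with additive
Gaussian noise under a fixed seed (identical seeds give identical
output).  Defaults mirror the experimental protocol: 1 Hz sampling
over the 600 s illumination window, 400 nm/146 mW/cm² conversion
metadata, 470 nm/167 mW/cm² switching metadata, pH 9.2 switching
buffer, and noise σ = 0.01 of the unit peak amplitude — the recorded
traces are low-noise, and 1% keeps recovery tolerances meaningful.

The nine variant presets transcribe the measured photoconversion,
switching (first- and second-cycle, including I₂/I₁), recovery, pK_a,
ε and φ values, with table rates stored in the printed 10⁻³ s⁻¹
convention.  Two preset fields are reconstructions, flagged as such in
the data file, because their sources are not quantified: the per-cycle
fatigue factor (1.0 for wt-like variants, 0.85 for C175A and
C21N/C175A, 0.80 for the triple mutant) and the per-cycle emission
blue-shift (−2 nm for wt-like, 0 for C175A-containing).  Later cycles
scale the t = 0 intensity to fatigue^(cycle−1) of cycle 1, treating
the 400 nm regeneration pulse as instantaneous and complete.  One
transcribed value carries a known internal inconsistency: the parent
variant's off-to-on recovery constant (22 × 10⁻³ s⁻¹ as printed)
implies a half-life of ~32 s, while the reported thermal half-life at
22 °C is 50 min; the value is used as printed and not reconciled.

What the generator does *not* emulate: photon shot noise, detector
response, drift, irradiance-to-rate conversion, or real emission band
asymmetry.  Passing round-trip tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
instrumental artefact of real data.

## Study sizes and reproducibility

Monte-Carlo recovery studies refit noisy replicates of the true curves
at σ = 0.01 and compare the median estimate with the generating value
(tolerance 2%).  The photoconversion and relaxation estimates are well
conditioned and use 100 replicates (median's own sampling error
~0.5%).  The opposed bi-exponential amplitude ratio has a wide
sampling distribution (IQR ≈ 0.16 around 0.27), so a 100-replicate
median is itself uncertain by several percent; that study uses 3000
replicates, bringing the median's sampling error to ~1%.  All
randomness in tests and in `scripts/acceptance.py` derives from fixed
or user-supplied seeds; a full acceptance run takes a few minutes on
one CPU.

## Known limitations

* Rates are effective constants; comparing them across instruments
  requires matched irradiance.
* The opposed bi-exponential remains weakly identifiable when the two
  rates are within a factor of ~2 at realistic noise — standard errors
  honestly report this, and medians rather than single fits should be
  used for panel comparisons.
* The photo-oxidation scheme is a plausible reconstruction used for
  simulation and hypothesis exploration, not a fitted mechanism.
* pK_a fitting assumes a single protonatable group; strongly
  cooperative titrations need the Hill exponent floated.
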